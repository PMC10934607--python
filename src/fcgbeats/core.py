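"""Core containers shared across the pipeline.

The package passes four kinds of objects between stages: uniformly sampled
traces (:class:`UniformSignal`), event time series (:class:`EventSeries`),
signal excerpts used for matching (:class:`Template`), and inter-beat
interval series (:class:`Tachogram`).  All times are seconds from the
signal's ``t0``; intervals are milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UniformSignal",
    "EventSeries",
    "Template",
    "Tachogram",
    "InvalidConfigError",
    "InvalidArgumentError",
    "InvalidTemplateError",
    "InsufficientDataError",
    "UndefinedStatisticError",
    "TemplateSelectionError",
]


class InvalidConfigError(ValueError):
    """A configuration object violates its own invariants."""


class InvalidArgumentError(ValueError):
    """An operation received arguments outside its domain."""


class InvalidTemplateError(ValueError):
    """A candidate template span is degenerate (e.g. zero variance)."""


class InsufficientDataError(ValueError):
    """Not enough samples/intervals for the requested statistic."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (zero denominator)."""


class TemplateSelectionError(RuntimeError):
    """Automatic template selection found no usable burst."""


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled real-valued trace.

    Parameters
    ----------
    samples : array-like of float
        Signal values, at least two samples, all finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidArgumentError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("signal contains non-finite samples")
        if not (self.fs > 0):
            raise InvalidArgumentError("sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (n/fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def replace_samples(self, samples: np.ndarray) -> "UniformSignal":
        """New signal with the same clock but different samples."""
        return UniformSignal(samples, self.fs, self.t0)


@dataclass(frozen=True)
class EventSeries:
    """Strictly increasing event timestamps with a label.

    ``label`` is one of ``{"R", "S1", "S2", "S1S2"}``.
    """

    times: np.ndarray
    label: str

    _LABELS = ("R", "S1", "S2", "S1S2")

    def __post_init__(self) -> None:
        arr = np.asarray(self.times, dtype=float)
        if arr.ndim != 1:
            raise InvalidArgumentError("event times must be 1-D")
        if arr.size > 1 and not np.all(np.diff(arr) > 0):
            raise InvalidArgumentError("event times must be strictly increasing")
        if self.label not in self._LABELS:
            raise InvalidArgumentError(f"unknown event label {self.label!r}")
        object.__setattr__(self, "times", arr)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Template:
    """A signal excerpt representing S1, S2 or an S1–S2 pair.

    ``peak_offset`` is the sample index of the template's absolute maximum;
    event timestamps produced by matching refer to this fiducial.
    ``source_span`` records where in the source signal the excerpt came from.
    """

    samples: np.ndarray
    fs: float
    label: str
    peak_offset: int
    source_span: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.size < 3:
            raise InvalidTemplateError("template needs at least 3 samples")
        if np.ptp(arr) == 0:
            raise InvalidTemplateError("template has zero variance")
        if not (0 <= self.peak_offset < arr.size):
            raise InvalidTemplateError("peak_offset outside template")
        if not (self.fs > 0):
            raise InvalidArgumentError("sampling rate must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class Tachogram:
    """Inter-beat intervals in ms with the time of each interval's end beat.

    ``valid_mask`` flags intervals usable for agreement analysis; intervals
    adjacent to missed or false detections are masked out by
    :func:`fcgbeats.beats.paired_valid_intervals`.
    """

    intervals: np.ndarray
    times: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        tt = np.asarray(self.times, dtype=float)
        if iv.size != tt.size:
            raise InvalidArgumentError("intervals and times must have equal length")
        if np.any(iv <= 0):
            raise InvalidArgumentError("intervals must be positive")
        if self.valid_mask is None:
            mask = np.ones(iv.size, dtype=bool)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.size != iv.size:
                raise InvalidArgumentError("valid_mask length mismatch")
        self.intervals = iv
        self.times = tt
        self.valid_mask = mask

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        """Span covered by the interval series, in seconds."""
        if self.intervals.size == 0:
            return 0.0
        return float(self.times[-1] - (self.times[0] - self.intervals[0] / 1000.0))
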