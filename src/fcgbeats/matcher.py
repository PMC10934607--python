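"""Template matching by normalized cross-correlation (NCC).

This is the core of the method: a short excerpt of the heart-sound signal —
one S1, one S2, or a whole S1–S2 pair — is slid along the signal and the
zero-mean normalized cross-correlation

    v[k] = sum_i (x[k+i] - xbar_k)(t[i] - tbar)
           / sqrt( sum_i (x[k+i] - xbar_k)^2 * sum_i (t[i] - tbar)^2 )

is evaluated at every window position.  Local maxima of the NCC trace above
a threshold mark occurrences of the sound.  Because the NCC is invariant to
affine amplitude changes, respiratory amplitude modulation of the sounds
does not move the detected times.

Event timestamps are re-aligned to the template's absolute maximum: the
event time of window k is the time at which the template's peak sample
lands, ``(k + peak_offset)/fs``.  For an S1–S2 pair template the absolute
maximum falls inside S1 (the louder sound), so pair detections are S1
fiducials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import (
    EventSeries,
    InvalidArgumentError,
    InvalidTemplateError,
    Template,
    TemplateSelectionError,
    UniformSignal,
)

__all__ = ["NccTrace", "extract_template", "ncc", "ncc_naive", "find_events", "auto_select_template"]

# default template widths (s) for automatic selection
_AUTO_WIDTH = {"S1": 0.120, "S2": 0.100, "S1S2": 0.450}

# Per-label NCC peak thresholds used by the pipeline.  In quiet diastolic
# stretches the NCC is a normalized match against noise alone, so its
# ceiling grows as the template shortens (~0.6-0.7 for the 100-120 ms S1/S2
# templates at 1 kHz); true matches stay above ~0.95.  The long pair
# template has a far lower noise ceiling but its true-match values are
# dragged down by beat-to-beat systolic-interval variability, so it needs a
# lower threshold.
DEFAULT_MIN_HEIGHT = {"S1": 0.8, "S2": 0.8, "S1S2": 0.3}

# Per-label peak-suppression distances.  0.3 s is the beat refractory for
# rates up to 200 bpm; the pair template additionally has a sidelobe one
# systolic interval (~0.3 s) away, where its S1 half aligns with the beat's
# S2, so pair detections use a wider window (pair events recur once per
# beat, ~0.9 s at rest).
DEFAULT_MIN_DISTANCE_S = {"S1": 0.3, "S2": 0.3, "S1S2": 0.5}


@dataclass(frozen=True)
class NccTrace:
    """Sliding NCC values with the alignment needed to map peaks to times.

    ``values[k]`` is the NCC of the template against the window starting at
    sample ``k``; the corresponding event time is
    ``t0 + (k + peak_offset) / fs``.
    """

    values: np.ndarray
    fs: float
    peak_offset: int
    t0: float = 0.0

    def __len__(self) -> int:
        return self.values.size

    def time_of(self, k: np.ndarray | int) -> np.ndarray | float:
        """Event time(s) of window position(s) ``k``, re-aligned to the peak."""
        return self.t0 + (np.asarray(k) + self.peak_offset) / self.fs


def extract_template(
    signal: UniformSignal,
    start_s: float,
    end_s: float,
    label: str,
    peak_on_abs: bool = False,
) -> Template:
    """Cut a template out of a signal span (half-open, seconds).

    ``peak_offset`` is the index of the span's maximum signed sample (or of
    the maximum absolute sample when ``peak_on_abs``).
    """
    if not (start_s < end_s):
        raise InvalidArgumentError("template span must satisfy start_s < end_s")
    i0 = int(round((start_s - signal.t0) * signal.fs))
    i1 = int(round((end_s - signal.t0) * signal.fs))
    if i0 < 0 or i1 > len(signal):
        raise InvalidArgumentError("template span outside the signal")
    if i1 - i0 < 3:
        raise InvalidArgumentError("template span shorter than 3 samples")
    chunk = signal.samples[i0:i1].copy()
    if np.ptp(chunk) == 0:
        raise InvalidTemplateError("template span has zero variance")
    peak = int(np.argmax(np.abs(chunk))) if peak_on_abs else int(np.argmax(chunk))
    return Template(
        samples=chunk,
        fs=signal.fs,
        label=label,
        peak_offset=peak,
        source_span=(start_s, end_s),
    )


def _sliding_sums(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Window sums of x and x**2 for every length-m window (cumsum trick)."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return c1[m:] - c1[:-m], c2[m:] - c2[:-m]


def ncc(signal: UniformSignal, template: Template, zero_mean: bool = True) -> NccTrace:
    """Normalized cross-correlation of a template against a signal.

    Zero-variance windows map to 0 (neutral similarity), so flat stretches
    never produce spurious peaks.  Values are clipped into [-1, 1] to absorb
    floating-point round-off.  Setting ``zero_mean=False`` skips the window
    and template mean removal.
    """
    if abs(signal.fs - template.fs) > 1e-9 * max(signal.fs, template.fs):
        raise InvalidArgumentError("signal and template sampling rates differ")
    x = signal.samples
    t = template.samples
    m = t.size
    if m > x.size:
        raise InvalidArgumentError("template longer than signal")
    tz = t - t.mean() if zero_mean else t.astype(float)
    sst = float(np.dot(tz, tz))
    if sst == 0:
        raise InvalidTemplateError("template has zero variance")
    # numerator: since sum(tz)=0 in the zero-mean case, the window mean drops out
    num = sps.fftconvolve(x, tz[::-1], mode="valid")
    s1, s2 = _sliding_sums(x, m)
    ssx = (s2 - s1 * s1 / m) if zero_mean else s2
    ssx = np.maximum(ssx, 0.0)
    denom = np.sqrt(ssx * sst)
    # zero-variance windows: threshold relative to the template's own scale
    tol = 1e-12 * m * max(1.0, float(np.max(np.abs(x))) ** 2)
    values = np.where(ssx > tol, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.clip(values, -1.0, 1.0, out=values)
    return NccTrace(values=values, fs=signal.fs, peak_offset=template.peak_offset, t0=signal.t0)


def ncc_naive(signal: UniformSignal, template: Template, zero_mean: bool = True) -> NccTrace:
    """Direct per-window O(N*M) evaluation of the NCC formula.

    Reference implementation used to validate the fast path; identical
    contract to :func:`ncc`.
    """
    x = signal.samples
    t = template.samples.astype(float)
    m = t.size
    if m > x.size:
        raise InvalidArgumentError("template longer than signal")
    tz = t - t.mean() if zero_mean else t
    sst = float(np.dot(tz, tz))
    out = np.zeros(x.size - m + 1)
    for k in range(out.size):
        w = x[k : k + m]
        wz = w - w.mean() if zero_mean else w
        ssx = float(np.dot(wz, wz))
        if ssx <= 1e-12 * m * max(1.0, float(np.max(np.abs(x))) ** 2):
            out[k] = 0.0
        else:
            out[k] = float(np.dot(wz, tz)) / np.sqrt(ssx * sst)
    np.clip(out, -1.0, 1.0, out=out)
    return NccTrace(values=out, fs=signal.fs, peak_offset=template.peak_offset, t0=signal.t0)


def find_events(
    trace: NccTrace,
    min_height: float = 0.5,
    min_distance_s: float = 0.3,
    label: str = "S1",
) -> EventSeries:
    """Localize events at NCC local maxima.

    Strict local maxima with value >= ``min_height`` are collected; peaks are
    then accepted greedily from the highest down, suppressing any candidate
    closer than ``min_distance_s`` to an already accepted one.  Ties in
    height are broken toward the earlier time.  Returned times are in the
    signal's clock, already re-aligned to the template peak.
    """
    peaks, _ = sps.find_peaks(trace.values, height=min_height)
    if peaks.size == 0:
        return EventSeries(times=np.empty(0), label=label)
    order = np.lexsort((peaks, -trace.values[peaks]))  # height desc, earlier first
    min_dist = int(round(min_distance_s * trace.fs))
    accepted: list[int] = []
    for idx in peaks[order]:
        if all(abs(int(idx) - a) >= min_dist for a in accepted):
            accepted.append(int(idx))
    accepted.sort()
    return EventSeries(times=trace.time_of(np.asarray(accepted, dtype=float)), label=label)


def _short_time_energy(x: np.ndarray, fs: float, win_s: float = 0.05) -> np.ndarray:
    w = max(1, int(round(win_s * fs)))
    return np.convolve(x * x, np.ones(w) / w, mode="same")


def auto_select_template(
    signal: UniformSignal,
    label: str,
    approx_rate_bpm: float | None = None,
    peak_on_abs: bool = False,
) -> Template:
    """Pick a template span automatically from the heart-sound signal.

    The strongest short-time-energy burst marks an S1; the strongest burst
    0.2–0.5 s after it marks the same beat's S2.  The S1 and S2 windows are
    centered on their bursts; the S1–S2 window is centered midway between the
    two bursts so the pair fits inside the default 450 ms span.  Manual
    selection via :func:`extract_template` remains the primary route.
    """
    if signal.duration < 5.0:
        raise InvalidArgumentError("automatic selection needs at least 5 s of signal")
    if label not in _AUTO_WIDTH:
        raise InvalidArgumentError(f"unknown template label {label!r}")
    energy = _short_time_energy(signal.samples, signal.fs)
    if not np.any(energy > 0):
        raise TemplateSelectionError("no energy burst found (flat signal)")
    fs = signal.fs
    i_s1 = int(np.argmax(energy))

    def _window(center: int, width_s: float) -> tuple[float, float]:
        half = int(round(width_s * fs / 2))
        lo = max(0, center - half)
        hi = min(len(signal), center + half)
        if hi - lo < 3:
            raise TemplateSelectionError("selected burst too close to the signal edge")
        return signal.t0 + lo / fs, signal.t0 + hi / fs

    if label == "S1":
        start, end = _window(i_s1, _AUTO_WIDTH["S1"])
    else:
        lo = i_s1 + int(round(0.2 * fs))
        hi = min(len(signal), i_s1 + int(round(0.5 * fs)))
        if lo >= hi:
            raise TemplateSelectionError("no room for an S2 burst after the S1 burst")
        seg = energy[lo:hi]
        if not np.any(seg > 0):
            raise TemplateSelectionError("no S2 burst found after the strongest S1")
        i_s2 = lo + int(np.argmax(seg))
        if label == "S2":
            start, end = _window(i_s2, _AUTO_WIDTH["S2"])
        else:  # S1S2
            start, end = _window((i_s1 + i_s2) // 2, _AUTO_WIDTH["S1S2"])
    return extract_template(signal, start, end, label, peak_on_abs=peak_on_abs)
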