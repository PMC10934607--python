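"""Beat-level bookkeeping: TP/FP/FN matching, recognition statistics, and
inter-beat intervals with the exclusion rule for missed/false events.

Detected heart sounds trail the reference R-peaks by a roughly constant
electromechanical delay, so detections are paired with reference beats after
subtracting a lag that is self-calibrated as the median detection-to-nearest-
reference offset.  Each pairing must be one-to-one and within a tolerance
(default 150 ms); detections left unpaired are false positives, reference
beats left unpaired are false negatives.

Sensitivity and positive predictive value are

    sensitivity = TP / (TP + FN) * 100        PPV = TP / (TP + FP) * 100

Intervals adjacent to a false positive or flanking a false negative are
excluded from agreement analyses (but retained for HRV, where artifact
correction handles them instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    EventSeries,
    InvalidArgumentError,
    Tachogram,
    UndefinedStatisticError,
)

__all__ = [
    "BeatMatch",
    "match_events",
    "recognition_stats",
    "sensitivity_ppv",
    "inter_beat_intervals",
    "paired_valid_intervals",
]


@dataclass(frozen=True)
class BeatMatch:
    """One-to-one pairing of detected events with reference beats.

    ``assignments[i]`` is the detected-event index matched to reference beat
    ``i``, or -1 if the beat was missed.  ``unmatched_detections`` lists the
    false-positive detection indices.
    """

    assignments: np.ndarray
    unmatched_detections: np.ndarray
    n_reference: int
    n_detected: int
    expected_lag_s: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        u = np.asarray(self.unmatched_detections, dtype=int)
        object.__setattr__(self, "assignments", a)
        object.__setattr__(self, "unmatched_detections", u)
        matched = a[a >= 0]
        if matched.size != np.unique(matched).size:
            raise InvalidArgumentError("assignment must be one-to-one")
        # conservation invariants
        assert self.tp + self.fn == self.n_reference
        assert self.tp + self.fp == self.n_detected

    @property
    def tp(self) -> int:
        return int(np.sum(self.assignments >= 0))

    @property
    def fn(self) -> int:
        return int(np.sum(self.assignments < 0))

    @property
    def fp(self) -> int:
        return int(self.unmatched_detections.size)

    def detected_to_reference(self) -> dict[int, int]:
        """Map detected-event index -> matched reference beat index."""
        return {int(d): int(r) for r, d in enumerate(self.assignments) if d >= 0}


def match_events(
    detected: EventSeries,
    reference: EventSeries,
    expected_lag_s: float | None = None,
    tol_s: float = 0.15,
) -> BeatMatch:
    """Pair detected events with reference beats.

    Candidate pairs with residual ``|d - (r + lag)| <= tol_s`` are accepted
    greedily by ascending residual, one-to-one.  When ``expected_lag_s`` is
    None it is calibrated as the median of (detection - nearest reference).
    """
    d = detected.times
    r = reference.times
    if r.size == 0:
        raise InvalidArgumentError("reference series is empty")
    if expected_lag_s is None:
        if d.size == 0:
            expected_lag_s = 0.0
        else:
            pos = np.searchsorted(r, d)
            lo = np.clip(pos - 1, 0, r.size - 1)
            hi = np.clip(pos, 0, r.size - 1)
            nearest = np.where(np.abs(d - r[lo]) <= np.abs(d - r[hi]), r[lo], r[hi])
            expected_lag_s = float(np.median(d - nearest))
    assignments = np.full(r.size, -1, dtype=int)
    if d.size:
        resid = np.abs(d[None, :] - (r[:, None] + expected_lag_s))
        ri, di = np.nonzero(resid <= tol_s)
        order = np.argsort(resid[ri, di], kind="stable")
        used_r = np.zeros(r.size, dtype=bool)
        used_d = np.zeros(d.size, dtype=bool)
        for k in order:
            i, j = ri[k], di[k]
            if not used_r[i] and not used_d[j]:
                assignments[i] = j
                used_r[i] = True
                used_d[j] = True
        unmatched = np.nonzero(~used_d)[0]
    else:
        unmatched = np.empty(0, dtype=int)
    return BeatMatch(
        assignments=assignments,
        unmatched_detections=unmatched,
        n_reference=int(r.size),
        n_detected=int(d.size),
        expected_lag_s=float(expected_lag_s),
    )


def sensitivity_ppv(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Sensitivity and PPV in percent from raw counts."""
    if tp + fn == 0 or tp + fp == 0:
        raise UndefinedStatisticError("TP+FN and TP+FP must both be positive")
    return 100.0 * tp / (tp + fn), 100.0 * tp / (tp + fp)


def recognition_stats(match: BeatMatch) -> tuple[float, float]:
    """Sensitivity and PPV (percent) of a beat matching."""
    return sensitivity_ppv(match.tp, match.fp, match.fn)


def inter_beat_intervals(events: EventSeries) -> Tachogram:
    """Intervals (ms) between successive events; times are the later event."""
    if len(events) < 2:
        raise InvalidArgumentError("need at least 2 events for intervals")
    iv = np.diff(events.times) * 1000.0
    return Tachogram(intervals=iv, times=events.times[1:])


def paired_valid_intervals(
    det_tacho: Tachogram,
    ref_tacho: Tachogram,
    match: BeatMatch,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (reference, detected) intervals untouched by FP/FN events.

    A detected interval k (between detected events k and k+1) is retained
    only when both bounding detections are true positives matched to
    *consecutive* reference beats; every interval involving a false positive
    or flanking a missed beat is dropped.  The ``valid_mask`` of both
    tachograms is updated in place.  Returns ``(x, y)`` with x the reference
    intervals (ms) and y the matched detected intervals.
    """
    if len(det_tacho) != match.n_detected - 1 or len(ref_tacho) != match.n_reference - 1:
        raise InvalidArgumentError("tachogram lengths inconsistent with the match")
    d2r = match.detected_to_reference()
    det_mask = np.zeros(len(det_tacho), dtype=bool)
    ref_mask = np.zeros(len(ref_tacho), dtype=bool)
    xs: list[float] = []
    ys: list[float] = []
    for k in range(len(det_tacho)):
        i = d2r.get(k)
        j = d2r.get(k + 1)
        if i is None or j is None or j != i + 1:
            continue
        det_mask[k] = True
        ref_mask[i] = True
        xs.append(float(ref_tacho.intervals[i]))
        ys.append(float(det_tacho.intervals[k]))
    det_tacho.valid_mask[:] = det_mask
    ref_tacho.valid_mask[:] = ref_mask
    return np.asarray(xs), np.asarray(ys)
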