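"""R-peak detection on the conditioned ECG (Pan–Tompkins stages).

The reference beat series for all recognition and agreement statistics comes
from the ECG.  The classic QRS detector is implemented directly: band-pass
5–15 Hz, five-point derivative, squaring, 150 ms moving-window integration,
adaptive dual thresholds with search-back, then refinement of each detection
to the local maximum of the conditioned ECG within ±50 ms.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import EventSeries, InvalidArgumentError, UniformSignal

__all__ = ["detect_r_peaks"]


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: UniformSignal, refractory_s: float = 0.25) -> EventSeries:
    """Locate R-peaks in a conditioned ECG.

    Returns an :class:`EventSeries` labelled ``"R"``.  A flat signal yields
    an empty series; sampling below 100 Hz is rejected because the derivative
    and integration stages assume adequate QRS bandwidth.
    """
    fs = ecg.fs
    if fs < 100:
        raise InvalidArgumentError("R-peak detection requires fs >= 100 Hz")
    if ecg.duration < 2.0:
        raise InvalidArgumentError("R-peak detection requires at least 2 s of ECG")
    x = ecg.samples
    if np.ptp(x) == 0:
        return EventSeries(times=np.empty(0), label="R")

    # 1) band-pass 5-15 Hz
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # 2) five-point derivative, 3) squaring, 4) 150 ms integration
    deriv_kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, deriv_kernel[::-1], mode="same")
    mwi = _moving_window_integral(deriv**2, max(1, int(round(0.15 * fs))))

    refractory = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return EventSeries(times=np.empty(0), label="R")

    # 5) adaptive dual thresholds with search-back
    init = mwi[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    accepted: list[int] = []
    recent_rr: list[float] = []
    pending: list[int] = []  # sub-threshold candidates since last acceptance

    def _accept(idx: int, searchback: bool) -> None:
        nonlocal spki
        peak = mwi[idx]
        w = 0.25 if searchback else 0.125
        spki = w * peak + (1 - w) * spki
        if accepted:
            recent_rr.append(idx - accepted[-1])
            if len(recent_rr) > 8:
                recent_rr.pop(0)
        accepted.append(idx)
        pending.clear()

    for idx in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if mwi[idx] >= thr1:
            _accept(idx, searchback=False)
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            pending.append(idx)
        # search-back when a beat seems overdue
        if accepted and recent_rr:
            rr_avg = float(np.mean(recent_rr))
            if idx - accepted[-1] > 1.66 * rr_avg and pending:
                thr2 = 0.5 * (npki + 0.25 * (spki - npki))
                missed = [p for p in pending if p > accepted[-1] and mwi[p] >= thr2]
                if missed:
                    best = max(missed, key=lambda p: mwi[p])
                    _accept(best, searchback=True)

    if not accepted:
        return EventSeries(times=np.empty(0), label="R")

    # 6) refine to the local maximum of the conditioned ECG within +-50 ms
    half = int(round(0.05 * fs))
    refined: list[int] = []
    for idx in sorted(accepted):
        lo = max(0, idx - half)
        hi = min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined_arr = np.array(sorted(set(refined)), dtype=int)

    # enforce the refractory period after refinement (keep the larger peak)
    keep: list[int] = []
    for idx in refined_arr:
        if keep and idx - keep[-1] < refractory:
            if x[idx] > x[keep[-1]]:
                keep[-1] = idx
        else:
            keep.append(idx)
    times = ecg.t0 + np.asarray(keep, dtype=float) / fs
    return EventSeries(times=times, label="R")
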