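"""Decomposition of the raw force signal and ECG conditioning.

The raw chest-wall force trace superimposes three components: a slow
respiratory movement, the cardiac (infra-sonic) force wave, and the
high-frequency heart-sound vibrations.  The chain implemented here is

1. estimate the respiratory component with a Savitzky–Golay smoother
   (frame ≈ 1.5 s),
2. subtract it to obtain the cardiac component,
3. band-pass 30–200 Hz (zero-phase Butterworth) to isolate heart sounds.

The ECG is band-passed 0.5–40 Hz and notched at the mains frequency and its
harmonics.  Every filter is applied forward–backward, so no stage introduces
group delay and detected event times stay on the raw signal's clock.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import InvalidArgumentError, UniformSignal

__all__ = [
    "extract_respiratory",
    "remove_baseline",
    "bandpass_heart_sounds",
    "preprocess_ecg",
]


def _odd_window(n: float) -> int:
    w = int(round(n))
    return w if w % 2 == 1 else w + 1


def extract_respiratory(
    raw: UniformSignal, frame_s: float = 1.5, polyorder: int = 3
) -> UniformSignal:
    """Estimate the respiratory baseline with a Savitzky–Golay smoother.

    The frame is the odd sample count nearest ``frame_s * fs``; a cubic
    polynomial per frame preserves the slow breathing waveform while
    rejecting cardiac oscillations.
    """
    window = _odd_window(frame_s * raw.fs)
    if window < polyorder + 2:
        raise InvalidArgumentError("frame too short for the polynomial order")
    if window > len(raw):
        raise InvalidArgumentError(
            f"frame of {window} samples exceeds signal length {len(raw)}"
        )
    smoothed = sps.savgol_filter(raw.samples, window, polyorder)
    return raw.replace_samples(smoothed)


def remove_baseline(raw: UniformSignal, resp: UniformSignal) -> UniformSignal:
    """Subtract the respiratory component, leaving the cardiac force wave."""
    if len(raw) != len(resp) or raw.fs != resp.fs:
        raise InvalidArgumentError("raw and respiratory signals must share length and fs")
    return raw.replace_samples(raw.samples - resp.samples)


def bandpass_heart_sounds(
    fcg: UniformSignal, lo: float = 30.0, hi: float = 200.0, order: int = 4
) -> UniformSignal:
    """Zero-phase Butterworth band-pass isolating the heart-sound component.

    ``order`` is the order of the low-pass prototype, matching the common
    ``butter(4, [lo hi])`` design idiom (the band-pass itself has twice as
    many poles); the forward–backward pass then squares the magnitude
    response.  Realized as second-order sections for stability at high
    sampling rates.
    """
    if not (0 < lo < hi):
        raise InvalidArgumentError("need 0 < lo < hi")
    if hi >= fcg.fs / 2:
        raise InvalidArgumentError("upper cut-off must be below Nyquist")
    if order < 1:
        raise InvalidArgumentError("band-pass order must be a positive integer")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fcg.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, fcg.samples)
    return fcg.replace_samples(filtered)


def preprocess_ecg(
    raw_ecg: UniformSignal,
    lo: float = 0.5,
    hi: float = 40.0,
    mains: float = 50.0,
    n_harmonics: int = 3,
    q: float = 30.0,
    order: int = 4,
) -> UniformSignal:
    """Condition the ECG: band-pass plus mains notch filters.

    Notches are applied at ``mains, 2*mains, ..., n_harmonics*mains``,
    skipping frequencies at or above Nyquist.  The fundamental is always
    notched even when it lies above the band-pass edge, because the
    band-pass roll-off alone does not fully suppress strong powerline
    interference close to the passband.
    """
    if not (0 < lo < hi < raw_ecg.fs / 2):
        raise InvalidArgumentError("band edges must satisfy 0 < lo < hi < fs/2")
    if mains >= raw_ecg.fs / 2:
        raise InvalidArgumentError("mains frequency must be below Nyquist")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=raw_ecg.fs, output="sos")
    x = sps.sosfiltfilt(sos, raw_ecg.samples)
    for k in range(1, n_harmonics + 1):
        f = k * mains
        if f >= 0.95 * raw_ecg.fs / 2:
            break
        b, a = sps.iirnotch(f, q, fs=raw_ecg.fs)
        x = sps.filtfilt(b, a, x)
    return raw_ecg.replace_samples(x)
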