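"""Heart-rate-variability indices from a tachogram.

Implements the standard short-term HRV panel: time-domain statistics
(mean RR, SDNN, HR statistics, RMSSD, NN50/pNN50), Welch-based frequency
bands (VLF 0–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz) on the 4 Hz
spline-resampled and smoothness-priors-detrended RR series, Poincaré
SD1/SD2, approximate and sample entropy, and detrended fluctuation
analysis exponents α1/α2.  A median-filter artifact correction in the
style of the Kubios guidelines precedes the indices.

Variance conventions: SDNN uses the sample SD (n−1); RMSSD, SD1 and the
entropies use uncentered/population moments, so the identity
``SD1 = RMSSD/sqrt(2)`` holds exactly for every input.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import log, sqrt

import numpy as np
from scipy import interpolate, signal as sps, sparse
from scipy.sparse.linalg import spsolve

from .core import InsufficientDataError, Tachogram

__all__ = [
    "HRVReport",
    "ArtifactCorrection",
    "correct_artifacts",
    "time_domain",
    "frequency_domain",
    "poincare",
    "entropy",
    "dfa",
    "hrv_report",
]


@dataclass
class HRVReport:
    """The full HRV index panel.  Missing indices are NaN."""

    mean_rr: float = np.nan      # ms
    sdnn: float = np.nan         # ms, sample SD
    mean_hr: float = np.nan      # bpm
    sd_hr: float = np.nan        # bpm
    min_hr: float = np.nan       # bpm, 5-beat moving average
    max_hr: float = np.nan       # bpm, 5-beat moving average
    rmssd: float = np.nan        # ms
    nn50: float = np.nan         # count
    pnn50: float = np.nan        # %
    vlf_abs: float = np.nan      # ms^2
    lf_abs: float = np.nan       # ms^2
    hf_abs: float = np.nan       # ms^2
    total_power: float = np.nan  # ms^2
    lf_rel: float = np.nan       # % of total power
    hf_rel: float = np.nan       # % of total power
    lf_nu: float = np.nan        # normalized units, LF/(LF+HF)*100
    hf_nu: float = np.nan        # normalized units
    lf_hf: float = np.nan        # ratio
    sd1: float = np.nan          # ms
    sd2: float = np.nan          # ms
    sd2_sd1: float = np.nan      # ratio
    apen: float = np.nan         # approximate entropy
    sampen: float = np.nan       # sample entropy
    dfa_a1: float = np.nan       # short-range scaling exponent
    dfa_a2: float = np.nan       # long-range scaling exponent

    def to_dict(self) -> dict[str, float]:
        return {k: (None if np.isnan(v) else float(v)) for k, v in asdict(self).items()}


@dataclass
class ArtifactCorrection:
    """Outcome of tachogram artifact correction."""

    tachogram: Tachogram
    n_corrected: int
    fraction_flagged: float
    quality_warning: bool  # set when more than 20% of intervals were flagged


def correct_artifacts(tacho: Tachogram, threshold_ms: float = 250.0) -> ArtifactCorrection:
    """Detect and correct ectopic/artifactual intervals (single pass).

    An interval deviating from the median of its 11-interval centered window
    by more than ``threshold_ms`` is replaced by cubic-spline interpolation
    over the surrounding accepted intervals.  A flagged fraction above 20%
    raises the quality warning (the series is still returned corrected).
    """
    rr = tacho.intervals
    if rr.size < 11:
        raise InsufficientDataError("artifact correction needs at least 11 intervals")
    from scipy.ndimage import median_filter

    med = median_filter(rr, size=11, mode="nearest")
    bad = np.abs(rr - med) > threshold_ms
    n_bad = int(bad.sum())
    frac = n_bad / rr.size
    out = rr.copy()
    if n_bad and (~bad).sum() >= 4:
        good_t = tacho.times[~bad]
        spline = interpolate.CubicSpline(good_t, rr[~bad])
        out[bad] = spline(tacho.times[bad])
    corrected = Tachogram(
        intervals=out, times=tacho.times.copy(), valid_mask=tacho.valid_mask.copy()
    )
    return ArtifactCorrection(
        tachogram=corrected,
        n_corrected=n_bad,
        fraction_flagged=frac,
        quality_warning=frac > 0.20,
    )


def time_domain(tacho: Tachogram) -> dict[str, float]:
    """Time-domain indices (see :class:`HRVReport` for units)."""
    rr = tacho.intervals
    if rr.size < 2:
        raise InsufficientDataError("time-domain indices need at least 2 intervals")
    hr = 60000.0 / rr
    drr = np.diff(rr)
    # min/max HR over a 5-beat moving average, per common HRV-software practice
    w = min(5, hr.size)
    hr_smooth = np.convolve(hr, np.ones(w) / w, mode="valid")
    nn50 = int(np.sum(np.abs(drr) > 50.0))
    return {
        "mean_rr": float(np.mean(rr)),
        "sdnn": float(np.std(rr, ddof=1)),
        "mean_hr": float(np.mean(hr)),
        "sd_hr": float(np.std(hr, ddof=1)),
        "min_hr": float(np.min(hr_smooth)),
        "max_hr": float(np.max(hr_smooth)),
        "rmssd": float(np.sqrt(np.mean(drr**2))),
        "nn50": float(nn50),
        "pnn50": 100.0 * nn50 / drr.size,
    }


def _smoothness_priors_detrend(z: np.ndarray, lam: float) -> np.ndarray:
    """Remove the smooth trend (I + lam^2 D2'D2)^-1 z from z (Tarvainen-style)."""
    n = z.size
    if n < 3:
        return z - np.mean(z)
    eye = sparse.identity(n, format="csc")
    ones = np.ones(n - 2)
    d2 = sparse.diags([ones, -2.0 * ones, ones], offsets=[0, 1, 2], shape=(n - 2, n)).tocsc()
    trend = spsolve((eye + lam**2 * (d2.T @ d2)).tocsc(), z)
    return z - trend


def frequency_domain(
    tacho: Tachogram,
    fs_interp: float = 4.0,
    detrend_lambda: float = 500.0,
    welch_window_s: float = 150.0,
) -> dict[str, float]:
    """Welch band powers of the resampled, detrended RR series.

    The RR series is cubic-spline interpolated on a uniform ``fs_interp``
    grid, detrended with the smoothness-priors regularization
    (``detrend_lambda``), and analyzed with a Hann-window Welch periodogram
    (segment 150 s or the full record if shorter, 50% overlap).  Band powers
    are trapezoid integrals of the PSD (ms²).
    """
    rr = tacho.intervals
    t = tacho.times
    if rr.size < 4 or (t[-1] - t[0]) < 120.0:
        raise InsufficientDataError("frequency-domain indices need >= 120 s of intervals")
    grid = np.arange(t[0], t[-1], 1.0 / fs_interp)
    rr_u = interpolate.CubicSpline(t, rr)(grid)
    rr_d = _smoothness_priors_detrend(rr_u, detrend_lambda)
    nperseg = min(rr_d.size, int(round(welch_window_s * fs_interp)))
    f, psd = sps.welch(
        rr_d, fs=fs_interp, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (f >= lo) & (f < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], f[mask]))

    vlf = band_power(0.0, 0.04)
    lf = band_power(0.04, 0.15)
    hf = band_power(0.15, 0.40)
    total = vlf + lf + hf
    lf_hf = lf / hf if hf > 0 else np.nan
    denom = lf + hf
    return {
        "vlf_abs": vlf,
        "lf_abs": lf,
        "hf_abs": hf,
        "total_power": total,
        "lf_rel": 100.0 * lf / total if total > 0 else np.nan,
        "hf_rel": 100.0 * hf / total if total > 0 else np.nan,
        "lf_nu": 100.0 * lf / denom if denom > 0 else np.nan,
        "hf_nu": 100.0 * hf / denom if denom > 0 else np.nan,
        "lf_hf": lf_hf,
    }


def poincare(tacho: Tachogram) -> tuple[float, float, float]:
    """Poincaré plot axes (sd1, sd2, sd2/sd1), all in ms.

    SD1 uses the uncentered second moment of the difference series, so
    ``sd1 == rmssd / sqrt(2)`` exactly; SD2 follows from
    ``2·SDNN² = SD1² + SD2²``.  A zero SD1 yields a NaN ratio.
    """
    rr = tacho.intervals
    if rr.size < 3:
        raise InsufficientDataError("Poincare indices need at least 3 intervals")
    drr = np.diff(rr)
    sd1 = sqrt(float(np.mean(drr**2)) / 2.0)
    sdnn = float(np.std(rr, ddof=1))
    sd2 = sqrt(max(0.0, 2.0 * sdnn**2 - sd1**2))
    ratio = sd2 / sd1 if sd1 > 0 else np.nan
    return sd1, sd2, ratio


def _chebyshev_counts(emb: np.ndarray, r: float) -> np.ndarray:
    """Per-row counts of rows within Chebyshev distance r (self included)."""
    n_vec = emb.shape[0]
    counts = np.zeros(n_vec, dtype=np.int64)
    chunk = max(1, int(2e7 // max(1, n_vec * emb.shape[1])))
    for lo in range(0, n_vec, chunk):
        hi = min(n_vec, lo + chunk)
        d = np.max(np.abs(emb[lo:hi, None, :] - emb[None, :, :]), axis=2)
        counts[lo:hi] = np.sum(d <= r, axis=1)
    return counts


def entropy(tacho: Tachogram, m: int = 2, r_frac: float = 0.2) -> tuple[float, float]:
    """Approximate and sample entropy of the RR series.

    Tolerance r = ``r_frac`` times the sample SD of RR; Chebyshev distance.
    ApEn includes self-matches (Pincus); SampEn excludes them
    (Richman–Moorman) and is NaN when no m+1 matches exist.
    """
    rr = tacho.intervals
    if rr.size < 50:
        raise InsufficientDataError("entropy estimation needs at least 50 intervals")
    r = r_frac * float(np.std(rr, ddof=1))
    n = rr.size

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(rr, mm)
        counts = _chebyshev_counts(emb, r)  # self-matches included (Pincus)
        return float(np.mean(np.log(counts / emb.shape[0])))

    apen = phi(m) - phi(m + 1)
    # SampEn: both template lengths use the first n-m vectors, no self-matches
    emb_m = np.lib.stride_tricks.sliding_window_view(rr, m)[: n - m]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(rr, m + 1)
    b = float(np.sum(_chebyshev_counts(emb_m, r)) - (n - m))
    a = float(np.sum(_chebyshev_counts(emb_m1, r)) - (n - m))
    sampen = -log(a / b) if a > 0 and b > 0 else np.nan
    return apen, sampen


def dfa(
    tacho: Tachogram,
    short: tuple[int, int] = (4, 16),
    long: tuple[int, int] = (16, 64),
) -> tuple[float, float]:
    """Detrended fluctuation analysis exponents (α1, α2).

    The mean-centered RR series is integrated; for every box size s the RMS
    residual F(s) of per-box linear detrending is computed, and each α is the
    log–log slope of F(s) over its range.  α1 needs ≥ 100 intervals, α2
    ≥ 300; unavailable exponents are NaN.
    """
    rr = tacho.intervals
    n = rr.size
    y = np.cumsum(rr - np.mean(rr))

    def fluctuation(s: int) -> float:
        n_boxes = n // s
        seg = y[: n_boxes * s].reshape(n_boxes, s)
        t = np.arange(s, dtype=float)
        t_mean = t.mean()
        tc = t - t_mean
        denom = float(np.dot(tc, tc))
        slopes = seg @ tc / denom
        inters = seg.mean(axis=1) - slopes * t_mean
        resid = seg - (inters[:, None] + slopes[:, None] * t[None, :])
        return float(np.sqrt(np.mean(resid**2)))

    def alpha(lo: int, hi: int, min_n: int) -> float:
        if n < min_n:
            return np.nan
        sizes = np.arange(lo, hi + 1)
        sizes = sizes[sizes <= n // 4]
        if sizes.size < 3:
            return np.nan
        fl = np.array([fluctuation(int(s)) for s in sizes])
        ok = fl > 0
        if ok.sum() < 3:
            return np.nan
        coef = np.polyfit(np.log(sizes[ok]), np.log(fl[ok]), 1)
        return float(coef[0])

    return alpha(short[0], short[1], 100), alpha(long[0], long[1], 300)


def hrv_report(
    tacho: Tachogram,
    correct: bool = True,
    threshold_ms: float = 250.0,
) -> HRVReport:
    """Compute the full HRV panel, optionally after artifact correction.

    Indices whose preconditions the tachogram does not meet (too short for
    spectra, entropy or DFA) are reported as NaN rather than failing the
    whole panel.
    """
    work = correct_artifacts(tacho, threshold_ms).tachogram if correct and len(tacho) >= 11 else tacho
    report = HRVReport()
    for k, v in time_domain(work).items():
        setattr(report, k, v)
    try:
        for k, v in frequency_domain(work).items():
            setattr(report, k, v)
    except InsufficientDataError:
        pass
    if len(work) >= 3:
        report.sd1, report.sd2, report.sd2_sd1 = poincare(work)
    if len(work) >= 50:
        report.apen, report.sampen = entropy(work)
    a1, a2 = dfa(work)
    report.dfa_a1, report.dfa_a2 = a1, a2
    return report
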