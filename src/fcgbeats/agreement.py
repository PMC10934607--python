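"""Method-comparison statistics for paired interval or index series.

Three complementary analyses quantify how well beat timings (or HRV indices)
from the force signal agree with those from the ECG reference:

* **Passing–Bablok regression** — non-parametric slope/intercept from the
  shifted median of pairwise slopes, robust to outliers and assuming no
  error-free method; the companion cusum test checks linearity.
* **Pearson correlation** with a Fisher-z 95% confidence interval.
* **Bland–Altman analysis** — bias and 95% limits of agreement (LoA), using
  mean ± 1.96·SD when the differences are compatible with normality
  (Shapiro–Wilk) and median / 2.5th–97.5th percentiles with bootstrap
  confidence intervals otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import InsufficientDataError, InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "passing_bablok",
    "cusum_linearity",
    "pearson_ci",
    "bland_altman",
    "compare_methods",
]

# Kolmogorov-Smirnov-type critical value for the cusum test at alpha = 0.10
_CUSUM_CRIT_10 = 1.22


@dataclass(frozen=True)
class RegressionResult:
    """Passing–Bablok fit plus correlation and linearity check."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r: float
    r_ci: tuple[float, float]
    cusum_linear: bool  # True when the cusum test p-value exceeds 0.1
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement of paired differences d = y - x."""

    bias: float
    bias_ci: tuple[float, float]
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]
    normal: bool
    n: int

    @property
    def loa_halfwidth(self) -> float:
        return (self.loa_high - self.loa_low) / 2.0


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be paired 1-D arrays")
    return x, y


def passing_bablok(
    x, y, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Passing–Bablok regression: (slope, intercept, slope_ci, intercept_ci).

    The slope is the shifted median of all pairwise slopes
    ``S_ij = (y_j - y_i) / (x_j - x_i)``, i < j, excluding ties in x and
    slopes equal to -1, with offset K = #{S_ij < -1}; confidence intervals
    use the rank-based normal approximation.  The intercept is
    ``median(y - slope * x)`` with its CI obtained from the slope CI bounds.
    """
    x, y = _as_pair(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError("Passing-Bablok needs at least 3 points")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("all x values are equal")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    ok = dx != 0
    s = dy[ok] / dx[ok]
    s = s[s != -1.0]
    if s.size == 0:
        raise UndefinedStatisticError("no valid pairwise slopes")
    s.sort()
    big_n = s.size
    k_off = int(np.sum(s < -1.0))
    # shifted median (1-based ranks)
    if big_n % 2:
        slope = float(s[k_off + (big_n - 1) // 2])
    else:
        slope = 0.5 * float(s[k_off + big_n // 2 - 1] + s[k_off + big_n // 2])
    z = stats.norm.ppf(1 - alpha / 2)
    w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((big_n - w) / 2.0))
    m2 = big_n - m1 + 1
    lo_i = np.clip(m1 + k_off - 1, 0, big_n - 1)
    hi_i = np.clip(m2 + k_off - 1, 0, big_n - 1)
    slope_ci = (float(s[lo_i]), float(s[hi_i]))
    intercept = float(np.median(y - slope * x))
    int_bounds = sorted(
        (float(np.median(y - slope_ci[1] * x)), float(np.median(y - slope_ci[0] * x)))
    )
    return slope, intercept, slope_ci, (int_bounds[0], int_bounds[1])


def cusum_linearity(x, y, slope: float, intercept: float) -> bool:
    """Cusum test of linearity for a Passing–Bablok fit.

    Residual signs, walked in order of increasing x, are accumulated; the
    maximum |cusum|, normalized by sqrt(L + 1) with L the number of nonzero
    scores, is compared against the Kolmogorov–Smirnov-type critical value
    at the 0.10 level.  Returns True when linearity is NOT rejected
    (p > 0.1).
    """
    x, y = _as_pair(x, y)
    resid = y - (intercept + slope * x)
    scores = np.sign(resid)
    order = np.argsort(x, kind="stable")
    cusum = np.cumsum(scores[order])
    n_nonzero = int(np.sum(scores != 0))
    if n_nonzero == 0:
        return True
    stat = float(np.max(np.abs(cusum))) / np.sqrt(n_nonzero + 1.0)
    return bool(stat < _CUSUM_CRIT_10)


def pearson_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson r with its Fisher-z confidence interval."""
    x, y = _as_pair(x, y)
    if x.size < 4:
        raise InsufficientDataError("correlation CI needs at least 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    return r, ci


def _bootstrap_ci(
    d: np.ndarray, fn, n_boot: int, rng: np.random.Generator, alpha: float = 0.05
) -> tuple[float, float]:
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    est = np.array([fn(d[row]) for row in idx])
    lo, hi = np.quantile(est, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def bland_altman(
    x,
    y,
    normality_alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    force_normal: bool | None = None,
) -> BlandAltmanResult:
    """Bland–Altman bias and limits of agreement for d = y - x.

    Normality of the differences is assessed with Shapiro–Wilk; when not
    rejected, bias = mean(d) and LoA = bias ± 1.96·SD with parametric
    confidence intervals (SE of bias = SD/sqrt(n); SE of each LoA =
    SD·sqrt(3/n)).  Otherwise bias = median(d), LoA are the 2.5th/97.5th
    percentiles (linear-interpolation quantiles) and all CIs come from a
    seeded bootstrap.  ``force_normal`` overrides the test.
    """
    x, y = _as_pair(x, y)
    d = y - x
    n = d.size
    if n < 10:
        raise InsufficientDataError("Bland-Altman needs at least 10 pairs")
    if np.ptp(d) == 0:
        v = float(d[0])
        return BlandAltmanResult(v, (v, v), v, v, (v, v), (v, v), normal=True, n=n)
    if force_normal is None:
        normal = bool(stats.shapiro(d).pvalue >= normality_alpha)
    else:
        normal = force_normal
    if normal:
        sd = float(np.std(d, ddof=1))
        bias = float(np.mean(d))
        loa_low = bias - 1.96 * sd
        loa_high = bias + 1.96 * sd
        tq = stats.t.ppf(0.975, n - 1)
        se_bias = sd / np.sqrt(n)
        se_loa = sd * np.sqrt(3.0 / n)
        return BlandAltmanResult(
            bias=bias,
            bias_ci=(bias - tq * se_bias, bias + tq * se_bias),
            loa_low=loa_low,
            loa_high=loa_high,
            loa_low_ci=(loa_low - tq * se_loa, loa_low + tq * se_loa),
            loa_high_ci=(loa_high - tq * se_loa, loa_high + tq * se_loa),
            normal=True,
            n=n,
        )
    rng = np.random.default_rng(seed)
    bias = float(np.median(d))
    loa_low = float(np.quantile(d, 0.025))
    loa_high = float(np.quantile(d, 0.975))
    return BlandAltmanResult(
        bias=bias,
        bias_ci=_bootstrap_ci(d, np.median, n_boot, rng),
        loa_low=loa_low,
        loa_high=loa_high,
        loa_low_ci=_bootstrap_ci(d, lambda a: np.quantile(a, 0.025), n_boot, rng),
        loa_high_ci=_bootstrap_ci(d, lambda a: np.quantile(a, 0.975), n_boot, rng),
        normal=False,
        n=n,
    )


def compare_methods(x, y) -> RegressionResult:
    """Full regression/correlation comparison of two paired series."""
    x, y = _as_pair(x, y)
    slope, intercept, slope_ci, intercept_ci = passing_bablok(x, y)
    r, r_ci = pearson_ci(x, y)
    linear = cusum_linearity(x, y, slope, intercept)
    return RegressionResult(
        slope=slope,
        slope_ci=slope_ci,
        intercept=intercept,
        intercept_ci=intercept_ci,
        r=r,
        r_ci=r_ci,
        cusum_linear=linear,
        n=int(x.size),
    )
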