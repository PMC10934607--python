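"""Optional diagnostic plots (regression scatter and Bland–Altman)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .agreement import BlandAltmanResult, RegressionResult

__all__ = ["regression_plot", "bland_altman_plot"]


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def regression_plot(x, y, result: RegressionResult, path: str | Path, unit: str = "ms") -> None:
    """Scatter of paired values with the Passing–Bablok fit and identity line."""
    plt = _axes()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(x, y, ".", ms=4, alpha=0.6)
    grid = np.linspace(x.min(), x.max(), 2)
    ax.plot(grid, grid, "k--", lw=1, label="identity")
    ax.plot(grid, result.intercept + result.slope * grid, "r-", lw=1.2,
            label=f"PB fit: y = {result.slope:.3f}x + {result.intercept:.2f}")
    ax.set_xlabel(f"reference ({unit})")
    ax.set_ylabel(f"detected ({unit})")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(f"r = {result.r:.4f}, n = {result.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(x, y, result: BlandAltmanResult, path: str | Path, unit: str = "ms") -> None:
    """Differences vs means with bias and limits of agreement."""
    plt = _axes()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mean = (x + y) / 2.0
    diff = y - x
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mean, diff, ".", ms=4, alpha=0.6)
    for value, style in ((result.bias, "r-"), (result.loa_low, "r--"), (result.loa_high, "r--")):
        ax.axhline(value, ls=style[1:], color="r", lw=1)
    ax.set_xlabel(f"mean of methods ({unit})")
    ax.set_ylabel(f"difference ({unit})")
    label = "mean" if result.normal else "median"
    ax.set_title(f"bias ({label}) = {result.bias:.2f} {unit}, "
                 f"LoA [{result.loa_low:.2f}, {result.loa_high:.2f}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
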