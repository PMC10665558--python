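"""Minimal diagnostic plot for allometric fits."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pgls import PglsFit

__all__ = ["plot_allometry"]


def plot_allometry(fit: PglsFit, x: pd.Series, y: pd.Series, ax=None):
    """Log-log scatter with the fitted line, 95%/99% slope bands pivoted at
    the mean predictor, and a unit-slope (isometry) reference through the
    fitted intercept.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    common = x.dropna().index.intersection(y.dropna().index)
    xs, ys = x.loc[common].astype(float), y.loc[common].astype(float)
    ax.scatter(xs, ys, s=18, color="0.25", zorder=3)
    grid = np.linspace(xs.min(), xs.max(), 50)
    xbar = xs.mean()
    ybar = fit.predict(xbar)
    ax.plot(grid, fit.predict(grid), color="k", lw=1.5, label=f"b = {fit.slope:.3f}")
    for ci, style, color in ((fit.ci95, ":", "k"), (fit.ci99, ":", "r")):
        for b in ci:
            ax.plot(grid, ybar + b * (grid - xbar), style, color=color, lw=0.8)
    ax.plot(grid, ybar + 1.0 * (grid - xbar), color="tab:blue", lw=1.0,
            label="isometry (b = 1)")
    ax.set_xlabel(f"log10 {fit.x_name}")
    ax.set_ylabel(f"log10 {fit.y_name}")
    ax.legend(frameon=False, fontsize=8)
    return ax
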