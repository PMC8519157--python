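"""Generic coefficient-function band plot."""

from __future__ import annotations

import numpy as np

from .fosr import FOSRFit, pointwise_band, simultaneous_band, significant_windows


def plot_coefficient_band(
    fit: FOSRFit,
    j,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int | None = 0,
    ax=None,
):
    """Coefficient function with pointwise and simultaneous bands.

    Bars under the curve mark clock-time windows where each band excludes
    zero. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    grid = fit.design.grid
    jj = fit.design.column(j)
    pw = pointwise_band(fit, jj, alpha=alpha)
    sb = simultaneous_band(fit, jj, alpha=alpha, n_sim=n_sim, seed=seed)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.fill_between(grid, sb.lo, sb.hi, color="tab:blue", alpha=0.15,
                    label="simultaneous band")
    ax.fill_between(grid, pw.lo, pw.hi, color="tab:blue", alpha=0.3,
                    label="pointwise band")
    ax.plot(grid, fit.coef[jj], color="tab:blue", lw=1.5)
    y0 = min(np.min(sb.lo), 0.0)
    for kind, band, color, dy in (("pointwise", pw, "tab:cyan", 0.02),
                                  ("simultaneous", sb, "tab:pink", 0.05)):
        for w in significant_windows(band, grid):
            end = w.end_hours if w.end_hours > w.start_hours else w.end_hours + 24
            ax.plot([w.start_hours, end], [y0 - dy * abs(y0 or 1)] * 2,
                    color=color, lw=4, solid_capstyle="butt")
    ax.set_xlabel("clock time (h)")
    ax.set_ylabel(f"$\\beta$({fit.design.col_names[jj]})(t)")
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 4))
    ax.legend(loc="best", fontsize=8)
    return ax
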