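"""Four-model overlay figures for biomarker-cognition relations.

Each figure overlays, on the biomarker-vs-CAMCOG scatter: (1) horizontal
lines at each diagnostic category's mean, (2) a single global robust
regression line, (3) the two-regime robust fit split at the combined
change-point (vertical dashed line), and (4) the model-free robust Lowess
curve.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .robust import mm_regression

__all__ = ["four_model_overlay"]


def four_model_overlay(table, biomarker, result, path=None, ax=None):
    sub = table[["camcog", biomarker] + (["group"] if "group" in table.columns else [])]
    sub = sub.dropna(subset=["camcog", biomarker])
    camcog = sub["camcog"].to_numpy(dtype=float)
    values = sub[biomarker].to_numpy(dtype=float)
    cp = result["changepoint"].combined

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(7, 5))

    if "group" in sub.columns:
        for grp, marker, filled in (("non-demented", "o", True), ("AD", "s", False)):
            mask = (sub["group"] == grp).to_numpy()
            if not mask.any():
                continue
            ax.scatter(
                camcog[mask],
                values[mask],
                marker=marker,
                facecolors="k" if filled else "none",
                edgecolors="k",
                s=18,
                label=grp,
            )
            # (1) category means
            ax.hlines(values[mask].mean(), camcog[mask].min(), camcog[mask].max(),
                      colors="tab:blue", linestyles="dashdot", lw=1.2)
    else:
        ax.scatter(camcog, values, s=18, c="k")

    # (2) global robust line
    fit = mm_regression(camcog, values)
    grid = np.linspace(camcog.min(), camcog.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "g:", lw=1.5, label="global robust")

    # (3) two-regime robust fit + change-point
    for mask, label in ((camcog > cp, None), (camcog <= cp, "two-regime robust")):
        if mask.sum() >= 3 and np.ptp(camcog[mask]) > 0:
            sfit = mm_regression(camcog[mask], values[mask])
            g = np.linspace(camcog[mask].min(), camcog[mask].max(), 20)
            ax.plot(g, sfit.intercept + sfit.slope * g, "k-", lw=2.0, label=label)
    ax.axvline(cp, color="k", linestyle="--", lw=1.0)

    # (4) Lowess curve
    order = np.argsort(camcog)
    ax.plot(camcog[order], result["lowess"][order], "r--", lw=1.5, label="Lowess")

    ax.set_xlabel("CAMCOG score")
    ax.set_ylabel(f"{biomarker} (pg/mL)")
    ax.set_title(f"{biomarker}: change-point at CAMCOG {cp:.1f}")
    ax.legend(fontsize=8, loc="best")
    if own_fig:
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=100)
            plt.close(fig)
            return path
        return fig
    return ax
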