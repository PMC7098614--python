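"""Optional figure writers: rate panels and 2-D score plots with ellipses.

All acceptance-relevant outputs of this package are tables; these figures
are reporting conveniences produced behind ``--plots`` flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordination import Ordination2D, confidence_ellipse_95  # noqa: E402

_GROUP_COLORS = {
    "control": "tab:blue",
    "dose1": "tab:orange",
    "dose2": "tab:green",
    "dose3": "tab:red",
}


def rate_panels(results: pd.DataFrame, title: str = ""):
    """Rejection-rate vs sample-size panels, one per (distribution, ratio)."""
    panels = sorted(
        {(d, v) for d, v in zip(results["distribution"], results["variance_ratio"])}
    )
    ncol = len(set(v for _, v in panels))
    nrow = len(set(d for d, _ in panels))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False, sharey=True
    )
    dists = sorted(set(d for d, _ in panels))
    ratios = sorted(set(v for _, v in panels))
    for i, dist in enumerate(dists):
        for j, vr in enumerate(ratios):
            ax = axes[i][j]
            sub = results[
                (results["distribution"] == dist) & (results["variance_ratio"] == vr)
            ]
            for method, grp in sub.groupby("method"):
                grp = grp.sort_values("n_per_group")
                ax.plot(grp["n_per_group"], grp["rate"], marker="o", label=method)
            ax.set_title(f"{dist}, variance ratio {vr:g}")
            ax.set_xlabel("n per group")
            ax.set_ylabel("rejection rate")
    axes[0][0].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def score_plot(ordination: Ordination2D, groups, convention: str = "chi2"):
    """Group-colored 2-D scores with 95% confidence ellipses per group."""
    groups = np.asarray(groups)
    fig, ax = plt.subplots(figsize=(5, 4))
    for nm in dict.fromkeys(groups):
        pts = ordination.scores[groups == nm]
        color = _GROUP_COLORS.get(str(nm))
        ax.scatter(pts[:, 0], pts[:, 1], label=str(nm), color=color, s=20)
        try:
            ell = confidence_ellipse_95(pts, convention=convention)
            b = ell.boundary(360)
            ax.plot(b[:, 0], b[:, 1], color=color, lw=1)
        except ValueError:
            pass
    ev = ordination.explained * 100
    ax.set_xlabel(f"axis 1 ({ev[0]:.0f}% variance)")
    ax.set_ylabel(f"axis 2 ({ev[1]:.0f}% variance)")
    ax.set_title(ordination.method.upper())
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig
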