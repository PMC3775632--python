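"""Plotting adapters: density, box and ROC plots.

Color conventions follow the field's habit for bidirectional
signatures: activated genes / activated groups in red, inhibited in
green.  All functions return the data used for plotting so results can
be re-plotted elsewhere; the ``plot_*`` wrappers render to a file with
a non-interactive matplotlib backend.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from bdfunc.cohort import ClassifierResult, ScoreMatrix, summarize_boxplot

__all__ = ["density_plot_data", "plot_density", "plot_box", "plot_roc"]

_MIN_BANDWIDTH = 1e-6

_BOX_COLORS = {"red": "#d62728", "green": "#2ca02c", "grey": "#bbbbbb"}


def density_plot_data(
    activated: Sequence[float],
    inhibited: Sequence[float],
    n_grid: int = 256,
) -> dict:
    """Gaussian KDE curves for the two gene populations on a common grid.

    Bandwidth is Silverman's rule with a floor of 1e-6 so a
    constant-valued side degrades to a narrow spike instead of crashing.
    """
    act = np.asarray(activated, dtype=float)
    inh = np.asarray(inhibited, dtype=float)
    if len(act) < 2 or len(inh) < 2:
        raise ValueError("need at least 2 values per side for a density plot")
    lo = min(act.min(), inh.min())
    hi = max(act.max(), inh.max())
    pad = 0.15 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, n_grid)

    def _kde(vals: np.ndarray) -> np.ndarray:
        sd = vals.std(ddof=1)
        if sd == 0.0:
            # constant side: render a narrow spike, wide enough to be
            # resolvable on the evaluation grid
            bw = max(_MIN_BANDWIDTH, float(grid[1] - grid[0]))
            return stats.norm.pdf(grid, loc=vals[0], scale=bw)
        kde = stats.gaussian_kde(vals, bw_method="silverman")
        if kde.factor * sd < _MIN_BANDWIDTH:
            kde.set_bandwidth(_MIN_BANDWIDTH / sd)
        return kde(grid)

    return {
        "grid": grid,
        "activated_density": _kde(act),
        "inhibited_density": _kde(inh),
        "activated_values": act,
        "inhibited_values": inh,
    }


def plot_density(
    activated: Sequence[float],
    inhibited: Sequence[float],
    path: str | Path,
    title: str = "",
) -> dict:
    data = density_plot_data(activated, inhibited)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(data["grid"], data["activated_density"], color=_BOX_COLORS["red"],
            label=f"activated (n={len(data['activated_values'])})")
    ax.plot(data["grid"], data["inhibited_density"], color=_BOX_COLORS["green"],
            label=f"inhibited (n={len(data['inhibited_values'])})")
    ax.set_xlabel("signal")
    ax.set_ylabel("density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return data


def plot_box(m: ScoreMatrix, path: str | Path, signature: str | None = None) -> pd.DataFrame:
    """Per-group box plot of per-sample statistics; boxes colored by the
    median-statistic rule (red > +2, green < -2)."""
    summary = summarize_boxplot(m)
    if signature is not None:
        summary = summary[summary["signature"] == signature]
    sigs = summary["signature"].unique()
    fig, axes = plt.subplots(1, len(sigs), figsize=(1 + 3 * len(sigs), 4), squeeze=False)
    scores, groups = m.labelled()
    for ax, sig in zip(axes[0], sigs):
        sub = summary[summary["signature"] == sig]
        data, colors = [], []
        for _, rec in sub.iterrows():
            vals = scores.loc[sig, groups[groups == rec["group"]].index]
            data.append(np.asarray(vals, dtype=float))
            colors.append(_BOX_COLORS[rec["color"]])
        bp = ax.boxplot(data, tick_labels=list(sub["group"]), patch_artist=True)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.axhline(2.0, ls=":", lw=0.8, color="k")
        ax.axhline(-2.0, ls=":", lw=0.8, color="k")
        ax.set_title(str(sig))
        ax.set_ylabel(f"{m.method} statistic")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return summary


def plot_roc(results: Sequence[ClassifierResult], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for res in results:
        ax.plot(res.fpr, res.tpr, label=f"{res.signature} (AUC={res.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
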