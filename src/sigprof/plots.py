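"""Optional report figures: half-life CDFs, parameter densities, per-well
fraction bar charts.  Matplotlib is imported lazily with the Agg backend so
headless pipelines can write PNG/SVG without a display."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_cdfs(curves: Sequence, path, xlabel: str = "cAMP half-life (s)") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(4, 3))
    for c in curves:
        ax.step(c.values, c.probs, where="post", label=c.condition or "sample")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_densities(summaries: Sequence, path) -> None:
    plt = _plt()
    params = sorted({s.parameter for s in summaries})
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3), squeeze=False)
    for ax, param in zip(axes[0], params):
        for s in summaries:
            if s.parameter == param:
                ax.plot(s.grid, s.density, label=s.condition)
        ax.set_xlabel(param)
        ax.set_ylabel("density")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile_fractions(fractions: pd.DataFrame, path) -> None:
    """Bar chart of mean per-well profile fractions with per-well points."""
    plt = _plt()
    conds = sorted(fractions["condition"].unique())
    profiles = sorted(fractions["profile"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(conds) * len(profiles) * 0.5 + 2, 3))
    width = 0.8 / len(profiles)
    for j, profile in enumerate(profiles):
        xs, means = [], []
        for i, cond in enumerate(conds):
            sub = fractions[(fractions["condition"] == cond) & (fractions["profile"] == profile)]
            x = i + (j - (len(profiles) - 1) / 2) * width
            xs.append(x)
            means.append(sub["fraction"].mean())
            ax.scatter(np.full(len(sub), x), sub["fraction"], s=8, color="k", zorder=3)
        ax.bar(xs, means, width=width * 0.9, label=f"profile {profile + 1}")
    ax.set_xticks(range(len(conds)), conds, rotation=30, ha="right")
    ax.set_ylabel("fraction of cells")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
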