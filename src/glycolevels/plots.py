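"""Publication-style plots: broken-axis abundance bar charts and the
cross-level heatmap.

Glycoform profiles span three orders of magnitude (majors at ~30 %, minors
at 0.3 %), so the bar chart uses a broken y-axis: a lower panel zoomed on
the minor-species range and an upper panel for the majors.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["abundance_barplot", "level_heatmap"]


def abundance_barplot(
    matrix: pd.DataFrame,
    path,
    break_at: float = 0.05,
    title: str = "Glycoform fractional abundances",
) -> None:
    """Grouped bar chart of per-level mean abundances with a broken y-axis
    at the low-abundance threshold."""
    levels = matrix.columns.get_level_values("level").unique()
    means = pd.DataFrame({lv: matrix[lv].mean(axis=1) for lv in levels})
    sds = pd.DataFrame({lv: matrix[lv].std(axis=1, ddof=1) for lv in levels})
    order = means.max(axis=1).sort_values(ascending=False).index
    means, sds = means.loc[order], sds.loc[order]

    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, sharex=True, figsize=(max(8, 0.45 * len(means)), 6),
        gridspec_kw={"height_ratios": [1, 1.4], "hspace": 0.06},
    )
    x = np.arange(len(means))
    width = 0.8 / len(levels)
    for i, lv in enumerate(levels):
        for ax in (ax_top, ax_bot):
            ax.bar(
                x + (i - (len(levels) - 1) / 2) * width,
                means[lv],
                width,
                yerr=sds[lv].fillna(0.0),
                capsize=2,
                label=lv if ax is ax_top else None,
            )
    top = float(np.nanmax(means.to_numpy())) * 1.15 if len(means) else 1.0
    ax_top.set_ylim(break_at, max(top, break_at * 2))
    ax_bot.set_ylim(0, break_at)
    ax_top.spines.bottom.set_visible(False)
    ax_bot.spines.top.set_visible(False)
    ax_top.tick_params(bottom=False)
    d = 0.012
    kw = dict(transform=ax_top.transAxes, color="k", clip_on=False, lw=1)
    ax_top.plot((-d, +d), (-d, +d), **kw)
    ax_top.plot((1 - d, 1 + d), (-d, +d), **kw)
    kw["transform"] = ax_bot.transAxes
    ax_bot.plot((-d, +d), (1 - d, 1 + d), **kw)
    ax_bot.plot((1 - d, 1 + d), (1 - d, 1 + d), **kw)
    ax_bot.set_xticks(x)
    ax_bot.set_xticklabels(means.index, rotation=60, ha="right", fontsize=8)
    ax_bot.set_ylabel("fractional abundance")
    ax_top.set_title(title)
    ax_top.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def level_heatmap(matrix: pd.DataFrame, path, log: bool = True) -> None:
    """Heatmap of per-(level, replicate) abundances; log10 colour scale by
    default because minors span decades."""
    data = matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        shown = np.log10(data) if log else data
    fig, ax = plt.subplots(
        figsize=(max(6, 0.5 * matrix.shape[1]), max(4, 0.3 * matrix.shape[0]))
    )
    im = ax.imshow(shown, aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(
        [f"{lv}/{rep}" for lv, rep in matrix.columns], rotation=90, fontsize=7
    )
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=7)
    fig.colorbar(
        im, ax=ax, label="log10 fractional abundance" if log else "fractional abundance"
    )
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
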