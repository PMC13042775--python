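"""Small plotting helpers for the pipeline's main result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_enrichment_heatmap(enrichment: pd.DataFrame, value: str = "z", ax=None):
    """Square type-by-type heatmap of mean enrichment over ROIs."""
    import matplotlib.pyplot as plt

    mat = enrichment.pivot_table(index="type_a", columns="type_b", values=value,
                                 aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(mat) + 2,) * 2)
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label=value)
    ax.set_title("cell-cell contact enrichment")
    return ax


def plot_pseudotime_by_stage(pseudotime: pd.Series, stages: pd.Series,
                             stage_order=None, ax=None):
    """Box plot of pseudotime per histological stage."""
    import matplotlib.pyplot as plt

    stages = stages.reindex(pseudotime.index)
    if stage_order is None:
        stage_order = list(pd.unique(stages))
    data = [pseudotime[stages == s].to_numpy() for s in stage_order]
    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(data, tick_labels=stage_order)
    ax.set_ylabel("pseudotime")
    ax.set_xlabel("stage")
    return ax


def plot_category_contributions(contrib: pd.DataFrame, ax=None):
    """Stacked bars of category contribution per stage transition."""
    import matplotlib.pyplot as plt

    wide = contrib.pivot(index="transition", columns="category", values="fraction")
    if ax is None:
        _, ax = plt.subplots()
    bottom = np.zeros(len(wide))
    for cat in wide.columns:
        ax.bar(wide.index, wide[cat].to_numpy(), bottom=bottom, label=cat)
        bottom += wide[cat].to_numpy()
    ax.set_ylabel("importance fraction")
    ax.legend(fontsize=7)
    ax.tick_params(axis="x", rotation=30)
    return ax
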