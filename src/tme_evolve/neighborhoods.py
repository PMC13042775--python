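"""Cellular-neighborhood (CN) identification by window capturing.

Each cell is represented by the cell-type frequency vector of its *n*
nearest cells (its "window"); windows pooled over ROIs are clustered with
mini-batch k-means, and every cell's window cluster is its cellular
neighborhood.  Per-core (per-ROI) CN prevalences are normalized to sum to 1,
z-scored per CN across cores, and dichotomized at z >= 0 into high/low
cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import MiniBatchKMeans

logger = logging.getLogger(__name__)

__all__ = [
    "window_vectors",
    "fit_neighborhoods",
    "NeighborhoodModel",
    "prevalence_and_dichotomize",
    "PrevalenceMatrix",
]


def window_vectors(
    cells: pd.DataFrame,
    n: int = 10,
    include_self: bool = False,
    types=None,
) -> pd.DataFrame:
    """Type-frequency vector of each cell's ``n`` nearest neighbors (one ROI).

    Euclidean nearest neighbors on (x_um, y_um); distance ties are broken by
    cell id so the result is deterministic.  Rows sum to 1; the index is the
    cell id.  Returns ``None`` (with a logged warning) if the ROI has too few
    cells.
    """
    if types is None:
        types = tuple(sorted(cells["cell_type"].unique()))
    else:
        types = tuple(types)
    n_cells = len(cells)
    need = n if include_self else n + 1
    if n_cells < need:
        roi = cells["roi_id"].iloc[0] if "roi_id" in cells and n_cells else "?"
        logger.warning("ROI %s has %d cells (< window size %d); skipped", roi, n_cells, n)
        return None

    order = np.argsort(cells["cell_id"].to_numpy(), kind="stable")
    cells = cells.iloc[order]
    pos = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    tindex = {t: i for i, t in enumerate(types)}
    lab_idx = np.array([tindex[t] for t in cells["cell_type"]])

    # full pairwise distances; ROIs are small enough that this beats a KD
    # tree and makes the (distance, cell_id) tie-break exact
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    if not include_self:
        np.fill_diagonal(d2, np.inf)
    # lexsort: primary key distance, secondary key position (== cell id order)
    idx = np.lexsort((np.broadcast_to(np.arange(n_cells), d2.shape), d2), axis=1)[:, :n]

    freq = np.zeros((n_cells, len(types)))
    np.add.at(freq, (np.repeat(np.arange(n_cells), n), lab_idx[idx].ravel()), 1.0)
    freq /= n
    return pd.DataFrame(freq, index=pd.Index(cells["cell_id"], name="cell_id"), columns=list(types))


@dataclass
class NeighborhoodModel:
    """Fitted CN model: k-means centroids plus per-cell assignments (1..k)."""

    k: int
    centroids: pd.DataFrame                 # k x types
    assignment: pd.Series = field(repr=False)  # cell_id -> CN in 1..k
    batch_size: int = 100
    random_state: int = 0


def fit_neighborhoods(
    windows: pd.DataFrame,
    k: int = 10,
    batch_size: int = 100,
    random_state: int = 0,
) -> NeighborhoodModel:
    """Mini-batch k-means over pooled window vectors.

    ``windows`` is the row-wise concatenation of :func:`window_vectors`
    output over ROIs (index = cell id).  Deterministic given
    ``random_state``; CN labels are 1-based.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = windows.to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError(f"cannot fit {k} neighborhoods from {len(X)} windows")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct window vectors")
    km = MiniBatchKMeans(
        n_clusters=k, batch_size=batch_size, random_state=random_state, n_init=3
    )
    labels = km.fit_predict(X)
    return NeighborhoodModel(
        k=k,
        centroids=pd.DataFrame(km.cluster_centers_, columns=windows.columns,
                               index=pd.RangeIndex(1, k + 1, name="cn")),
        assignment=pd.Series(labels + 1, index=windows.index, name="cn"),
        batch_size=batch_size,
        random_state=random_state,
    )


@dataclass
class PrevalenceMatrix:
    """Per-core CN prevalences (rows sum to 1) with z-scores and high/low split."""

    prevalence: pd.DataFrame  # core x CN, rows sum to 1
    z: pd.DataFrame           # per-CN z-score across cores (0 where sd = 0)
    highlow: pd.DataFrame     # True where z >= 0
    constant_cns: tuple[int, ...] = ()  # CNs with zero variance across cores


def prevalence_and_dichotomize(
    model: NeighborhoodModel, roi_ids: pd.Series
) -> PrevalenceMatrix:
    """Normalized per-core CN prevalence, z-scored per CN, split at z >= 0.

    ``roi_ids`` maps cell id -> core (ROI) id for every assigned cell.
    Cores with zero cells are simply absent; z-scoring is per CN across
    cores, with zero-variance CNs reported as z = 0 and flagged.
    """
    df = pd.DataFrame({"cn": model.assignment, "core": roi_ids.reindex(model.assignment.index)})
    if df["core"].isna().any():
        missing = df.index[df["core"].isna()][:5].tolist()
        raise ValueError(f"cells without an roi id, e.g. {missing}")
    counts = pd.crosstab(df["core"], df["cn"]).reindex(
        columns=pd.RangeIndex(1, model.k + 1, name="cn"), fill_value=0
    )
    prev = counts.div(counts.sum(axis=1), axis=0)
    sd = prev.std(axis=0, ddof=0)
    constant = tuple(int(c) for c in sd.index[sd == 0])
    z = (prev - prev.mean(axis=0)).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    return PrevalenceMatrix(prevalence=prev, z=z, highlow=z >= 0, constant_cns=constant)
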