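"""Cell-contact graphs and pairwise interaction enrichment.

Cells in physical contact are identified by Delaunay triangulation of the
cell centroids, with edges longer than a pruning threshold removed (nuclei of
touching cells sit within a few cell diameters of each other; long Delaunay
edges bridge empty space).  Two complementary statistics quantify how cell
types mix on the resulting graph:

* a **global assortativity coefficient** ``r`` over the edge-type mixing
  matrix — 1 when contacts occur only within a type, 0 under random mixing,
  negative when cross-type contacts dominate;
* **per-pair permutation tests** — type labels are shuffled within the ROI
  (preserving type counts and the graph), and each pair's observed contact
  count is compared with its permutation distribution to give a z-score and
  an empirical p-value with an interaction/avoidance direction.

Because the direction (interaction vs avoidance) is chosen by the data, the
one-sided empirical p is compared against alpha/2 when flagging
significance at a two-sided level alpha.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.stats import ttest_ind

from ._rng import substream

__all__ = [
    "ContactGraph",
    "MixingMatrix",
    "build_contact_graph",
    "mixing_and_assortativity",
    "permutation_enrichment",
    "compare_enrichment_groups",
]


@dataclass
class ContactGraph:
    """Undirected cell-contact graph for one ROI."""

    cell_ids: np.ndarray            # (n,) original cell ids
    positions: np.ndarray           # (n, 2) centroids in µm
    edges: np.ndarray = field(repr=False)  # (m, 2) int indices into cell_ids
    max_edge_um: float = np.inf
    roi_id: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_contact_graph(
    cells: pd.DataFrame, max_edge_um: float = 50.0, roi_id: str | None = None
) -> ContactGraph:
    """Delaunay triangulation of cell centroids, pruned at ``max_edge_um``.

    ``cells`` needs columns ``cell_id``, ``x_um``, ``y_um`` (one ROI).
    Raises for fewer than 3 cells or collinear centroids, naming the ROI.
    """
    roi = roi_id if roi_id is not None else (
        str(cells["roi_id"].iloc[0]) if "roi_id" in cells and len(cells) else "?"
    )
    pos = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(pos) < 3:
        raise ValueError(f"ROI {roi}: need at least 3 cells to triangulate, got {len(pos)}")
    try:
        tri = Delaunay(pos)
    except QhullError as err:
        raise ValueError(f"ROI {roi}: degenerate (collinear?) cell positions") from err
    edges = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    E = np.array(sorted(edges), dtype=int)
    lengths = np.linalg.norm(pos[E[:, 0]] - pos[E[:, 1]], axis=1)
    E = E[lengths <= max_edge_um]
    return ContactGraph(
        cell_ids=cells["cell_id"].to_numpy(),
        positions=pos,
        edges=E,
        max_edge_um=float(max_edge_um),
        roi_id=roi,
    )


@dataclass
class MixingMatrix:
    """Edge-endpoint mixing matrix with marginals and assortativity."""

    types: tuple[str, ...]
    e: pd.DataFrame          # symmetric, sums to 1
    a: pd.Series             # row marginals
    r: float                 # assortativity coefficient in [-1, 1]
    degenerate: bool = False # single effective type: r reported as 1


def _mixing_from_counts(counts: np.ndarray, types: tuple[str, ...]) -> MixingMatrix:
    m = counts.sum()
    if m == 0:
        e = counts.astype(float)
        return MixingMatrix(
            types=types,
            e=pd.DataFrame(e, index=list(types), columns=list(types)),
            a=pd.Series(np.zeros(len(types)), index=list(types)),
            r=float("nan"),
            degenerate=True,
        )
    e = (counts + counts.T) / (2.0 * m)
    a = e.sum(axis=1)
    denom = 1.0 - float(a @ a)
    if denom <= 1e-12:
        r, degenerate = 1.0, True
    else:
        r = (float(np.trace(e)) - float(a @ a)) / denom
        degenerate = False
    return MixingMatrix(
        types=types,
        e=pd.DataFrame(e, index=list(types), columns=list(types)),
        a=pd.Series(a, index=list(types)),
        r=float(r),
        degenerate=degenerate,
    )


def _edge_type_counts(edges: np.ndarray, lab_idx: np.ndarray, n_types: int) -> np.ndarray:
    """counts[s, t] = number of edges with one endpoint of type s, other t
    (each edge counted once, in the (s, t) orientation of its endpoints)."""
    counts = np.zeros((n_types, n_types), dtype=float)
    if len(edges):
        np.add.at(counts, (lab_idx[edges[:, 0]], lab_idx[edges[:, 1]]), 1.0)
    return counts


def mixing_and_assortativity(
    graph: ContactGraph, labels: pd.Series | np.ndarray, types=None
) -> MixingMatrix:
    """Edge mixing matrix ``e`` and assortativity ``r`` for one ROI.

    ``r = (sum_s e_ss - sum_s a_s^2) / (1 - sum_s a_s^2)``; with a single
    effective type the denominator vanishes and ``r`` is reported as 1 with
    ``degenerate=True``.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != graph.n_cells:
        raise ValueError("labels length does not match graph vertices")
    if pd.isna(labels).any():
        raise ValueError("every vertex must be labeled")
    if types is None:
        types = tuple(sorted(set(labels)))
    else:
        types = tuple(types)
    tindex = {t: i for i, t in enumerate(types)}
    try:
        lab_idx = np.array([tindex[l] for l in labels])
    except KeyError as err:
        raise ValueError(f"label {err} not in the declared type set") from None
    counts = _edge_type_counts(graph.edges, lab_idx, len(types))
    return _mixing_from_counts(counts, types)


def _pair_counts_for_perms(
    edges: np.ndarray, labels_matrix: np.ndarray, n_types: int
) -> np.ndarray:
    """Vectorized per-permutation unordered-pair contact counts.

    ``labels_matrix`` is (n_perm, n_cells) int; returns (n_perm, T, T) with
    symmetric counts (edge between s and t counted once at [s, t] and [t, s];
    same-type edges counted once on the diagonal).
    """
    n_perm = labels_matrix.shape[0]
    s = labels_matrix[:, edges[:, 0]]
    t = labels_matrix[:, edges[:, 1]]
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    flat = lo * n_types + hi + (np.arange(n_perm)[:, None] * n_types * n_types)
    counts = np.bincount(flat.ravel(), minlength=n_perm * n_types * n_types)
    counts = counts.reshape(n_perm, n_types, n_types).astype(float)
    upper = np.triu(counts, k=1)
    return counts + np.transpose(upper, (0, 2, 1))


def _distinct_label_permutations(labels: np.ndarray, limit: int) -> np.ndarray | None:
    """All distinct arrangements of the label multiset, or None if > limit."""
    vals, counts = np.unique(labels, return_counts=True)
    total = math.factorial(len(labels))
    for c in counts:
        total //= math.factorial(int(c))
    if total > limit:
        return None
    perms = sorted(set(itertools.permutations(labels)))
    return np.array(perms)


def permutation_enrichment(
    graph: ContactGraph,
    labels: pd.Series | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    types=None,
    exhaustive: bool = False,
    randomized_p: bool = False,
) -> pd.DataFrame:
    """Per-pair contact enrichment by within-ROI label permutation.

    For every ordered type pair the observed contact count is compared with
    its distribution over uniform relabelings of the ROI (type counts and
    graph fixed).  Columns: observed, perm_mean, perm_sd, z, p, direction,
    significant.  ``z = (obs - mean)/sd`` (0 when sd = 0); ``p`` is the
    add-one empirical p-value in the observed direction,
    ``(1 + #{perm as-or-more-extreme}) / (n_perm + 1)``; ``significant``
    compares ``p`` with ``alpha/2`` (two-sided level ``alpha``, since the
    direction is data-chosen).  Deterministic given ``seed``.

    ``exhaustive=True`` enumerates all distinct labelings instead of
    sampling (small ROIs only).  ``randomized_p=True`` adds a ``p_uniform``
    column: the tie-broken, fixed-tail (interaction) randomized p-value,
    which is exactly Uniform(0, 1) under the null and is the quantity to use
    for calibration diagnostics of this discrete test.
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels, dtype=object)
    if types is None:
        types = tuple(sorted(set(labels)))
    else:
        types = tuple(types)
    T = len(types)
    tindex = {t: i for i, t in enumerate(types)}
    lab_idx = np.array([tindex[l] for l in labels])
    edges = graph.edges

    obs = _pair_counts_for_perms(edges, lab_idx[None, :], T)[0]

    if exhaustive:
        perms = _distinct_label_permutations(lab_idx, limit=50_000)
        if perms is None:
            raise ValueError("too many distinct labelings for exhaustive enumeration")
    else:
        rng = substream(seed, "perm", graph.roi_id)
        perms = np.empty((n_perm, len(lab_idx)), dtype=lab_idx.dtype)
        for b in range(n_perm):
            perms[b] = rng.permutation(lab_idx)
    B = perms.shape[0]
    null_counts = _pair_counts_for_perms(edges, perms, T)

    mean = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    ge = (null_counts >= obs).sum(axis=0)
    le = (null_counts <= obs).sum(axis=0)
    interaction = obs > mean
    extreme = np.where(interaction, ge, le)
    p = (1.0 + extreme) / (B + 1.0)

    if randomized_p:
        gt = (null_counts > obs).sum(axis=0)
        ties = B - gt - (null_counts < obs).sum(axis=0)
        u = substream(seed, "perm_u", graph.roi_id).random(size=obs.shape)
        p_uniform = (gt + u * (1.0 + ties)) / (B + 1.0)

    rows = []
    present = set(lab_idx.tolist())
    for i, a_t in enumerate(types):
        for j, b_t in enumerate(types):
            absent = tindex[a_t] not in present or tindex[b_t] not in present
            row = {
                "roi_id": graph.roi_id,
                "type_a": a_t,
                "type_b": b_t,
                "observed": float(obs[i, j]),
                "perm_mean": float(mean[i, j]),
                "perm_sd": float(sd[i, j]),
                "z": float(z[i, j]),
                "p": 1.0 if absent else float(p[i, j]),
                "direction": "interaction" if interaction[i, j] else "avoidance",
                "significant": (not absent) and float(p[i, j]) <= alpha / 2.0,
            }
            if randomized_p:
                row["p_uniform"] = float(p_uniform[i, j])
            rows.append(row)
    return pd.DataFrame(rows)


def compare_enrichment_groups(
    tables: pd.DataFrame,
    groups: pd.Series,
    value: str = "z",
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Compare per-ROI enrichment between two ROI groups, pair by pair.

    ``tables`` is the concatenated long-format enrichment output over ROIs;
    ``groups`` maps roi_id -> group label (exactly two groups); optional
    ``strata`` (e.g. stage) maps roi_id -> stratum and the comparison is run
    within each stratum.  Uses a two-tailed two-sample t test on the per-ROI
    values (default the permutation z).  Pairs with fewer than 2 ROIs in
    either group are flagged ``testable=False``.
    """
    gvals = pd.unique(groups)
    if len(gvals) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(gvals)}")
    df = tables.copy()
    df["group"] = df["roi_id"].map(groups)
    df["stratum"] = df["roi_id"].map(strata) if strata is not None else "all"
    rows = []
    for (stratum, a_t, b_t), sub in df.groupby(["stratum", "type_a", "type_b"], sort=True):
        x = sub.loc[sub["group"] == gvals[0], value].dropna().to_numpy()
        y = sub.loc[sub["group"] == gvals[1], value].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append(
                dict(stratum=stratum, type_a=a_t, type_b=b_t, group_a=gvals[0],
                     group_b=gvals[1], mean_a=np.nan, mean_b=np.nan,
                     t=np.nan, p=np.nan, testable=False)
            )
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = ttest_ind(x, y)
        rows.append(
            dict(stratum=stratum, type_a=a_t, type_b=b_t, group_a=gvals[0],
                 group_b=gvals[1], mean_a=float(x.mean()), mean_b=float(y.mean()),
                 t=float(t_stat), p=float(p_val), testable=True)
        )
    return pd.DataFrame(rows)
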