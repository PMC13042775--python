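"""Synthetic staged multi-ROI single-cell datasets with known ground truth.

This module emulates the kind of data produced by an imaging-mass-cytometry
study of staged mouse lung adenocarcinoma (LUAD): per-ROI segmented cell
tables (positions in µm, cell-type labels, morphology, marker expression over
a configurable channel panel), ROI metadata, multichannel marker images with
injectable acquisition artifacts, and variant tables with trinucleotide
context.  Every generator parameter is recorded in the returned dataset so
downstream stages have a parameter-recovery oracle.

Spatial model
-------------
Cell positions follow a Neyman-Scott-style parent/offspring scheme: each cell
type owns a set of uniformly placed parent (cluster-seed) points, and a cell
is either attached to a parent (Gaussian offspring) or placed uniformly.  A
symmetric ``interaction_strength`` matrix modulates this: a positive diagonal
entry makes a type clump with itself, a positive off-diagonal entry makes the
two types share cluster seeds (attraction), and a negative entry thins cells
of one type out of the other's vicinity (avoidance).  With the matrix at zero
positions are uniform and independent of the labels, so contact graphs show
random mixing.

Expression model
----------------
Marker counts are negative-binomial per (type, channel) with a log-normal
per-cell size factor; channel spillover is applied as ``observed = true @ S``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .preprocessing import SpilloverMatrix

__all__ = [
    "DEFAULT_STAGES",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_STATE_MARKERS",
    "SimConfig",
    "SyntheticDataset",
    "default_composition",
    "default_marker_means",
    "generate_dataset",
    "generate_marker_image",
    "generate_variants",
]

DEFAULT_STAGES: tuple[str, ...] = (
    "normal", "hyperplasia", "E-Adenoma", "L-Adenoma", "IAC",
)

# 15 named types of 4 major categories plus "other_lymphoid" and
# "unclassified" to reach the 17-type roster; fully configurable.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    # epithelial
    "neoplastic_epithelial", "at2_like_neoplastic", "at1_like_epithelial", "at2_like_epithelial",
    # lymphoid
    "cd4_t", "cd8_t", "treg", "b_cell", "other_lymphoid",
    # myeloid
    "macrophage", "mdsc", "dendritic", "neutrophil",
    # stromal
    "endothelial", "fibroblast", "smooth_muscle",
    "unclassified",
)

DEFAULT_STATE_MARKERS: tuple[str, ...] = (
    "CD44", "ECAD", "ICOS", "PDL1", "CTLA4", "TIM3", "GranzymeB",
    "CD25", "iNOS", "CD127", "Ki67", "CD21", "CD206",
)

# stage trajectories (normal -> IAC) for the default composition; rows are
# normalized to probabilities in default_composition()
_DEFAULT_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "at1_like_epithelial":    (0.20, 0.12, 0.07, 0.04, 0.02),
    "at2_like_epithelial":    (0.30, 0.20, 0.12, 0.06, 0.03),
    "neoplastic_epithelial":  (0.01, 0.06, 0.12, 0.18, 0.22),
    "at2_like_neoplastic":    (0.02, 0.10, 0.18, 0.26, 0.31),
    "macrophage":             (0.06, 0.09, 0.11, 0.13, 0.15),
    "cd4_t":                  (0.03, 0.05, 0.06, 0.07, 0.08),
    "cd8_t":                  (0.02, 0.05, 0.06, 0.04, 0.02),
    "b_cell":                 (0.06, 0.05, 0.04, 0.03, 0.02),
    "treg":                   (0.005, 0.01, 0.02, 0.03, 0.04),
    "dendritic":              (0.005, 0.01, 0.015, 0.02, 0.025),
    "neutrophil":             (0.02, 0.02, 0.02, 0.02, 0.02),
    "mdsc":                   (0.01, 0.015, 0.02, 0.025, 0.03),
    "endothelial":            (0.08, 0.07, 0.06, 0.05, 0.05),
    "fibroblast":             (0.06, 0.07, 0.08, 0.09, 0.09),
    "smooth_muscle":          (0.02, 0.02, 0.02, 0.02, 0.02),
    "other_lymphoid":         (0.02, 0.015, 0.01, 0.01, 0.01),
    "unclassified":           (0.02, 0.02, 0.02, 0.02, 0.02),
}

# markers elevated per type in the default expression model
_DEFAULT_HIGH_MARKERS: dict[str, tuple[str, ...]] = {
    "treg": ("CD25", "CTLA4", "ICOS"),
    "cd8_t": ("GranzymeB", "CD44"),
    "cd4_t": ("CD127", "ICOS"),
    "b_cell": ("CD21",),
    "macrophage": ("CD206", "iNOS"),
    "dendritic": ("TIM3",),
    "neoplastic_epithelial": ("ECAD", "Ki67", "PDL1"),
    "at2_like_neoplastic": ("ECAD", "Ki67"),
    "at1_like_epithelial": ("ECAD",),
    "at2_like_epithelial": ("ECAD",),
}

# morphology priors: mean cell area (µm²) per major compartment
_AREA_MEANS = {
    "neoplastic_epithelial": 130.0, "at2_like_neoplastic": 120.0,
    "at1_like_epithelial": 110.0, "at2_like_epithelial": 100.0,
    "endothelial": 90.0, "fibroblast": 95.0, "smooth_muscle": 100.0,
    "macrophage": 85.0,
}
_AREA_DEFAULT = 55.0


def default_composition(
    stages=DEFAULT_STAGES, cell_types=DEFAULT_CELL_TYPES
) -> pd.DataFrame:
    """Stage x type composition table (rows sum to 1).

    For the default roster the table encodes the canonical LUAD progression:
    normal alveolar epithelium gives way to neoplastic epithelium, macrophages
    and CD4 T cells rise steadily, CD8 T cells peak at the precursor stages
    then contract, and B cells decline.  For non-default rosters types are
    given flat trajectories.
    """
    n_stage = len(stages)
    rows = []
    for t in cell_types:
        traj = _DEFAULT_TRAJECTORIES.get(t)
        if traj is None or len(traj) != n_stage:
            traj = tuple([1.0 / len(cell_types)] * n_stage)
        rows.append(traj)
    comp = pd.DataFrame(np.array(rows).T, index=list(stages), columns=list(cell_types))
    return comp.div(comp.sum(axis=1), axis=0)


def default_marker_means(
    cell_types=DEFAULT_CELL_TYPES, channels=DEFAULT_STATE_MARKERS,
    baseline: float = 0.5, high: float = 15.0,
) -> pd.DataFrame:
    """Type x channel negative-binomial mean table for the default panel."""
    M = pd.DataFrame(baseline, index=list(cell_types), columns=list(channels))
    for t, markers in _DEFAULT_HIGH_MARKERS.items():
        if t not in M.index:
            continue
        for m in markers:
            if m in M.columns:
                M.loc[t, m] = high
    return M


@dataclass
class SimConfig:
    """Full parameterisation of a synthetic staged dataset.

    Parameters
    ----------
    n_rois_per_stage : int
        ROIs generated for each stage.
    stages : ordered stage labels.
    cell_types : ordered type roster (default 17 types).
    composition_by_stage : DataFrame (stage x type), rows summing to 1.
    interaction_strength : DataFrame (type x type), symmetric.  Positive =
        attraction, negative = avoidance, zero = spatial independence.
    roi_area_um2 : ROI area in µm² (square ROIs).
    cells_per_roi : expected cell count per ROI.
    marker_means / marker_dispersion : negative-binomial expression model.
    spillover : channel spillover applied to the clean expression
        (``observed = true @ S``); ``None`` means no spillover.
    seed : root seed for all randomness.
    """

    n_rois_per_stage: int = 25
    stages: tuple[str, ...] = DEFAULT_STAGES
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    composition_by_stage: pd.DataFrame | None = None
    interaction_strength: pd.DataFrame | None = None
    roi_area_um2: float = 1_000_000.0  # 1000 µm x 1000 µm
    cells_per_roi: int = 500
    marker_means: pd.DataFrame | None = None
    marker_dispersion: float = 3.0
    spillover: SpilloverMatrix | None = None
    cluster_sigma_um: float = 40.0
    model: str = "U"
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.cell_types = tuple(self.cell_types)
        if self.composition_by_stage is None:
            self.composition_by_stage = default_composition(self.stages, self.cell_types)
        if self.interaction_strength is None:
            self.interaction_strength = pd.DataFrame(
                0.0, index=list(self.cell_types), columns=list(self.cell_types)
            )
        if self.marker_means is None:
            self.marker_means = default_marker_means(self.cell_types)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.marker_means.columns)

    def validate(self) -> None:
        comp = self.composition_by_stage
        if list(comp.index) != list(self.stages):
            raise ValueError("composition_by_stage rows must match stages in order")
        if list(comp.columns) != list(self.cell_types):
            raise ValueError("composition_by_stage columns must match cell_types in order")
        sums = comp.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = [s for s, v in zip(self.stages, sums) if abs(v - 1) > 1e-9]
            raise ValueError(f"composition rows must sum to 1; offending stages: {bad}")
        if (comp.to_numpy() < 0).any():
            raise ValueError("composition probabilities must be nonnegative")
        W = self.interaction_strength.to_numpy(dtype=float)
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("interaction_strength must be symmetric")
        if self.roi_area_um2 <= 0:
            raise ValueError("roi_area_um2 must be > 0")
        if self.cells_per_roi <= 0:
            raise ValueError("cells_per_roi must be > 0")
        if self.n_rois_per_stage <= 0:
            raise ValueError("n_rois_per_stage must be > 0")
        if self.spillover is not None and tuple(self.spillover.channels) != self.channels:
            raise ValueError("spillover channels must match marker_means columns")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = {
            "n_rois_per_stage": self.n_rois_per_stage,
            "stages": list(self.stages),
            "cell_types": list(self.cell_types),
            "composition_by_stage": {
                s: [float(v) for v in self.composition_by_stage.loc[s]] for s in self.stages
            },
            "interaction_strength": {
                t: [float(v) for v in self.interaction_strength.loc[t]] for t in self.cell_types
            },
            "roi_area_um2": float(self.roi_area_um2),
            "cells_per_roi": int(self.cells_per_roi),
            "channels": list(self.channels),
            "marker_means": {
                t: [float(v) for v in self.marker_means.loc[t]] for t in self.cell_types
            },
            "marker_dispersion": float(self.marker_dispersion),
            "cluster_sigma_um": float(self.cluster_sigma_um),
            "model": self.model,
            "seed": int(self.seed),
        }
        if self.spillover is not None:
            d["spillover"] = {
                "channels": list(self.spillover.channels),
                "S": self.spillover.S.tolist(),
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        stages = tuple(d["stages"])
        types = tuple(d["cell_types"])
        channels = d.get("channels", list(DEFAULT_STATE_MARKERS))
        sp = d.get("spillover")
        return cls(
            n_rois_per_stage=d["n_rois_per_stage"],
            stages=stages,
            cell_types=types,
            composition_by_stage=pd.DataFrame(
                [d["composition_by_stage"][s] for s in stages], index=list(stages), columns=list(types)
            ),
            interaction_strength=pd.DataFrame(
                [d["interaction_strength"][t] for t in types], index=list(types), columns=list(types)
            ),
            roi_area_um2=d["roi_area_um2"],
            cells_per_roi=d["cells_per_roi"],
            marker_means=pd.DataFrame(
                [d["marker_means"][t] for t in types], index=list(types), columns=channels
            ),
            marker_dispersion=d.get("marker_dispersion", 3.0),
            spillover=None if sp is None else SpilloverMatrix(tuple(sp["channels"]), np.array(sp["S"])),
            cluster_sigma_um=d.get("cluster_sigma_um", 40.0),
            model=d.get("model", "U"),
            seed=d.get("seed", 0),
        )


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    rois: pd.DataFrame          # roi_id, mouse_id, model, stage, region_class, area_um2
    cells: pd.DataFrame         # CellTable (see module docstring)
    variants: pd.DataFrame | None
    config: SimConfig
    realized_composition: pd.DataFrame  # roi_id x type fractions

    def cells_for_roi(self, roi_id: str) -> pd.DataFrame:
        return self.cells[self.cells["roi_id"] == roi_id]

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.rois.to_csv(out / "rois.csv", index=False)
        if self.variants is not None:
            self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "sim_config.yaml")
        self.realized_composition.to_csv(out / "realized_composition.csv")


# ---------------------------------------------------------------------------
# dataset generation


def _sample_positions(labels: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Two-pass parent/offspring placement modulated by interaction_strength."""
    side = float(np.sqrt(config.roi_area_um2))
    types = list(config.cell_types)
    tindex = {t: i for i, t in enumerate(types)}
    W = config.interaction_strength.to_numpy(dtype=float)
    n = len(labels)
    lab_idx = np.array([tindex[l] for l in labels])

    # parent points per type
    parents: list[np.ndarray] = []
    for i, t in enumerate(types):
        n_t = int((lab_idx == i).sum())
        n_par = max(1, int(np.ceil(n_t / 25)))
        parents.append(rng.uniform(0, side, size=(n_par, 2)))

    pos = rng.uniform(0, side, size=(n, 2))
    sigma = config.cluster_sigma_um
    Wpos = np.clip(W, 0.0, None)
    for i, t in enumerate(types):
        cells_i = np.nonzero(lab_idx == i)[0]
        if cells_i.size == 0:
            continue
        weights = Wpos[i]
        total = weights.sum()
        if total <= 0:
            continue
        p_cluster = 1.0 - np.exp(-total)
        clustered = cells_i[rng.random(cells_i.size) < p_cluster]
        if clustered.size == 0:
            continue
        src_types = rng.choice(len(types), size=clustered.size, p=weights / total)
        for s in np.unique(src_types):
            idx = clustered[src_types == s]
            # attraction between two types means sharing one seed pool, so
            # the pair (i, s) canonically uses the lower-indexed type's parents
            pool = parents[min(i, s)]
            par = pool[rng.integers(0, len(pool), size=idx.size)]
            pos[idx] = par + rng.normal(0.0, sigma, size=(idx.size, 2))
    np.clip(pos, 0.0, side, out=pos)

    # avoidance: thin cells of type t out of the vicinity of type s
    neg_pairs = [(i, j) for i in range(len(types)) for j in range(len(types)) if W[i, j] < 0 and i <= j]
    if neg_pairs:
        from scipy.spatial import cKDTree

        r_avoid = 2.0 * sigma
        for _ in range(2):
            for i, j in neg_pairs:
                p_move = 1.0 - np.exp(W[i, j])  # |W| -> probability
                for a, b in ((i, j), (j, i)) if i != j else ((i, j),):
                    src = np.nonzero(lab_idx == a)[0]
                    tgt = np.nonzero(lab_idx == b)[0]
                    if src.size == 0 or tgt.size == 0:
                        continue
                    tree = cKDTree(pos[src])
                    near = tree.query_ball_point(pos[tgt], r_avoid)
                    close = np.array([len(nb) > 0 for nb in near])
                    move = tgt[close & (rng.random(tgt.size) < p_move)]
                    pos[move] = rng.uniform(0, side, size=(move.size, 2))
    return pos


def _sample_morphology(labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(labels)
    area_mean = np.array([_AREA_MEANS.get(t, _AREA_DEFAULT) for t in labels])
    area = area_mean * np.exp(rng.normal(0.0, 0.25, n) - 0.25**2 / 2)
    ecc = rng.beta(2.5, 2.5, n)
    # area = pi/4 * major * minor, minor/major = sqrt(1 - ecc^2)
    ratio = np.sqrt(1.0 - ecc**2)
    major = np.sqrt(4.0 * area / (np.pi * ratio))
    minor = major * ratio
    return pd.DataFrame(
        {"area_um2": area, "eccentricity": ecc, "major_axis_um": major, "minor_axis_um": minor}
    )


def _sample_expression(labels: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with a log-normal per-cell size factor."""
    M = config.marker_means.loc[list(labels)].to_numpy(dtype=float)
    size = np.exp(rng.normal(0.0, 0.3, size=(len(labels), 1)) - 0.3**2 / 2)
    mu = M * size
    r = config.marker_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam).astype(float)


def generate_dataset(config: SimConfig, with_variants: bool = False) -> SyntheticDataset:
    """Generate a full staged multi-ROI dataset from ``config``.

    Deterministic given ``config.seed``; each ROI draws from its own named
    substream, so regenerating a subset of ROIs reproduces the full run.
    """
    config.validate()
    roi_rows = []
    cell_frames = []
    realized = []
    channels = list(config.channels)
    S = config.spillover.S if config.spillover is not None else None
    cell_counter = 0
    for s_idx, stage in enumerate(config.stages):
        p = config.composition_by_stage.loc[stage].to_numpy(dtype=float)
        for r in range(config.n_rois_per_stage):
            roi_id = f"{config.model}_{stage}_{r:03d}"
            rng = substream(config.seed, "roi", roi_id)
            n = config.cells_per_roi
            lab_idx = rng.choice(len(config.cell_types), size=n, p=p)
            labels = np.array(config.cell_types, dtype=object)[lab_idx]
            pos = _sample_positions(labels, config, rng)
            morph = _sample_morphology(labels, rng)
            expr = _sample_expression(labels, config, rng)
            if S is not None:
                expr = expr @ S
            cell_ids = np.arange(cell_counter, cell_counter + n)
            cell_counter += n
            df = pd.DataFrame(
                {
                    "cell_id": cell_ids,
                    "roi_id": roi_id,
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "cell_type": labels,
                }
            )
            df = pd.concat([df, morph, pd.DataFrame(expr, columns=channels)], axis=1)
            cell_frames.append(df)
            roi_rows.append(
                {
                    "roi_id": roi_id,
                    "mouse_id": f"mouse_{r % 4:02d}",
                    "model": config.model,
                    "stage": stage,
                    "stage_index": s_idx,
                    "region_class": "lesion" if stage != "normal" else "normal",
                    "area_um2": config.roi_area_um2,
                }
            )
            frac = pd.Series(0.0, index=list(config.cell_types), name=roi_id)
            vc = pd.Series(labels).value_counts(normalize=True)
            frac.loc[vc.index] = vc.to_numpy()
            realized.append(frac)

    cells = pd.concat(cell_frames, ignore_index=True)
    rois = pd.DataFrame(roi_rows)
    realized_df = pd.DataFrame(realized)
    realized_df.index.name = "roi_id"

    variants = None
    if with_variants:
        variants = generate_variants(
            n_samples=len(rois), n_variants_per_sample=50,
            spectrum=None, scheme="96", seed=config.seed,
            sample_ids=list(rois["roi_id"]),
        )
    return SyntheticDataset(
        rois=rois, cells=cells, variants=variants, config=config, realized_composition=realized_df
    )


# ---------------------------------------------------------------------------
# marker images


def generate_marker_image(
    cells_roi: pd.DataFrame,
    channels,
    image_size_px: int,
    um_per_px: float = 1.0,
    hot_pixel_rate: float = 0.0,
    aggregate_sizes_px: tuple[int, ...] = (),
    aggregate_intensity: float = 500.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a multichannel integer image plus label mask for one ROI.

    Each cell is drawn as a disk with its morphological area; its expression
    is spread uniformly over the footprint.  Acquisition artifacts are then
    injected: isolated hot pixels at ``hot_pixel_rate`` per pixel, and bright
    connected components ("antibody aggregates") of the requested pixel
    sizes.  The mask labels pixels with ``cell_id + 1`` (0 = background).

    Returns ``(image, mask)`` with image shape ``(C, H, W)``.
    """
    rng = substream(seed, "marker_image")
    H = W = int(image_size_px)
    channels = list(channels)
    img = np.zeros((len(channels), H, W), dtype=float)
    mask = np.zeros((H, W), dtype=np.int64)

    yy, xx = np.mgrid[0:H, 0:W]
    for _, row in cells_roi.iterrows():
        cx, cy = row["x_um"] / um_per_px, row["y_um"] / um_per_px
        if not (0 <= cx < W and 0 <= cy < H):
            raise ValueError(f"cell {row['cell_id']} lies outside the image bounds")
        radius = max(1.0, np.sqrt(row["area_um2"] / np.pi) / um_per_px)
        y0, y1 = int(max(0, cy - radius - 1)), int(min(H, cy + radius + 2))
        x0, x1 = int(max(0, cx - radius - 1)), int(min(W, cx + radius + 2))
        disk = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= radius**2
        npx = int(disk.sum())
        if npx == 0:
            continue
        mask[y0:y1, x0:x1][disk] = int(row["cell_id"]) + 1
        for c, ch in enumerate(channels):
            img[c, y0:y1, x0:x1][disk] += float(row[ch]) / npx

    img = np.rint(img)

    if hot_pixel_rate > 0:
        n_hot = rng.binomial(H * W, hot_pixel_rate, size=len(channels))
        for c in range(len(channels)):
            idx = rng.choice(H * W, size=n_hot[c], replace=False)
            flat = img[c].ravel()
            flat[idx] = max(100.0, 20.0 * (flat.max() + 1))

    for size in aggregate_sizes_px:
        if size > H * W:
            raise ValueError(f"aggregate size {size} exceeds the image extent")
        c = int(rng.integers(0, len(channels)))
        # grow a random connected component of exactly `size` pixels
        start = (int(rng.integers(0, H)), int(rng.integers(0, W)))
        comp = {start}
        frontier = [start]
        while len(comp) < size and frontier:
            y, x = frontier[int(rng.integers(0, len(frontier)))]
            nbrs = [(y + dy, x + dx) for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))]
            nbrs = [p for p in nbrs if 0 <= p[0] < H and 0 <= p[1] < W and p not in comp]
            if not nbrs:
                frontier.remove((y, x))
                continue
            p = nbrs[int(rng.integers(0, len(nbrs)))]
            comp.add(p)
            frontier.append(p)
        for y, x in comp:
            img[c, y, x] = aggregate_intensity

    return img, mask


def write_marker_image(path, image: np.ndarray) -> None:
    """Write a (C, H, W) multichannel image (or a 2-D mask) as TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image))


def read_marker_image(path) -> np.ndarray:
    """Read a multichannel TIFF written by :func:`write_marker_image`."""
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# variants

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _channel_to_variant(channel: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """Return (ref, alt, context) realizing the given spectrum channel."""
    if ">" in channel and "[" not in channel:  # 12-class, e.g. "A>G"
        ref, alt = channel.split(">")
        five, three = rng.choice(list(_BASES)), rng.choice(list(_BASES))
        ref, alt, context = ref, alt, five + ref + three
    else:  # 96-class, e.g. "A[C>T]A"
        five, rest = channel[0], channel[2:]
        ref, alt = rest[0], rest[2]
        three = channel[-1]
        context = five + ref + three
    # emit half the rows on the opposite strand to exercise strand collapse
    if rng.random() < 0.5 and "[" in channel:
        ref, alt = _COMP[ref], _COMP[alt]
        context = "".join(_COMP[b] for b in reversed(context))
    return ref, alt, context


def generate_variants(
    n_samples: int,
    n_variants_per_sample: int,
    spectrum: np.ndarray | None,
    scheme: str = "96",
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Generate a variant table whose substitution spectrum is known.

    ``spectrum`` is a probability vector over the channels of the chosen
    scheme ("12" or "96"); ``None`` means uniform.  Counts per channel are
    multinomial.  For the 96-class scheme half the rows are emitted in
    purine-strand notation so that classification must collapse strands.
    """
    from .spectrum import channel_names

    channels = channel_names(scheme)
    k = len(channels)
    if spectrum is None:
        spectrum = np.full(k, 1.0 / k)
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (k,):
        raise ValueError(f"spectrum must have length {k} for the {scheme}-class scheme")
    if not np.isclose(spectrum.sum(), 1.0, atol=1e-9):
        raise ValueError("spectrum must sum to 1")

    if sample_ids is None:
        sample_ids = [f"sample_{i:03d}" for i in range(n_samples)]
    rng = substream(seed, "variants")
    rows = []
    for sid in sample_ids:
        counts = rng.multinomial(n_variants_per_sample, spectrum)
        pos = 1
        for ch_i in np.nonzero(counts)[0]:
            for _ in range(int(counts[ch_i])):
                ref, alt, context = _channel_to_variant(channels[ch_i], rng)
                rows.append(
                    {
                        "SAMPLE": sid,
                        "CHROM": f"chr{int(rng.integers(1, 20))}",
                        "POS": pos,
                        "REF": ref,
                        "ALT": alt,
                        "CONTEXT": context,
                    }
                )
                pos += int(rng.integers(100, 10_000))
    df = pd.DataFrame(rows, columns=["SAMPLE", "CHROM", "POS", "REF", "ALT", "CONTEXT"])
    # shuffle row order deterministically so channel order carries no signal
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True)
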