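"""The ROI-level TME feature catalog and gene-signature scoring.

Four feature categories are extracted per ROI for a declared set of included
cell types (T types, M state markers):

* **composition** (2T): per-type proportion of total cells, and density in
  cells/mm² of ROI area;
* **morphology** (4T): per-type mean cell area (µm²), eccentricity, and
  major/minor axis lengths (µm);
* **state** (MT): per-type mean expression of each functional marker;
* **interaction** (T²): the ordered pair's contact-enrichment z-score.

With the default 16 included types and 13 state markers the catalog has
32 + 64 + 208 + 256 = 560 features.  (A 17th, unclassifiable type exists in
the clustering roster but is excluded from the feature catalog by default;
the category sizes are only consistent with 16.)

The same operations applied to cellular-neighborhood (CN) labels instead of
cell-type labels yield the CN-level analogue of each category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "MORPHOLOGY_METRICS",
    "FeatureCatalog",
    "build_catalog",
    "extract_features",
    "features_long",
    "score_signature",
    "CYTOTOXICITY_GENES",
    "EXHAUSTION_GENES",
]

CATEGORIES = ("composition", "morphology", "state", "interaction")
MORPHOLOGY_METRICS = ("area_um2", "eccentricity", "major_axis_um", "minor_axis_um")

# established T-cell functional gene lists used for signature scoring
CYTOTOXICITY_GENES = (
    "Gzmb", "Gzma", "Prf1", "Fasl", "Ifng", "Tnf", "Nkg7", "Cd107a", "Lamp1",
    "Ccl5", "Cd69", "Cxcr3", "Il2rb", "Tbx21", "Eomes", "Runx3", "Prdm1",
    "Gzmk", "Ccl4", "Cd2",
)
EXHAUSTION_GENES = (
    "Pdcd1", "Ctla4", "Lag3", "Tigit", "Havcr2", "Cd244", "Tox", "Tox2",
    "Eomes", "Nr4a1", "Nr4a2", "Nr4a3", "Batf", "Id2", "Id3", "Cxcr5",
    "Prdm1", "Entpd1", "Cd160",
)


@dataclass(frozen=True)
class FeatureCatalog:
    """Declared ROI-feature catalog: ordered names with category labels."""

    included_types: tuple[str, ...]
    state_markers: tuple[str, ...]
    names: tuple[str, ...]
    category_of: dict[str, str]

    @property
    def category_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(CATEGORIES, 0)
        for c in self.category_of.values():
            sizes[c] += 1
        return sizes

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "included_types": list(self.included_types),
                    "state_markers": list(self.state_markers),
                    "features": [
                        {"name": n, "category": self.category_of[n]} for n in self.names
                    ],
                },
                fh,
                indent=1,
            )


def build_catalog(included_types, state_markers, categories=CATEGORIES) -> FeatureCatalog:
    """Enumerate the feature catalog for the given types and markers.

    Category sizes are 2T (composition), 4T (morphology), MT (state) and T²
    (interaction); names are stable: ``composition/<type>/proportion``,
    ``morphology/<type>/<metric>``, ``state/<type>/<marker>``,
    ``interaction/<a>-><b>``.  ``categories`` restricts the catalog to a
    subset of the four categories (default: all).
    """
    included_types = tuple(included_types)
    state_markers = tuple(state_markers)
    if not included_types or not state_markers:
        raise ValueError("type and marker lists must be nonempty")
    if len(set(included_types)) != len(included_types):
        raise ValueError("duplicate cell types in catalog")
    if len(set(state_markers)) != len(state_markers):
        raise ValueError("duplicate state markers in catalog")

    names: list[str] = []
    category: dict[str, str] = {}

    def add(name: str, cat: str) -> None:
        if name in category:
            raise ValueError(f"duplicate feature name {name!r}")
        names.append(name)
        category[name] = cat

    categories = tuple(categories)
    if "composition" in categories:
        for t in included_types:
            add(f"composition/{t}/proportion", "composition")
            add(f"composition/{t}/density", "composition")
    if "morphology" in categories:
        for t in included_types:
            for metric in MORPHOLOGY_METRICS:
                add(f"morphology/{t}/{metric}", "morphology")
    if "state" in categories:
        for t in included_types:
            for m in state_markers:
                add(f"state/{t}/{m}", "state")
    if "interaction" in categories:
        for a in included_types:
            for b in included_types:
                add(f"interaction/{a}->{b}", "interaction")

    return FeatureCatalog(
        included_types=included_types,
        state_markers=state_markers,
        names=tuple(names),
        category_of=category,
    )


def extract_features(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    enrichment: pd.DataFrame | None,
    catalog: FeatureCatalog,
    label_column: str = "cell_type",
    min_cells: int = 5,
) -> pd.DataFrame:
    """ROI x feature matrix against ``catalog``.

    proportion = type count / total cells in the ROI; density = type count /
    ROI area in cells/mm²; morphology and state = means over the type's
    cells; interaction = the ordered pair's permutation z from
    ``enrichment`` (long format over all ROIs).  Every ROI listed in
    ``rois`` must appear in ``enrichment`` if the catalog has interaction
    features.

    Per-type means (morphology and state) are missing-coded (NaN) when the
    ROI has fewer than ``min_cells`` cells of that type — a mean over a
    handful of cells is dominated by sampling noise and would otherwise
    leak that noise into every downstream comparison.  Absent types have
    proportion and density 0.
    """
    roi_ids = list(rois["roi_id"])
    areas = rois.set_index("roi_id")["area_um2"]
    need_interaction = any(c == "interaction" for c in catalog.category_of.values())
    z_lookup = {}
    if need_interaction:
        if enrichment is None:
            raise ValueError("catalog has interaction features but no enrichment was given")
        have = set(enrichment["roi_id"].unique())
        missing = [r for r in roi_ids if r not in have]
        if missing:
            raise ValueError(f"ROIs without enrichment results: {missing[:5]}")
        z_lookup = enrichment.set_index(["roi_id", "type_a", "type_b"])["z"]

    sizes = catalog.category_sizes
    types = catalog.included_types
    grouped = dict(tuple(cells.groupby("roi_id", sort=False)))
    rows = []
    for roi_id in roi_ids:
        sub = grouped.get(roi_id)
        if sub is None:
            raise ValueError(f"ROI {roi_id} has no cells")
        total = len(sub)
        area_mm2 = areas.loc[roi_id] / 1e6
        by_type = dict(tuple(sub.groupby(label_column, sort=False)))
        row: dict[str, float] = {}
        for t in types:
            grp = by_type.get(t)
            n_t = 0 if grp is None else len(grp)
            if sizes["composition"]:
                row[f"composition/{t}/proportion"] = n_t / total if total else 0.0
                row[f"composition/{t}/density"] = n_t / area_mm2
            enough = n_t >= max(1, min_cells)
            if sizes["morphology"]:
                for metric in MORPHOLOGY_METRICS:
                    row[f"morphology/{t}/{metric}"] = float(grp[metric].mean()) if enough else np.nan
            if sizes["state"]:
                for m in catalog.state_markers:
                    row[f"state/{t}/{m}"] = float(grp[m].mean()) if enough else np.nan
        if need_interaction:
            for a in types:
                for b in types:
                    row[f"interaction/{a}->{b}"] = float(z_lookup.get((roi_id, a, b), np.nan))
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(roi_ids, name="roi_id"), columns=list(catalog.names))


def features_long(matrix: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Tidy long form of a feature matrix (roi_id, feature, category, value)."""
    long = matrix.reset_index().melt(id_vars="roi_id", var_name="feature", value_name="value")
    long["category"] = long["feature"].map(catalog.category_of)
    return long[["roi_id", "feature", "category", "value"]]


def score_signature(expr: pd.DataFrame, genes) -> tuple[pd.Series, list[str]]:
    """Mean z-scored log1p expression of a gene list, per row.

    Listed genes absent from the matrix are dropped and returned; constant
    genes contribute a z of 0.  Raises if no listed gene is present.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.columns]
    dropped = [g for g in genes if g not in expr.columns]
    if not present:
        raise ValueError(f"none of the requested genes are in the matrix: {genes}")
    X = np.log1p(expr[present].to_numpy(dtype=float))
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    return pd.Series(Z.mean(axis=1), index=expr.index, name="score"), dropped
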