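"""End-to-end pipeline: simulate (or load) -> preprocess -> interactions ->
neighborhoods -> features -> transitions -> trajectory -> spectra.

A single YAML config drives the whole run.  One global seed fans out to
per-stage named substreams (see :mod:`tme_evolve._rng`), so a partial rerun
of any stage reproduces the corresponding slice of a full run, and rerunning
the same config yields byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import contacts, features, neighborhoods, spectrum, stage_stats, trajectory
from .preprocessing import SpilloverMatrix, compensate_spillover
from .synthetic import SimConfig, generate_dataset, generate_variants

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved pipeline parameters; every field has a usable default."""

    outdir: str = "tme_run"
    seed: int = 0
    simulate: bool = True
    cells_csv: str | None = None
    rois_csv: str | None = None
    variants_tsv: str | None = None
    spillover_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    max_edge_um: float = 50.0
    n_perm: int = 300
    alpha: float = 0.05
    window_size: int = 10
    k_neighborhoods: int = 10
    batch_size: int = 100
    random_state: int = 0
    excluded_types: tuple[str, ...] = ("unclassified",)
    min_frac: float = 0.25
    adjust: str = "fdr_bh"
    k_feature_groups: int = 5
    n_components: int = 10
    k_clusters: int = 8
    spectrum_scheme: str = "96"

    def validate(self) -> None:
        if self.k_clusters < 2:
            raise ValueError("k_clusters must be >= 2 (trajectory)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not self.simulate:
            for key in ("cells_csv", "rois_csv"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ValueError(f"{key} must point to an existing file when simulate=false")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim_d = d.pop("sim", {})
        sim = SimConfig(**sim_d) if sim_d else SimConfig()
        known = {f for f in cls.__dataclass_fields__ if f != "sim"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(sim=sim, **d)
        cfg.sim.seed = cfg.seed
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the run report dict.

    All artifacts are written under ``config.outdir`` with stable names;
    the report itself is written as ``run_report.json``.
    """
    config.validate()
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "warnings": []}

    def stage_report(name, **kw):
        report["stages"][name] = kw
        logger.info("stage %s: %s", name, kw)

    # ---- input ---------------------------------------------------------
    if config.simulate:
        config.sim.seed = config.seed
        ds = generate_dataset(config.sim)
        cells, rois = ds.cells, ds.rois
        variants = generate_variants(
            n_samples=min(12, len(rois)), n_variants_per_sample=200,
            spectrum=None, scheme=config.spectrum_scheme, seed=config.seed,
        )
        spill = config.sim.spillover
        ds.write(out / "simulated")
    else:
        cells = pd.read_csv(config.cells_csv)
        rois = pd.read_csv(config.rois_csv)
        variants = (
            spectrum.read_variants(config.variants_tsv) if config.variants_tsv else None
        )
        spill = (
            SpilloverMatrix.from_csv(config.spillover_csv) if config.spillover_csv else None
        )
    channels = [c for c in cells.columns if c not in (
        "cell_id", "roi_id", "x_um", "y_um", "cell_type",
        "area_um2", "eccentricity", "major_axis_um", "minor_axis_um")]
    stage_report("input", n_cells=len(cells), n_rois=len(rois), n_channels=len(channels))

    # ---- preprocessing -------------------------------------------------
    if spill is not None:
        comp = compensate_spillover(cells[channels], spill)
        cells = cells.copy()
        cells[channels] = comp
        stage_report("preprocess", compensated=True, n_channels=len(channels))
    else:
        stage_report("preprocess", compensated=False, n_channels=len(channels))
    cells.to_csv(out / "cells_preprocessed.csv", index=False)

    # ---- contact interactions ------------------------------------------
    all_types = sorted(cells["cell_type"].unique())
    enr_tables, mixing_rows = [], []
    for roi_id, sub in cells.groupby("roi_id", sort=True):
        graph = contacts.build_contact_graph(sub, max_edge_um=config.max_edge_um)
        mm = contacts.mixing_and_assortativity(graph, sub["cell_type"].to_numpy(), types=all_types)
        mixing_rows.append({"roi_id": roi_id, "assortativity": mm.r,
                            "n_edges": graph.n_edges, "degenerate": mm.degenerate})
        enr_tables.append(contacts.permutation_enrichment(
            graph, sub["cell_type"].to_numpy(), n_perm=config.n_perm,
            seed=config.seed, alpha=config.alpha, types=all_types))
    enrichment = pd.concat(enr_tables, ignore_index=True)
    enrichment.to_csv(out / "enrichment.csv", index=False)
    pd.DataFrame(mixing_rows).to_csv(out / "assortativity.csv", index=False)
    stage_report("interactions", n_rois=len(mixing_rows), n_perm=config.n_perm)

    # ---- neighborhoods -------------------------------------------------
    wins = []
    for roi_id, sub in cells.groupby("roi_id", sort=True):
        w = neighborhoods.window_vectors(sub, n=config.window_size, types=all_types)
        if w is not None:
            wins.append(w)
    windows = pd.concat(wins)
    model = neighborhoods.fit_neighborhoods(
        windows, k=config.k_neighborhoods,
        batch_size=config.batch_size, random_state=config.random_state)
    prev = neighborhoods.prevalence_and_dichotomize(
        model, cells.set_index("cell_id")["roi_id"])
    prev.prevalence.to_csv(out / "cn_prevalence.csv")
    model.assignment.rename_axis("cell_id").to_csv(out / "cn_assignment.csv")
    stage_report("neighborhoods", k=config.k_neighborhoods, n_windows=len(windows))

    # ---- features ------------------------------------------------------
    included = [t for t in all_types if t not in set(config.excluded_types)]
    markers = [m for m in channels]
    catalog = features.build_catalog(included, markers)
    fm = features.extract_features(cells, rois, enrichment, catalog)
    fm.to_csv(out / "features_wide.csv")
    features.features_long(fm, catalog).to_csv(out / "features_long.csv", index=False)
    catalog.to_json(out / "feature_catalog.json")
    sizes = catalog.category_sizes
    stage_report("features", catalog_size=len(catalog), **sizes)

    # ---- stage transitions ---------------------------------------------
    stages = rois.set_index("roi_id")["stage"]
    stage_order = list(config.sim.stages) if config.simulate else list(pd.unique(stages))
    contribs = []
    for a, b in zip(stage_order[:-1], stage_order[1:]):
        try:
            res = stage_stats.transition_de(
                fm, stages, (a, b), min_frac=config.min_frac, adjust=config.adjust)
        except ValueError as err:
            report["warnings"].append(f"transition {a}->{b}: {err}")
            continue
        res.table.to_csv(out / f"transition_{a}_to_{b}.csv", index=False)
        c = stage_stats.category_contribution(res, catalog)
        contribs.append(pd.DataFrame(
            {"transition": f"{a}->{b}", "category": c.index, "fraction": c.to_numpy()}
        ))
    if contribs:
        pd.concat(contribs, ignore_index=True).to_csv(
            out / "category_contributions.csv", index=False)
    stage_means = fm.groupby(stages).mean().reindex(stage_order).T.dropna(how="any")
    groups = stage_stats.cluster_feature_profiles(
        stage_means, k=min(config.k_feature_groups, max(1, len(stage_means))), seed=config.seed)
    groups.rename_axis("feature").to_csv(out / "feature_groups.csv")
    stage_report("transitions", n_transitions=len(contribs))

    # ---- trajectory ----------------------------------------------------
    traj = trajectory.fit_trajectory(
        fm, stages, n_components=config.n_components,
        k_clusters=min(config.k_clusters, len(fm)), seed=config.seed,
        root_stage=stage_order[0])
    traj.to_frame().to_csv(out / "trajectory.csv")
    with open(out / "trajectory_graph.json", "w") as fh:
        json.dump({"root_cluster": traj.root_cluster,
                   "edges": [list(e) for e in traj.graph_edges]}, fh)
    rho = trajectory.stage_ordering_score(traj, stages, stage_order=stage_order)
    stage_report("trajectory", spearman_rho_vs_stage=round(rho, 4))

    # ---- spectra -------------------------------------------------------
    if variants is not None and len(variants):
        spec = spectrum.spectrum_matrix(variants, scheme=config.spectrum_scheme)
        spec.counts.to_csv(out / "spectrum_counts.csv")
        spec.proportions.to_csv(out / "spectrum_proportions.csv")
        spec.pooled.rename("proportion").rename_axis("channel").to_csv(out / "spectrum_pooled.csv")
        stage_report("spectrum", scheme=config.spectrum_scheme,
                     n_variants=int(spec.counts.to_numpy().sum()),
                     n_channels=spec.counts.shape[1])

    report["elapsed_s"] = round(time.time() - t0, 2)
    report["seed"] = config.seed
    report["catalog_sizes"] = sizes
    report["catalog_total"] = len(catalog)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
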