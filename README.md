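# tme-evolve

Spatial single-cell analysis of tumor-microenvironment (TME) evolution across
the histological stages of mouse lung adenocarcinoma (LUAD): normal →
hyperplasia → early adenoma → late adenoma → invasive adenocarcinoma.

The package is aimed at analysts working with imaging-mass-cytometry (IMC)
style data — per-ROI segmented cell tables with positions, cell-type labels,
morphology, and multiplexed marker expression — who want to quantify how
cellular composition, morphology, functional state, and cell–cell
interactions change as lesions progress.  A synthetic-data generator with
known ground truth ships as a first-class module, so every stage of the
pipeline can be exercised and validated without any external download.

## What it computes

* **Spillover compensation** — per-cell expression rows are corrected for
  channel crosstalk by nonnegative least squares against a measured
  spillover matrix `S` (`observed = true · S`, diagonal 1): for each cell
  `x̂ = argmin_{x≥0} ‖xS − y‖²`.  Raw images can additionally be cleaned of
  hot pixels and small antibody aggregates.
* **Cell-contact interaction analysis** — physical contacts are modeled as
  the Delaunay triangulation of cell centroids pruned at a maximum edge
  length (default 50 µm).  Two enrichment statistics are reported: the
  global assortativity coefficient
  `r = (Σ_s e_ss − Σ_s a_s²) / (1 − Σ_s a_s²)` over the edge-type mixing
  matrix `e` (1 = contacts only within a type, 0 = random mixing, negative
  = cross-type preference), and per-pair permutation tests (labels shuffled
  within the ROI) giving a z-score, an add-one empirical p-value, and an
  interaction/avoidance direction.
* **Cellular neighborhoods (CNs)** — each cell is represented by the
  type-frequency vector of its *n* nearest cells (default n = 10), windows
  are clustered with mini-batch k-means (default k = 10, batch size 100,
  random state 0), and per-core CN prevalences are normalized to 1,
  z-scored per CN, and dichotomized at z ≥ 0.
* **TME feature catalog** — per ROI, four feature categories over T included
  types and M state markers: composition (2T: proportion, density in
  cells/mm²), morphology (4T: mean area, eccentricity, major/minor axes),
  state (MT: mean marker expression), and interaction (T²: enrichment
  z-scores).  The default 16 types × 13 markers gives 32/64/208/256 = 560
  features.
* **Stage-transition feature importance** — Wilcoxon rank-sum tests per
  feature between adjacent stages (only features present in ≥ 25% of ROIs
  in both stages), Benjamini–Hochberg adjustment, and normalized importance
  `f_i = (−log p̄_i) / Σ_k (−log p̄_k)`; importances are summed per category
  to give category contributions, and per-stage feature profiles can be
  k-means-grouped into stage-enrichment patterns.
* **Feature-space pseudotime** — PCA (eigenvalue-weighted scores) → k-means
  → minimum spanning tree over centroids, rooted at the cluster richest in
  normal ROIs; each ROI's pseudotime is the geodesic arc length to its
  projection on the tree.  Validated by the Spearman correlation between
  pseudotime and the ordinal stage.
* **Mutation spectra** — variant tables (REF/ALT plus trinucleotide CONTEXT)
  summarized as 12-class literal `ref>alt` spectra or the 96-channel
  COSMIC-style pyrimidine-collapsed trinucleotide catalog.
* **Gene-signature scoring** — mean z-scored log1p expression of curated
  gene lists (T-cell cytotoxicity and exhaustion lists included).

## Worked example

```python
from tme_evolve import SimConfig, generate_dataset, build_catalog
from tme_evolve.features import extract_features
from tme_evolve.contacts import build_contact_graph, mixing_and_assortativity
from tme_evolve.stage_stats import transition_de, category_contribution
from tme_evolve.trajectory import fit_trajectory, stage_ordering_score

cfg = SimConfig(seed=1)                    # 5 stages x 25 ROIs x 500 cells
ds = generate_dataset(cfg)
print(f"{len(ds.cells):,} cells in {len(ds.rois)} ROIs")

roi = ds.rois["roi_id"].iloc[0]
sub = ds.cells_for_roi(roi)
g = build_contact_graph(sub, max_edge_um=50)
mm = mixing_and_assortativity(g, sub["cell_type"].to_numpy())
print(f"{roi}: {g.n_edges} contacts, assortativity r = {mm.r:.3f}")

types = [t for t in cfg.cell_types if t != "unclassified"]
cat = build_catalog(types, list(cfg.channels),
                    categories=("composition", "morphology", "state"))
fm = extract_features(ds.cells, ds.rois, None, cat)
stages = ds.rois.set_index("roi_id")["stage"]

res = transition_de(fm, stages, ("normal", "hyperplasia"))
print(category_contribution(res, cat).round(3).to_string())

traj = fit_trajectory(fm, stages, seed=1)
rho = stage_ordering_score(traj, stages, stage_order=list(cfg.stages))
print(f"pseudotime vs stage: Spearman rho = {rho:.3f}")
```

Output:

```
62,500 cells in 125 ROIs
U_normal_000: 790 contacts, assortativity r = 0.017
composition    0.824
morphology     0.052
state          0.123
interaction    0.000
pseudotime vs stage: Spearman rho = 0.969
```

Reading it: the normal-stage ROI mixes its cell types spatially at random
(r ≈ 0 — the default generator plants no attraction or avoidance); the
normal → hyperplasia transition is dominated by composition features
(82% of the importance mass), because the generator's stage trajectories
change only cell-type abundances; and the inferred pseudotime orders ROIs
almost perfectly by their true histological stage (rho 0.97).

The full pipeline (simulate-or-load → preprocess → interactions →
neighborhoods → features → transitions → trajectory → spectra) runs from a
single YAML config:

```bash
tme-evolve run --config run.yaml
```

with per-stage subcommands (`simulate`, `preprocess`, `interactions`,
`neighborhoods`, `features`, `transitions`, `trajectory`, `spectrum`) that
compose to the same outputs.

## Documentation

`docs/methods.md` describes the statistical model behind every stage, the
synthetic generator's assumptions, the defaults and why they were chosen,
and known limitations.
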