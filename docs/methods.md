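# Methods

This note documents the statistical procedures implemented in `tme_evolve`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generator does and does not emulate.

## Study design being modeled

The package targets staged spatial single-cell data from mouse lung
adenocarcinoma (LUAD) models: multiple regions of interest (ROIs) acquired
by imaging mass cytometry at ~1 µm resolution, each ROI assigned to one of
five histological stages (normal, hyperplasia, E-Adenoma, L-Adenoma, IAC)
and to one of two models (a Kras-driven genetic model "K" and a
urethane-induced carcinogen model "U").  The unit of feature extraction is
the ROI; cells carry a type label from a 17-type roster spanning four
compartments (epithelial, lymphoid, myeloid, stromal).

Because the full published datasets are large and external, all tests run
against the synthetic generator below, whose defaults mirror the study's
scale: 25 ROIs per stage (≈125 per model; the real study acquired 126 and
156 ROIs per model across the five stages) and 500 cells per ROI in a
1 mm² ROI.  Five hundred cells per ROI is a deliberate size reduction
(real ROIs carry a few thousand cells); it keeps binomial sampling noise
on composition features realistic while making full pipeline runs take
seconds.

## Synthetic-data generator

**Labels.**  Cell types are drawn i.i.d. per cell from the stage's
composition row, so realized per-stage compositions are multinomial around
the configured targets (recovery is tested at 3 binomial standard errors).
The default composition trajectories encode the canonical progression:
alveolar AT1/AT2 epithelium declining, neoplastic epithelium rising,
macrophages and CD4 T cells rising, CD8 T cells peaking at precursor
stages then contracting, B cells declining.

**Positions.**  A Neyman–Scott-style parent/offspring process: each type
owns uniformly placed parent points (one per ~25 cells), and a cell is
either Gaussian offspring of a parent (σ = 40 µm) or uniform.  The
symmetric `interaction_strength` matrix modulates placement: diagonal
entries control same-type clumping; a positive off-diagonal entry makes
the pair share one seed pool (attraction — the shared pool is canonically
the lower-indexed type's parents); negative entries thin one type out of
the other's 2σ vicinity over two rejection passes.  With the matrix at
zero, positions are uniform and independent of labels, so contact graphs
show random mixing (assortativity ≈ 0) — this is the null used for
calibration tests.  This is not a Gibbs point process; it trades
distributional realism for cheap, directly controllable ground truth.

**Expression.**  Negative-binomial counts per (type, channel) with
dispersion 3 and a log-normal per-cell size factor (σ = 0.3), multiplied
through the spillover matrix when one is configured.  The default panel is
the 13 functional state markers, with 1–3 markers elevated per type
(e.g. CD25/CTLA4/ICOS on Tregs, Granzyme-B on CD8 T cells).

**Morphology.**  Cell area is log-normal around a per-compartment mean
(epithelial ≈ 100–130 µm², immune ≈ 55 µm²), eccentricity is Beta(2.5, 2.5),
and the axis lengths are derived so that area = π·a·b/4 and
ecc = √(1 − (b/a)²) hold exactly.

**Artifacts.**  Marker images are rendered as integer-valued disks (one per
cell) with two injectable acquisition artifacts: isolated hot pixels at a
configurable per-pixel rate, and bright connected components of exact
pixel sizes emulating antibody aggregates.

**Variants.**  Substitutions are multinomial over a 12- or 96-channel
spectrum; each variant realizes its channel as (REF, ALT, trinucleotide
CONTEXT).  In the 96-class scheme half the rows are emitted in
purine-strand notation, so correct strand collapse is required to recover
the spectrum.

**Randomness.**  One root seed; every ROI and every generator component
draws from a named substream (`SeedSequence` over hashed keys), so
regenerating any subset reproduces the corresponding slice of a full run.

What the generator does **not** emulate: tissue architecture (vessels,
airways, lesion boundaries), segmentation errors, spatial marker gradients
within a type, batch/slide effects, and cell-density differences between
stages.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated sampling model, not robustness to real-tissue
artifacts.

## Spillover compensation

Channel crosstalk follows `observed = true · S` with `S[i, j]` the fraction
of channel *i* signal read in channel *j* (diagonal 1, off-diagonal in
[0, 1)); this row convention is written into the CSV header.  Compensation
solves per-row nonnegative least squares; the implementation first tries
the unconstrained linear solve and falls back to NNLS only for rows where
nonnegativity binds, which is exact and much faster on clean data.  The
routine does not assume diagonal dominance.  A helper estimates `S` from
single-stained controls by median ratio; it is a convenience, not a
validated estimation stage.  Whether compensation should run on pixels or
per-cell values is left to the caller: the same routine accepts either,
and the pipeline applies it to per-cell values.

Image cleaning: pixels above `hot_factor` (default 5) times their 3×3
neighborhood median are replaced by that median; connected components above
the 99.9th intensity percentile with at most `agg_max_px` (default 25)
pixels are set to the local background, estimated as the neighborhood
median after masking bright pixels so an aggregate cannot dominate its own
estimate.  No pixel is ever increased.  The thresholds are configuration
keys; the defaults are editorial choices, not published values.  The 3×3
hot filter will also clip isolated corners of genuine small structures —
it is a spike filter, not a structure-aware denoiser.

## Contact graphs and interaction enrichment

Contacts are Delaunay edges between cell centroids with length ≤ 50 µm
(default; configurable).  Delaunay adapts to local density, which matters
because nucleus-to-nucleus distances vary with cell size and crowding; the
pruning threshold removes spurious long edges across empty space.

Two complementary enrichment readouts are computed, since raw contact
frequencies confound preference with abundance:

1. **Assortativity.**  With `e[s, t]` the fraction of edge endpoints
   joining types s and t (symmetrized, summing to 1) and `a` its marginals,
   `r = (Σ e_ss − Σ a_s²)/(1 − Σ a_s²)`.  The single-type degenerate case
   (denominator 0) is reported as r = 1 with an explicit flag.
2. **Permutation tests.**  Type labels are permuted uniformly within the
   ROI (preserving counts, density, and the graph); per ordered pair the
   observed contact count is compared with the permutation distribution:
   `z = (obs − mean)/sd` (0 if sd = 0) and the add-one empirical p-value
   `p = (1 + #{perm as-or-more-extreme in the observed direction})/(B + 1)`.
   Permutations default to B = 1,000 within-ROI; an exhaustive mode
   enumerates all distinct labelings for small ROIs.

Because the direction (interaction vs avoidance) is chosen by the data, the
one-sided `p` is compared against α/2 when flagging significance at a
two-sided level α — otherwise the false-positive rate would double.
Permutation counts are heavily tied on small graphs, which makes the
add-one p-value conservative and *non*-uniform under the null; for
calibration diagnostics the module can also emit the randomized
(tie-broken), fixed-tail p-value, which is exactly Uniform(0, 1) under
exchangeability.  The calibration acceptance test uses the randomized
p-values for the uniformity check and the reported significance flags for
the false-positive-rate check.

Group comparison (e.g. carcinogen vs genetic model at a matched stage)
applies a two-tailed two-sample t test to the per-ROI z-scores of each
pair, stratified by stage; pairs with fewer than two ROIs in either group
are flagged not-testable rather than dropped silently.

## Cellular neighborhoods

Window capturing: each cell's window is the type-frequency vector of its
n nearest cells by Euclidean distance (default n = 10, self excluded;
both are configuration keys and the values are editorial, as is k = 10).
Distance ties are broken by cell id, and windows are computed from a full
pairwise distance matrix per ROI — exact and fast at ROI scale, and it
makes the tie-break deterministic under row reordering.  Pooled windows
are clustered with mini-batch k-means (batch size 100, random state 0 —
published settings).  Per-core prevalences are row-normalized to 1,
z-scored per CN across cores (zero-variance CNs flagged and given z = 0),
and dichotomized at z ≥ 0.  The downstream use of the high/low split is
stage-group comparison; the original survival-endpoint comparison has no
analogue in a mouse staging design.

## Feature catalog

For T included types and M state markers the catalog is
2T (composition) + 4T (morphology) + MT (state) + T² (interaction).
The default roster has 17 types but the catalog includes 16 — the
unclassifiable type is excluded — because 32/64/208/256 (total 560) is
only consistent with T = 16, M = 13.  Both lists are configurable, and the
identity holds for any T, M.  Densities are cells/mm² so that
density × area recovers the integer count exactly.  Per-type morphology
and state means require at least `min_cells = 5` cells of the type in the
ROI; below that they are missing-coded, since a mean over a handful of
cells is sampling noise that would otherwise contaminate PCA, DE testing,
and clustering.  (Composition features are always defined; absent types
get 0.)  The same extraction can be run over CN labels instead of type
labels via `label_column`, yielding the CN-level analogue of every
category with sizes depending on k.

Signature scores are the mean over present genes of per-gene z-scored
log1p expression; genes absent from the matrix are dropped and reported,
and constant genes contribute 0.  The method is deliberately transparent
rather than a bin-matched control-gene scheme; scores are comparable only
within a matrix.

## Stage-transition testing and importance

For each adjacent stage pair, features present (nonzero and nonmissing by
default; a switch accepts nonmissing-only) in at least 25% of ROIs of both
stages are tested with the two-sided Wilcoxon rank-sum test, and adjusted
p-values (Benjamini–Hochberg by default, Bonferroni available) are
converted to importances `f_i = (−log p̄_i)/Σ_k(−log p̄_k)`.  The printed
form of this formula yields negative values if read literally; the
implementation uses the evident intent — nonnegative weights summing to 1,
monotone decreasing in p̄.  p-values are floored at 1e-300; the degenerate
all-p̄ = 1 case returns uniform importances with a warning.  Category
contributions are importance sums per catalog category.  Feature-profile
grouping z-scores each feature's per-stage means across stages and k-means
clusters the profiles (default k = 5), relabeling groups by the stage at
which their centroid peaks.

## Pseudotime

The trajectory module is a deliberately simplified, self-contained
principal-graph pseudotime (the original analysis used an external
trajectory package; reproducing it is out of scope).  Features are
standardized, PCA-projected (default 10 components), and the scores are
eigenvalue-weighted: component j is scaled by λ_j/λ_1.  At ROI-scale
sample sizes (~125) with ~550 features, trailing components are
near-isotropic noise whose unweighted coordinates would dominate Euclidean
distances and derail the principal graph; quadratic down-weighting keeps
the dominant progression axis in charge while preserving genuine secondary
structure.  ROIs are k-means-clustered (default k = 8), a minimum spanning
tree is built over the centroids, the root is the cluster with the highest
fraction of normal-stage ROIs, and each ROI's pseudotime is the geodesic
arc length from the root centroid to the ROI's orthogonal projection onto
the nearest tree edge, shifted so the minimum is 0.  On default synthetic
datasets this recovers the stage order with Spearman rho ≥ 0.95 across
seeds.  Branch detection is out of scope; the MST guarantees a connected
graph.

## Mutation spectra

The 12-class scheme is the literal `ref>alt` substitution without strand
collapse — the convention used for coarse per-timepoint spectrum plots
(the urethane model's signature classes appear there as A>G and A>T).
The 96-class scheme is the COSMIC trinucleotide catalog: purine-reference
variants are reverse-complemented together with their context, giving
6 × 16 channels named `5'[ref>alt]3'` in the standard order.
Classification is strand-involutive (a variant and its reverse complement
share a channel), collapsing the 96 channels over flanks reproduces the
6-class matrix exactly, and per-sample channel sums equal SNV counts.
Contexts are input columns (1-based, variant at center), not fetched from
a reference genome, keeping the module download-free.  Both per-sample and
pooled proportions are emitted, since published figures may use either
aggregation.

## Numerical and reproducibility choices

* All stochastic steps take explicit seeds; the pipeline's single global
  seed fans out to named substreams, so partial reruns match full runs and
  rerunning a config is byte-identical.
* sd = 0 cases are mapped to z = 0 with flags rather than NaN throughout
  (permutation z, prevalence z-scores, signature z-scores, profile
  z-scores).
* Wilcoxon tests use the exact distribution where SciPy selects it and the
  normal approximation otherwise; identical-value columns short-circuit to
  p = 1.
* Degenerate geometry (fewer than 3 cells, collinear centroids) raises
  errors naming the ROI; undersized ROIs are skipped with a logged warning
  in window capture, as specified.

## Limitations

* The generator's spatial model produces clumping and co-location but not
  realistic tissue morphology; enrichment effect sizes on real tissue will
  differ.
* Permutation tests condition on the within-ROI type counts; they do not
  address between-ROI composition differences (the feature-level stage
  tests do).
* The pseudotime is a single principal path; branching progressions would
  need a different tool.
* Signature scoring assumes log1p-scale expression in a reasonably
  normalized matrix; no control-gene matching is performed.
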