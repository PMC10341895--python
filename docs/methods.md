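# Methods

## Mixing model and conventions

All computation assumes the linear mixing model `B = S·P` on linear-scale,
non-negative expression. Log-scale input must be unlogged first (readers
expose an `unlog` switch applying `2^x`); sums of log signals have no mixing
interpretation. Proportion matrices are validated in two modes: `strict`
(every entry in [0, 1], columns sum to 1 within 1e-9) and `raw`
(intermediate estimates). Estimates are finalized uniformly across methods:
negative coefficients are truncated to zero and each sample column is
divided by its sum. An all-zero column becomes the uniform distribution
`1/c` and is flagged rather than raising, so noisy pipelines do not abort;
columns whose sum is already within 1e-12 of one are left untouched, which
makes the projection exactly idempotent. Gene matching between bulk and
signature intersects identifiers, keeps bulk row order, and warns when less
than half the signature is found.

## Synthetic mixtures: what they emulate

The generator produces the statistical structure the estimators assume,
with known truth:

* **Signature** (`SignatureDesign`): each cell type over-expresses
  `markers_per_type` private marker genes at `marker_fold` × a shared
  `background_level`; all other genes sit at background. `spillover`
  ∈ [0, 1) leaks that fraction of a marker's excess into one other,
  seed-deterministically chosen cell type — the "overlapping signatures"
  confusion between related populations. Defaults: 500 genes, 10 markers
  per type, fold 10, background 10, spillover 0. A ten-fold marker contrast
  is a conservative, realistic figure for curated immune markers.
* **Proportions** (`MixtureDesign`): symmetric Dirichlet(α) columns
  (default α = 1, a flat prior on the simplex), explicit matrices, or the
  `gse64385_like` design: 12 samples over six types (cancer cells CC +
  neutrophils, monocytes, B, NK, T), samples 1–2 one-hot on CC, samples
  3–12 with CC fraction drawn from {0.3, 0.4, 0.5} and the remainder split
  over the immune types by a flat Dirichlet (the immune sub-proportions are
  free parameters of the design).
* **Noise**: multiplicative log-normal factors with unit mean and
  coefficient of variation `noise_cv` (σ² = log(1 + cv²), μ = −σ²/2).
  Expression noise scales with signal, which is why additive Gaussian noise
  is deliberately not the default. `noise_cv = 0` yields `B = S·P` exactly
  (within 1e-12).

What the generator does **not** model: count sampling, gene-length/GC bias,
batch effects, correlated biological programs shared across cell types, or
platform differences between bulk and signature. Passing tests on this
generator therefore demonstrate correctness of the estimators under their
own assumptions, not performance on any particular experimental dataset.

## Supervised estimators

Per sample `j`, all four solve `b_j ≈ S p_j`.

* **NNLS** (`nnls_deconvolve`): `min ‖S p − b‖₂, p ≥ 0` (scipy's
  Lawson–Hanson), then simplex projection. On 2-type problems it agrees
  with exhaustive grid search over the simplex at step 1e-4 (tested).
* **ν-SVR** (`svr_deconvolve`): the mixture and the signature are each
  z-scored by their own global mean/sd (a single affine transform per
  object, which preserves the linear relation because proportions sum to
  one); a linear `NuSVR` (C = 1) is fit for each ν in {0.25, 0.5, 0.75} and
  the ν with the smallest RMSD between reconstruction and mixture is kept.
  The ε-insensitive tube tolerates small deviations, hence the 0.02
  recovery tolerance on clean data (the exact methods reach 1e-6). A sample
  with no signal along any signature column (all coefficients truncated to
  zero, or zero variance) is flagged degenerate and reported uniform.
* **Robust linear model** (`rlm_deconvolve`): Huber M-estimation by
  iteratively reweighted least squares, tuning constant 1.345 (95% Gaussian
  efficiency), scale re-estimated each iteration from the normalized median
  absolute deviation of residuals; convergence when coefficients move
  < 1e-8, at most 50 iterations. Two numerical safeguards matter: a
  perfect-fit exit (max |residual| ≤ 1e-10 × data scale) so noiseless data
  reduces to OLS, and a floor on the scale (1e-8 × data scale) because data
  with many exactly tied residuals — e.g. flat background genes — give
  MAD = 0 even when gross outliers remain, and a vanishing scale must
  down-weight those outliers rather than disable reweighting (the zero-scale
  limit acts like an L1 fit). The optional mRNA-abundance factors α_k
  (`fit_mrna_scaling`) have the closed form `⟨p̂, p⟩/⟨p̂, p̂⟩` per cell type,
  clipped to bounds (default [0.1, 10]); they require known proportions and
  are exposed purely as a calibration utility, never applied silently.
* **Adaptive least trimmed squares** (`alts_deconvolve`): iterate NNLS on
  the kept genes; flag genes with squared residual above
  `threshold_multiplier` (default 10) × the median squared residual of the
  kept genes (the inlier scale, as in any trimmed estimator); stop when the
  flag set is stable. Trimming is gradual — at most 5% of genes newly
  flagged per sweep, worst first, with re-entry allowed — because the
  initial fit is biased by the outliers themselves and a single sweep can
  discard informative marker genes and lock in a wrong solution. A
  near-zero median (noiseless data) falls back to an absolute tolerance of
  1e-10 so nothing is flagged on clean data; flagging more than half the
  genes aborts as degenerate contamination. Note the 50% breakdown point of
  a median threshold: a *majority* of self-consistent contaminated genes is
  statistically indistinguishable from signal and will be followed, not
  flagged; the abort guard fires in the runaway-trimming regime (e.g. a
  threshold multiplier near 1 on noisy data).

## Unsupervised estimators

* **ICA** (`ica_deconvolve`): scikit-learn FastICA (parallel fixed-point,
  logcosh contrast, tol 1e-6, max 1000 iterations, seeded) on the bulk with
  genes as observations and samples as variables. Because centering acts on
  the gene dimension, the recovered mixing rows are scaled copies of the
  proportion rows up to sign; each component is oriented so its gene-loading
  skewness is positive (marker loadings are sparse positive spikes), then
  negative mixing weights are truncated and each sample renormalized.
  Requires `c < m`; non-convergence (e.g. Gaussian-only data, for which ICA
  is unidentifiable) returns the last iterate with a recorded warning.
* **Simplex corners** (`linseed_deconvolve`):
  1. *Collinearity filter*: pairwise squared Pearson correlation across
     samples on the `top_n_genes` (2000) by mean expression; per-gene score
     = sum of its 10 strongest edges; keep genes scoring at or above the
     0.9 quantile. Near-constant genes (sd < 1e-9 × mean) are excluded
     first — rows constant up to float rounding correlate spuriously
     through shared rounding patterns. A floor of max(10c, 30) top-scoring
     genes is kept so that clean data, where the graph may contain only
     markers, retains every cell type.
  2. *Baseline removal and row normalization*: each kept gene's per-sample
     minimum is subtracted before dividing by the row sum. Every gene is a
     convex combination of the row-normalized proportion rows either way,
     but ubiquitous background expression pulls all gene points toward the
     centre of the simplex, so without baseline removal even a perfect
     marker sits well inside the hull (at fold f its corner coordinate is
     shrunk by f/(c+f−1)) and a pure sample could never be estimated near
     1. After removal, marker points are exact vertices on clean data.
     Near-zero rows (relative to the original scale) are dropped.
  3. *Projection and corner search*: project the gene points onto the top-c
     right singular subspace; find c corners by successive projection (take
     the farthest point from the origin, deflate its direction, repeat) —
     deterministic, and equal to the exhaustive extreme points on 2-type
     data (tested). Degenerate geometry (fewer extreme directions than
     requested components) raises with a hint to lower `c`.
  4. *Markers*: genes within the 0.05 distance quantile of a corner (with a
     1e-9 absolute floor so coincident points are never split), at least 3
     per corner. The rule is deliberately conservative: called markers are
     reliable; completeness grows with the quantile.
  5. *Proportions*: the row-normalized proportion estimate H̃ is the
     marker-centroid of each corner; every kept gene's simplex loading on
     the corners is solved by sum-constrained NNLS. Row normalization is
     undone by scaling each corner's row with its total (baseline-
     subtracted) marker signal — markers are the only genes attributable to
     a single type — then columns are renormalized. The estimate is exactly
     scale-invariant in B and equivariant under sample permutation.

  On designed mixtures the corner estimate has a characteristic signature:
  near-perfect per-type correlation with the truth but a compressed scale
  for types that are present everywhere (their per-sample minimum is
  removed with the baseline), e.g. a larger absolute RMSE for a cancer
  fraction that never falls below 30% — while pure samples are still
  estimated at ≈ 1.0. This correlation-accurate/scale-biased profile is the
  known trade-off of complete deconvolution without a reference.

Component labels are assigned against a reference (`assign_components`) by
maximizing total Pearson correlation over one-to-one assignments
(Hungarian algorithm); constant rows correlate as 0, ties break by lexical
cell-type order, and matches below r = 0.5 are flagged low-confidence. When
only marker truth is available, the mean expression of each type's markers
serves as the surrogate reference row.

## Evaluation layer

`correlation_matrix` (real types × estimated types, Pearson across samples,
constant rows → 0 with a note), `rmse_per_cell_type` (proportion scale),
`mean_diagonal_correlation` (with an exclusion list for hard subtypes),
long-format `bar_mixture_table` (2·c·m rows; per sample and source the
proportions sum to 1) and per-type `cell_signature_table` back the three
standard comparison figures; the figures themselves (`mixdecon.plots`) are
conveniences rendered from the tables, which are the tested contract.

`refine_signature` distills a broad signature: subtypes are collapsed to
major lineages by column means (the lineage map is user-supplied data),
the simplex-corner method runs on the shared genes, corners are assigned to
lineages by overlap between corner markers and each lineage's most specific
signature genes (top 50 by share of the collapsed row signal, exact
bipartite matching; a corner with zero overlap everywhere is an error), and
the per-lineage marker lists are by construction subsets of the base
signature.

## Comparison pipeline

`run_comparison` executes the requested methods on identical gene-matched
inputs, labels unsupervised components, evaluates each method when truth is
available, and writes per-method tables plus one summary. Failures are
isolated per method and recorded. The run is deterministic under a fixed
config and seed — byte-identical TSV output — which is why wall-clock
runtimes are logged and kept in the in-memory summary but never written
into the tables.

## Problem sizes and test design

The test and acceptance workloads use sizes at which the estimators'
asymptotic behaviour is already stable: 500 genes × 12 samples × 5–6 cell
types for recovery, robustness and noise-curve checks (the noise curve
averages a fixed suite of ten seeds per level), 120 genes × 10 samples for
the 50-configuration simplex contract sweep, 300 genes × 3 types for
planted-marker recovery, and 20 random 2-type problems against the
exhaustive simplex grid (step 1e-4). Published per-dataset performance
numbers are bound to specific experimental cohorts and are not reproduced
here; the properties above are what is checkable from first principles.

## Known limitations

* Supervised accuracy is conditional on the signature matching the bulk
  platform and containing the sampled cell types; a cell type absent from
  the signature (e.g. tumour cells against an immune-only signature) is
  redistributed over the listed types.
* The median-based trimming in `alts` cannot detect majority contamination
  (50% breakdown).
* ICA proportions are identified only up to the truncate-and-renormalize
  convention; strongly overlapping or Gaussian-like signals degrade it
  first.
* The simplex-corner route assumes each cell type has at least a few
  near-exclusive markers surviving the collinearity filter; its absolute
  scale for never-absent cell types is compressed (see above).
* Automatic selection of the number of cell types `c` is out of scope; all
  methods take `c` (or a signature) as given.
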