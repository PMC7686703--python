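# Methods

This note documents the models, defaults and design decisions behind
`widlo`, in the order the pipeline runs them.

## Outcome definition

A sample is community-type **L** when the summed relative abundance of
*L. crispatus*, *L. gasseri*, *L. iners* and *L. jensenii* is **at least**
0.5 (boundary inclusive), else **O**.  Taxon names are matched after
case-folding and whitespace normalisation; a user-supplied synonym map
handles naming variants.  All taxa enter the denominator (how unclassified
reads should be treated is left to the caller's upstream processing).
Class encoding throughout is O = 1, L = 0, so a higher index favours O.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw microarray physics (no fluorescence intensities, probe chemistry or
sequencing reads).

- **Mixture signal.** Clean beta is β_ij = Σ_k f_ik μ_kj.  Reference means
  μ are drawn from a bimodal (Beta(2,8) / Beta(8,2)) baseline shared across
  cell types with small jitter; for every pair of cell types a disjoint
  block of d = 50 probes is forced to differ by ≥ 0.7, which guarantees the
  deconvolution problem is identifiable.
- **Cell fractions.** Dirichlet(8, 1, 3) over (epithelial, fibroblast,
  immune): mean IC 0.25 and epithelial dominance, typical of cervical
  smears.  The concentration may differ by label, but the default is
  identical for L and O (immune load is modelled as independent of
  community type).
- **Planted effects.** Community-type CpGs shift one compartment's mean by
  ±Δ (half hyper-, half hypo-methylated by default) in O samples *before*
  mixing, so the observable effect is Δ·f_compartment — exactly the
  structure the Δβ statistic and the cell-type interaction model are built
  to detect.  Planted probes are drawn from those whose compartment mean
  leaves room for the shift, keeping effects exact rather than clipped.
  Age-effect probes add slope·(age − mean age) to the mixed signal.
- **Noise.** Additive Gaussian on the beta scale, clipped to [0, 1];
  default sd 0.045, representing combined technical and biological
  (inter-individual) variability.  A materially smaller value makes a
  Δ = 0.15 compartment effect separate the classes completely at every
  planted probe — a regime real smear methylomes do not show and in which
  per-CpG logistic fits degenerate.  A variance-matched Beta noise model is
  available (`noise_model="beta"`).
- **Ages.** Normal(45, 12) truncated to [18, 80] years.
- **Detection p.** Good entries uniform(0, 0.01) — any value below the
  masking threshold is equivalent downstream — failures uniform(0.01, 1) at
  rate 0.002.
- **Abundance.** L samples draw a total designated-Lactobacillus share from
  U(0.5, 0.95), O samples from U(0.05, 0.49), split within groups by
  Dirichlet draws; re-typing the table reproduces the planted labels
  exactly.
- **Default effect sizes** (Δ = 0.06–0.2 in the examples and tests) are
  chosen for testability.  Real cohorts carry weaker, more diffuse signal
  spread over many more CpGs, so a passing recovery test demonstrates the
  machinery, not clinical-scale performance.

Everything is drawn from one `numpy` Generator per cohort: identical seeds
give byte-identical outputs.

## QC

Order is fixed: exclusion lists → mask entries with detection p > 0.01 →
remove samples with strictly more than 10% failed probes → remove probes
with strictly more than 10% failures *computed over surviving samples* →
impute.  The strict inequalities follow the usual reading of "> 10%".
Exclusion lists use set-union semantics; ids absent from the matrix are
ignored.

Imputation fills a missing (probe, sample) entry with the unweighted mean,
over the k = 10 probes nearest in Euclidean distance (computed on samples
where both probes are observed), of their values at that sample; neighbours
missing there are skipped in favour of the next nearest.  This is
implemented directly (scikit-learn's KNNImputer uses a rescaled
nan-Euclidean distance that does not reproduce this rule entry for entry)
and verified against a naive O(p²) oracle.  Observed entries are never
altered.  Intensity-based sample exclusion is out of scope: it needs raw
intensities, which a beta-level pipeline does not have.

## Deconvolution

Per sample, beta over the reference probes is regressed on the reference
profiles by iteratively reweighted least squares with Huber weights
(tuning constant 1.345, MAD scale), no intercept; negative coefficients are
truncated to zero and the vector renormalised to sum 1.  IC is the summed
immune-compartment fraction.  The IRLS is written in-package because exact
noiseless mixtures give MAD(residual) = 0, where the robust fit must fall
back to the least-squares solution rather than error; results agree with
statsmodels RLM (HuberT) on noisy data to < 5e-3.  Reference probes missing
in a sample are dropped pairwise.  At least 50 shared probes are required;
collinear references are rejected.

## Ranking

Five statistics, each producing a full 1..p rank (ties broken by probe id):

- **adjusted_logistic** — per probe, logit P(O) ~ β_j + age + IC, Wald z
  for the β_j coefficient, fit by batched Newton iterations across probes.
  Non-convergent or inestimable probes (e.g. constant beta) are flagged,
  assigned statistic 0 and p = 1, and sink to the bottom; a genome-scale
  scan never aborts.  BH q-values are attached (the deterministic choice;
  a π₀-estimating q-value variant was considered and rejected because it
  adds a density-estimation step with tuning sensitivity).  Hyper/hypo
  direction is the sign of the β_j coefficient.
- **welch**, **bartlett** — vectorised closed forms of the unequal-variance
  t and the equal-variance chi-square tests, checked per-probe against
  scipy.
- **delta_beta** — within each group, OLS of β on IC; Δβ is the difference
  of the intercepts at IC = 0 (the extrapolated pure-epithelial group
  difference); ranked by |Δβ|.  Each group needs ≥ 2 samples with distinct
  IC for the intercept to be identifiable.  Plain OLS, unweighted.
- **celldmc** — per probe, β ~ Σ_k f_k + Σ_k f_k×label without a global
  intercept over the three compartments; the summary p is the
  Bonferroni-scaled minimum of the per-compartment interaction p-values
  (the scaling keeps the summary calibrated under the null), and the
  direction comes from the winning interaction coefficient.  The seven
  immune subtypes of the reference framework are collapsed into one immune
  compartment, matching the use of a single IC proportion everywhere else.

Aggregation is the geometric mean of the five ranks, computed by
multiplying sorted ranks so the result is bit-identical under any method
order; ties break by the adjusted-logistic rank (first supplied method if
absent), then probe id.

## Signature training

`SignatureModel.fit()` runs the pool × α × λ scan:

- **Pools** are prefixes of the aggregated ranking; the default grid is
  {1000, 2000, 5000, 10000, 20000, 50000} clipped to the probe count.
- **α grid** is the 11 values 0.0–1.0.
- **λ path**: 50 values geometrically spaced from λ_max (the smallest λ
  with an all-zero solution) down to λ_max·r; inside cross-validation
  r = 1e-2 — λ far below the CV optimum only slows the scan.
- **Folds** are label-stratified (prevents single-class folds at moderate
  n); a degenerate fold draw is re-drawn with a sub-seed, at most 10 times.
- **Selection** maximises mean validation AUC over folds; a
  one-standard-error rule is available (`lambda_rule="1se"`).  Exact ties —
  common under strong synthetic signal where many grid points reach
  AUC 1.0 — break toward the smaller pool, then the smaller α (the
  grouping effect of the ridge component keeps correlated CpGs together
  rather than picking an arbitrary representative), then the larger λ.
- The winning triple is refit on all training data; coefficients are
  reported on the original beta scale.

The solver minimises (1/n)·NLL + λ[(1−α)/2‖w‖² + α‖w‖₁] with features
standardised internally, by IRLS with cyclic coordinate descent, an active
set, full-gradient screening between convergences, and warm starts along
the path (ridge uses a direct solve).  Correctness is pinned by three
oracle families: the λ→0 limit against a Newton MLE (≤ 1e-4), subgradient
stationarity along the lasso path (≤ 1e-6), and an exact all-zero solution
at λ ≥ λ_max with intercept logit(prevalence).  IRLS weights are floored at
1e-5 (as in standard practice); the floor cancels out of the stationarity
conditions at the fixed point.  Coordinate sweeps are JIT-compiled when
numba is available, with an identical pure-Python fallback.

Nonlinear mode adds a β×IC column for every pooled probe — the penalty
decides which interactions survive, so linear and interaction terms of the
same CpG can coexist.  With IC ≡ 0 the interaction block is constant and
the NL index reduces to the linear index.

Signatures serialise to a TSV with `#`-prefixed metadata (α, λ, pool,
seed, a hash of the training data) and round-trip losslessly.

## Evaluation

- **Split**: within each (age bin × IC bin × label) stratum, a seeded
  shuffle assigns the integer count closest to 2/3 to training; singletons
  go to training.  Default bins are decades for age and quartiles for IC
  (the stratifiers are fixed; the bin edges are a documented default, not
  an inference).
- **AUC** is the Mann–Whitney pair statistic with half-credit ties.  CIs:
  DeLong placement-value variance with a normal interval truncated to
  [0, 1] (default), or stratified bootstrap (resampling within class,
  percentile interval, 2000 draws).  Both are exposed because the two are
  often conflated; they agree within 0.03 at n = 200/class.
- **Firth logistic**: Newton iterations on the Jeffreys-modified score with
  step-halving; CIs by bisection on the profile penalized likelihood
  (χ²₁ = 3.84 cutoff, tolerance 1e-6); p by penalized LRT.  Estimates stay
  finite under separation and zero cells and approach the MLE as n grows.
  The association scan fits the index unadjusted and adjusted for age, IC
  and both, dropping missing covariates per model.
- **Trends**: per-group OLS of the index on age or IC with a two-sided
  slope test.
- **Enrichment**: per annotation category (island/shore/shelf/open sea or
  gene region; unannotated probes become "unknown"), a two-sided Fisher
  exact test of selected vs background-remainder membership, BH-adjusted
  across categories.

## Problem sizes and controls

Tests and the acceptance script run at desk scale: cohorts of n = 300
samples × 5,000 probes with 100 planted epithelial CpGs at Δ = 0.15,
deconvolution fixtures of 100 samples × 1,000 probes, 20 null-cohort seeds
for calibration, and CV scans over pools {50–200} × α {0, 0.5, 1} × 25 λ.
These sizes exercise every code path while keeping a full run in minutes;
the machinery is the same at array scale (the per-probe scans are batched
and chunked).

The permutation control deserves a caveat that applies to the original
design as much as to this implementation: ranking CpGs on the same samples
that are then cross-validated is optimistically biased — if the ranking is
recomputed under permuted labels, feature-selection leakage alone pushes
the best CV AUC above 0.9 at p = 5,000, n = 300.  Only held-out data gives
an unbiased performance estimate, which is why the validation split exists.
The control implemented here therefore isolates the scan: labels are
permuted at the scan input while the probe ordering comes from an
independently drawn cohort (an ordering built from the same samples'
original labels retains ~1/√n correlation with any permutation of them and
inflates the null by ≈ 0.04).  The per-seed "best CV AUC" is a maximum over
a hyper-parameter grid and fluctuates with CV noise; the stable quantity,
and the one asserted, is its mean over the 10 permutation seeds.

## Known limitations

- The generator's planted effects are sparse, compartment-pure and of
  uniform magnitude; real community-type signal is diffuse, partially
  shared across compartments, and confounded with unmodelled factors
  (batch, storage, device drift).  Passing recovery tests validate the
  machinery, not clinical performance.
- Raw-intensity preprocessing (background/dye correction, within-array
  normalisation, intensity-based sample exclusion) is out of scope; inputs
  are beta values.
- Microbiome read processing (OTU clustering, chimera removal, taxonomic
  classification) is out of scope; inputs are abundance tables.
- The Δβ statistic extrapolates to IC = 0 but not to zero fibroblast
  content, so it under-reads a pure-epithelial effect by the fibroblast
  share (≈ 8% under the default fractions) — visible in the recovery
  numbers (mean Δβ ≈ 0.13 for a planted 0.15).
- Firth profile CIs can be very wide (upper OR bounds of 1e20 and beyond)
  under complete separation with a continuous covariate; they are finite
  but should be read as "unbounded in practice".
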