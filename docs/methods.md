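# Methods

This note documents the statistical models, algorithmic choices and
defaults behind each module, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Bayesian endpoint intervals

Rate endpoints (disease control, objective response, CD8 conversion)
are binomial proportions. With a Beta(α₀, β₀) prior the posterior is
Beta(α₀ + s, β₀ + n − s) and we report the equal-tailed interval
(quantiles at (1 − level)/2 and 1 − (1 − level)/2), computed by
scipy's regularized-incomplete-beta inversion (absolute accuracy far
below the 1e−9 probability-scale tolerance we require). Percentages are
displayed to one decimal with half-up rounding.

* DCR/ORR prior: Beta(0.4, 1.6) — an informative prior with mean 0.2,
  matching the design assumption of a ~20% background response rate.
* Conversion "no prior": read literally as zero pseudo-counts, i.e. the
  improper Beta(0, 0) with posterior Beta(s, n − s); this is the default
  and, at s = 14, n = 39, yields 21.8–51.4%, matching the published
  interval (the uniform Beta(1, 1) alternative, kept as a config switch
  and always reported side by side, gives 22.7–51.7%). The improper
  posterior requires 0 < s < n; boundary counts raise an error advising
  the uniform prior.
* Disease control requires SD of at least 24 weeks (the endpoint
  definition; a 6-month reading can be configured via
  `sd_min_duration_weeks`). NE best responses stay in the denominator
  (intent-to-treat). Multiple on-treatment biopsies are summarized by
  the maximum CD8 percentage.

A calibration property holds by construction and is tested: when the
true proportion is drawn from the same prior, the 95% interval covers
it in 95% of replicates.

## Logistic association and exact tests

Endpoint–marker association uses logistic regression with an intercept,
fit by iteratively reweighted least squares (statsmodels GLM, binomial
family). Convergence is declared only if the score (log-likelihood
gradient) has max absolute value < 1e−8 at the solution; complete or
quasi-complete separation — where coefficients diverge while fitted
probabilities saturate — is detected (statsmodels' separation warning,
or perfect prediction of every observation) and returned as a flagged,
non-converged fit with a warning rather than a silent estimate.
Wald p-values use the normal reference, two-sided. 2×2 tables use
Fisher's exact test (two-sided by summation of hypergeometric
probabilities ≤ the observed table's); a table with an empty margin
carries no information and returns p = 1 with a warning.

## Differential comparison rules

Each assay layer is compared feature-by-feature between two clinical
groups with the equal-variance Student t (df = n₁ + n₂ − 2; "Student"
taken literally, not Welch) and declared significant only when both the
p-value gate and the layer's effect gate pass:

| layer               | p      | effect metric | threshold |
|---------------------|--------|---------------|-----------|
| RNA (log₂ TPM)      | 0.05   | log₂FC        | 1         |
| NPX proteomics      | 0.05   | log₂FC        | 0.75      |
| CyTOF % of parent   | 0.01   | mean diff     | 0         |
| 28-color flow (X50) | 0.05   | mean diff     | 20 pp     |
| mIF % of parent     | 0.05   | mean diff     | 5 pp      |

log₂FC is computed as the difference of group means of log₂(TPM + 1)
(pseudocount 1; the transform makes the fold change well defined at
zero). No multiple-testing correction is applied in this stage — the
design relies on raw p plus the effect gate. Features with zero pooled
variance are not testable (returned flagged, p = NaN), with one
convention: two *identical* constant groups give t = 0, p = 1 (no
evidence of difference), which the ctDNA delta comparison relies on for
fully degenerate input.

Quantile normalization forces every sample onto the mean distribution
of order statistics; ties within a sample receive the mean of the
reference values their ranks span, which makes the operation
idempotent. Baseline normalization subtracts each subject's
pretreatment value and drops baseline columns; subjects without a
baseline are dropped with a warning.

Signature scores z-score each member gene across all samples in the
matrix (not within groups) and average member z-scores per sample; a
per-sample score is the only reading that supports plotting signatures
by sample group. Over-representation uses the one-sided hypergeometric
upper tail with a p < 0.01 gate.

## mIF phenotyping

Thresholds are computed per image and marker from the pooled pixel
intensities of all segmented cells in all ROIs of the image (pixels
inside segmentation masks only). The 3-means problem is solved exactly:
in one dimension the optimal clusters are contiguous runs of the sorted
values, so dynamic programming over the two boundary indices finds the
global within-cluster-SSE minimum; the middle DP layer uses
divide-and-conquer over the monotone optimal split positions
(O(n log n)). Ties are broken toward the smallest boundary indices, so
thresholds are fully deterministic. Lloyd's algorithm appears only as a
test oracle (the DP solution is never worse than 50 seeded restarts).

The threshold is the mean of the two largest centers. A cell is called
positive iff strictly more than half of its pixels are strictly above
the threshold (both inequalities strict). Positivity calls are invariant
to shifting all of an image's intensities by a constant, and thresholds
are affine-equivariant.

QC: when the two largest centers are closer than 3 within-cluster
standard deviations (a single Gaussian mode produces ≈2.8), the channel
is flagged as poorly separated and a warning is raised — positivity
calls on such channels are near chance.

Percent-of-parent is computed per ROI (child count / parent count) and
averaged unweighted across ROIs of the image; ROIs with an empty parent
population are excluded from the mean and recorded as not evaluable.
Group comparison of image-level percentages uses the (0.05, 5 pp) rule
above.

## Principal-curve pseudotime

The curve is fit by the Hastie–Stuetzle alternation: initialize the
parameter by projection onto the first principal component, then repeat
(i) smooth each coordinate against the parameter with a cubic smoothing
spline whose penalty is chosen by generalized cross-validation, and
(ii) reproject every point onto the discretized curve (200 points,
nearest-segment projection) and recompute arc-length positions.
Numerical choices:

* The fit runs in the PCA basis of the input. Per-coordinate smoothing
  with per-coordinate GCV penalties is not rotation-equivariant on its
  own; fitting in the PCA basis makes pseudotime invariant under rigid
  rotation of the embedding by construction.
* The parameter axis is aggregated into at most 250 weighted
  equal-count bins before spline fitting. This conditions the GCV
  problem (thousands of near-duplicate abscissae make it ill-posed) and
  bounds the cost per iteration; if the GCV search still fails, a fixed
  mild penalty is used for that coordinate.
* Convergence: relative change in total squared orthogonal distance
  < 1e−4, or 1000 iterations. The distance is recorded after each
  projection step; if a re-smoothing step increases it, the previous
  curve is kept and iteration stops, so the recorded history is
  non-increasing.
* Pseudotime is min–max scaled to [0, 1]. Orientation is arbitrary; an
  optional anchor score (e.g., a naive-marker signature expected high
  at the start) fixes the sign, and the flip is recorded.

Gene association uses a Gaussian identity-link GLM (ordinary least
squares with t-reference p-values — for this model IRLS and OLS
coincide). Genes are z-scored across cells (sample sd, ddof 1) before
fitting, so the coefficient cutoffs are on the standardized scale.
Vendor enters as a categorical covariate. Group/timepoint dependence is
modeled as a pseudotime × group interaction (with the group main
effect); a main-effect-only variant is available via
`TrajectoryTestConfig(interaction=False)`. Significance requires
Bonferroni-adjusted p ≤ 0.10 (family = genes tested in the analysis)
AND |coefficient| above the cutoff (1.0 for trajectory association,
0.25 for group/timepoint).

Density trends along pseudotime use a Gaussian KDE with Silverman's
bandwidth on a 256-point grid, renormalized to unit trapezoid integral
over [0, 1]; strata under 20 cells are suppressed. Signature-vs-
pseudotime curves reuse the binned GCV smoothing spline.

## TCR repertoires

Chao1 is S_obs + f₁²/(2 f₂) when doubletons exist, falling back to the
bias-corrected S_obs + f₁(f₁ − 1)/2 when f₂ = 0; the variant used is
recorded per result. Clone identity is exact CDR3 amino-acid sequence
within a chain; duplicate records collapse (counts summed) before any
estimate, so results are invariant to record order. Sharing reports a
symmetric patient × patient matrix (diagonal = per-patient richness)
and the public clones (≥ 2 carriers). Blood–tumor overlap counts
distinct blood CDR3s per peripheral subset also observed in the same
patient's tumor.

## ctDNA

A sample is ctDNA-positive with ≥ 2 of the 16 tracked patient-specific
SNVs detected. Molecular response is an on-treatment MTM/ml at or below
half the baseline (boundary inclusive); zero-baseline patients are not
evaluable. Group comparison works on Δ = log₁₀(C2D1) − log₁₀(baseline)
per patient (unit-invariant) with the Student t above. Logistic
association with response uses log₁₀ baseline MTM/ml; zeros are offset
by half the smallest positive observed value before the transform.

## Synthetic-data generators

Each generator is a pure function of its config + seed (single
`numpy.random.default_rng` stream, no other entropy; outputs written
with fixed formatting are byte-identical across runs). Defaults encode
the study conditions the analyses are validated under:

* **Cohort** — 79 patients (≈ 72 CD8-low / 7 CD8-high), baseline CD8
  below/above the 15% cutoff, a latent standard-normal "inflammation"
  score driving conversion (logistic: intercept −0.8, slope 1.2) and
  response (intercept −2.0, conversion coefficient 1.3, inflammation
  coefficient 0.5), ~54% on-treatment biopsy rate. These shapes mirror
  the published cohort margins; the latent-score machinery exists so
  logistic recovery is testable against known coefficients.
* **Omics** — 1000 features × 10 + 10 samples, 50 planted log₂ shifts
  of 2.0, Gaussian noise sd 0.5.
* **ROI images** — 2 ROIs/image, Poisson(80) cells, 15–40 pixels/cell,
  negative mode N(10, 5), positive mode N(60, 5) (10 sd separation),
  planted positive fractions 30% (CD8) / 20% (TOX).
* **Trajectory** — latent time t ~ U(0, 1) on a line, quarter-circle
  arc or one-period S-curve; isotropic Gaussian noise with sd equal to
  10% of the curve extent per dimension; genes linear in t with vendor
  offsets and optional group × t interactions. The curve families are
  intrinsically planar, so recovery benchmarks run in the native 2-D
  plane; the generator embeds into any dimension (default 10) via a
  random rotation for the GLM analyses. Note that noise at 10% of
  extent *per dimension* in 10-D is a materially harder condition than
  the same fraction in 2-D (total orthogonal noise grows with √d).
* **Clones** — log-series abundances (p = 0.9), public pool of 200
  CDR3s drawn with probability 0.05, blood→tumor re-observation rate
  0.2.
* **ctDNA** — log-normal baselines (log₁₀ mean 1.5, sd 0.6),
  response-dependent log₁₀ decline (−1.0 responders, +0.2 progressors,
  sd 0.3).

What the generators do **not** emulate: gene–gene and marker–marker
covariance, heavy-tailed or zero-inflated noise, segmentation errors,
spatial structure within ROIs, clonal lineage structure, or assay
detection limits. Passing recovery tests therefore demonstrates the
correctness and calibration of the algorithms under their stated
assumptions, not robustness to real-data pathologies.

## Problem sizes in the test suite

The suite validates calibration at the sizes stated in the docstrings:
10,000 null features for type-I error, 20 replicates for planted
differential sensitivity, 50 synthetic images (two channels) for mIF
recovery, 200 random instances for the DP-vs-Lloyd cross-check, 10
seeds × 2,000 cells for S-curve pseudotime, 100 seeds for GLM coverage
and 200 replicates for the Bonferroni family-wise error bound. These
sizes were chosen to keep Monte-Carlo noise well below the asserted
margins while remaining desk-scale.

## Limitations

* Batch correction of embeddings (Harmony-style) and upstream
  quantification are out of scope: the trajectory module consumes any
  cells × d embedding.
* The published tumor-biology findings (specific differential gene
  lists, pathway calls, figure-level results) depend on patient-level
  data that are not publicly shareable and are not reproduced here;
  the synthetic recovery suites stand in for them.
* The improper-prior conversion interval is undefined at boundary
  counts (0 or n conversions); the uniform prior must be selected
  explicitly in that case.
* Exact 1-D k-means assumes the pixel pool fits in memory; images with
  tens of millions of masked pixels per channel should be subsampled
  before thresholding.
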