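# Methods

This note documents the statistical procedures `metabeq` implements, the
choices made where more than one construction was defensible, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Data model and preprocessing

The unit of observation is an individual seed; the unit of *inference* is
the line (genetic background). Intensities are integrated peak ion counts,
non-negative, with missing cells interpreted as below the instrument
detection limit.

Preprocessing runs in a fixed order, enforced by a scale-state tag on the
matrix:

1. **Minimum imputation** (raw scale). Each missing cell of metabolite *j*
   receives the smallest intensity at which *j* was detected anywhere in the
   dataset (a global, not per-line, minimum). Metabolites never detected are
   dropped. The imputation mask is kept.
2. **Median scaling**. Each metabolite is divided by the median of its
   *detected* values — imputed cells are excluded from the median, so
   imputation cannot move it. After scaling, the detected median of every
   metabolite is exactly 1.0 (even counts use the midpoint of the two
   central order statistics).
3. **log2** (or natural log) for the multivariate analysis and displays.

Imputing before scaling gives the statistics a complete matrix while
preserving the median-equals-1 display contract. Detection frequencies are
computed on the raw matrix: per line, the fraction of that line's seeds in
which the compound was detected, and per metabolite the overall null
fraction. Metabolites with overall null fraction strictly above a threshold
(default 0.5) are **flagged**, not corrected: minimum imputation collapses
the censored tail, understates within-line variance, and therefore tends to
understate p-values for heavily null compounds. The flag, together with an
`all_null_in_test_line` indicator, tells the reader which rows to discount.

## Natural variation profile

For each metabolite, the dynamic range is the ratio of the highest to the
lowest per-line mean, taken on the median-scaled *linear* scale (ratios of
means; scale-invariant by construction). Ties in the extreme lines break
toward the lexicographically smallest line id so results are unique. A zero
minimum line mean yields an infinite-ratio sentinel: excluded from class
medians, binned into [100, ∞), and flagged. Per pathway class the profile
reports counts, median/min/max finite ratio, and counts in the bins
[1,2), [2,10), [10,100), [100,∞), plus the overall fraction of metabolites
varying less than 10-fold.

## Univariate screen

One-way random-effects model per metabolite with line as a random effect;
variance components by the method of moments from the ANOVA mean squares.
For a balanced design with k lines of m seeds:

- `sigma²_error = MS_within`,
- `sigma²_line = (MS_between − MS_within) / m`, truncated at 0 for
  reporting with the truncation recorded; the untruncated value satisfies
  the identity `var(line means) = sigma²_line_untrunc + sigma²_error / m`.

Unbalanced designs use the unweighted-means analysis: line means carry
equal weight and the effective per-line size is the harmonic mean of the
n_i. This is the minimal extension; the targeted design is balanced.

The (1 − alpha) prediction interval for the mean of a new line of m seeds is
`center ± t(1−alpha/2, k−1) · sqrt(s²_lm (1 + 1/k))` with `s²_lm` the sample
variance of the baseline line means; by the identity above this equals the
component-based construction when the new line has the same m, and the
component form `sigma²_line + sigma²_error/m_new` is substituted when it
does not. The two-sided p-value is the exact inversion of this interval
(p > alpha ⇔ candidate mean inside), i.e. a t-test of the candidate mean
against the baseline line means with predictive variance `s²_lm(1 + 1/k)`
and k − 1 df. Degenerate panels (all line means identical) report p = 1 at
the center and 0 elsewhere, with a flag.

The screen defaults to the **median-scaled linear scale**; `--log` switches
to log-scale testing. On the linear scale the line means of strongly
log-normal metabolites are right-skewed: overall size stays near nominal
(measured ≈ 0.05 at alpha = 0.05), but the extreme tail is anti-conservative,
so occasional very small null p-values occur for the most variable
compounds. Log-scale screening removes this at the cost of departing from
the default analysis scale; both are exposed.

**q-values.** Storey–Tibshirani: π̂₀ from the natural-cubic-spline smoother
of π₀(λ) on the grid λ = 0, 0.05, …, 0.90, evaluated at 0.90 and clamped to
(0, 1]; with fewer than 100 p-values the spline is unstable and π̂₀ falls
back to 1 (logged), reducing the procedure to Benjamini–Hochberg with the
step-up minimum. q-values are monotone in p and bounded by π̂₀.

## Multivariate screen

Line means on the log scale are standardised per metabolite (mean 0, sample
SD 1 over the k baseline lines; zero-variance metabolites dropped with a
warning) and decomposed by thin SVD — no covariance detour, so J ≫ k is
fine. Loadings are orientation-fixed (largest-magnitude entry positive);
variance-explained fractions cover all computable components and sum to 1.
Held-out lines are projected through the stored center/scale and loadings;
projecting a baseline line reproduces its stored score exactly.

**Score prediction interval.** The interval is
`0 ± t(1−alpha/2, k−1) · s · sqrt(1 + 1/k)`, symmetric about 0 because
baseline scores are centered. The choice that matters is what `s`
estimates:

- *naive*: the SD of the in-sample baseline scores. When J ≫ k the leading
  component partly chases sampling noise, so in-sample scores are
  systematically over-dispersed relative to the projection of a genuinely
  new line; on panels of ~170 metabolites and ~48 lines with little true
  inter-metabolite correlation the naive interval is roughly 3× too wide
  and covers essentially always.
- *calibrated* (default in `assess_multivariate`): the root-mean-square of
  **leave-one-out held-out scores** — each baseline line projected onto a
  PCA refitted (including re-standardisation) without it. Held-out
  projection is exactly the event the interval is supposed to cover, so
  this estimate is calibrated under both noise-dominated and
  structure-dominated panels; measured coverage on null panels is ≈ 0.93 at
  the 95% level. Models fitted directly from a pre-standardised grid carry
  no cross-validated scores and fall back to the naive estimate.

Only per-component intervals are provided (default: PC1); no joint
Hotelling-type region.

## Synthetic panels

The generator realises the analysis model on the log2 scale:
`log2 y_isj = mu_j + L_ij + e_isj`, exponentiated to intensities. Defaults
(the study conditions the package targets):

| parameter | default | meaning |
|---|---|---|
| n_lines × n_seeds × n_metabolites | 49 × 8 × 169 | germplasm panel size |
| mu_j | U(10, 20) log2 | grand mean ion counts (~10³–10⁶) |
| sigma_line_j | U(0.05, 1.4) log2 | between-line SD; spans ~1.3-fold to >100-fold realised line-mean ranges |
| sigma_error_j | U(0.1, 0.4) log2 | within-line replicate SD (≈7–30% CV), a typical seed-replicate noise level; no published within-line CV constrains it |
| detection_quantile | 0.1 | per-metabolite quantile below which values are censored to missing |

All draws come from a single `default_rng(seed)` stream in the documented
order (mu, sigma_line, sigma_error, line effects, seed errors), so panels
are platform-reproducible. Perturbations multiply named line × metabolite
cells by 2^delta after generation (no RNG consumed), and censoring replaces
cells strictly below the per-metabolite quantile of generated values,
recording the limit in the truth object.

**Spike scenario.** The spike-detection study shifts one metabolite by
δ = 2 (log2, i.e. 4-fold) in the test line and targets the metabolite with
the smallest between-line SD. This models the motivating situation — an
engineered-pathway compound that is tightly regulated across conventional
germplasm, so the engineered shift dwarfs its natural variation. A 4-fold
shift in a metabolite whose natural between-line SD is itself ≥1 log2 is
statistically indistinguishable from line-to-line variation (t ≈ 2/σ_line),
and no screen should be expected to flag it; the targeted scenario is the
one the method is for.

**Parameter recovery** compares the method-of-moments estimates on log2
intensities against the generating variances, reporting median relative
bias and RMSE. The *untruncated* between-line estimate is used for bias
assessment, since truncation at zero is positively biased by construction
for near-zero components (the screen itself still reports the truncated
value). Under heavy censoring plus minimum imputation, `sigma²_error` is
systematically underestimated — the direction the flagging rule anticipates.

**What the generator does not emulate:** inter-metabolite correlation
(pathway co-regulation), so realistic panels have a leading component with
far larger variance explained than the ~5% seen on synthetic panels;
environmental/site effects and genotype-by-environment interaction;
heterogeneous per-metabolite missingness patterns (every metabolite is
censored at the same quantile); non-Gaussian within-line error. Passing
calibration here therefore validates the machinery under the stated model,
not robustness to correlated or structured real data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 20 null panels of 48 + 1
lines × 8 seeds × 500 metabolites for size/coverage (10,000 tests); 200
replicate panels of 169 metabolites for PC1 coverage; one 500-metabolite
panel for parameter recovery; 100 spiked panels for detection rates. These
sizes put Monte-Carlo error comfortably inside the asserted bands while
keeping a full run in tens of seconds on one core.

## Numerical choices and degenerate inputs

- Ties: argmax/argmin over lines break lexicographically; SVD orientation
  takes the first largest-magnitude loading entry.
- Exact duality between p-values and intervals is preserved by computing
  the inside/outside flag as `p > alpha`.
- Zero predictive variance → degenerate interval `[center, center]`,
  flagged; p is 1 at the center, else 0.
- Components with singular values below `1e-12 · s₁` are treated as null
  rank; PCA contracts (orthonormality, centering, reconstruction) are
  asserted at 1e-10.
- Missing-value tokens on input: empty cell, `NA`, `NaN` (case-insensitive);
  an opt-in switch treats literal 0 as missing. Unknown tokens are an error
  naming the token.

## Limitations

- The q < 0.1 decision rule inherits the linear-scale tail behaviour noted
  above; heavy-tailed metabolites can produce occasional very small null
  p-values. Use `--log` when the panel is strongly log-normal.
- Minimum imputation is the implemented rule by design; no model-based
  left-censored imputation is provided, and heavily null compounds are
  flagged rather than corrected.
- The multivariate interval is per-component; joint multi-component regions
  are out of scope.
- Prediction-interval logic assumes exchangeable lines from one pool grown
  under comparable conditions; it does not model multi-environment designs.
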