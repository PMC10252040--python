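# Methods

This note documents the statistical model behind `sweatvoc`, the synthetic
cohort generator it is validated against, the parameters that matter, and
the design decisions taken where the workflow was genuinely open.

## Data model

A measurement is a vector of `p` non-negative peak areas (default `p = 761`,
the size of the screening library), plus metadata: subject, body site
(hand/breast), status (pre/post surgery), GC-column batch
(column1/column2), and technical-replicate index (1–4). Vector position is
defined by library order; file readers re-align permuted columns by
descriptor id and reject unknown or missing columns. Metadata vocabulary is
closed: unknown tokens are errors, never coerced, because silently corrupted
labels would invalidate every group comparison downstream.

The transform chain is tracked explicitly (`raw → logged → standardized`)
and stages refuse out-of-order input. The log transform is `ln(1 + a)`:
areas of absent compounds are exactly 0, and the +1 offset keeps them at 0
while remaining strictly monotone. Standardization (per-descriptor mean 0,
population-sd 1) is always fitted on a declared fitting subset and applied
without refitting elsewhere; descriptors constant on the fitting rows map
to 0 and are flagged.

## Univariate screening

Per descriptor, a two-sided Mann–Whitney U test compares pre vs post
values. The exact null distribution is used when both groups have ≤ 8
observations and the descriptor has no ties (verified against an exhaustive
label-assignment enumeration in the test suite); otherwise the tie-corrected
normal approximation with continuity correction. Ranks are 1 = smallest p,
ties broken by library order, so rankings are deterministic. No multiplicity
correction is applied — the ranking, not the individual p-value, is what
feeds the classifier, and the probe-variable step provides the
noise-relative error control.

Under a zero-inflated null the tie-corrected test is *conservative*
(fraction of p < 0.05 around 0.02 rather than 0.05); on fully-present
(continuous) null data the nominal 0.05 level is recovered as the mean over
seeds. Descriptors are mutually correlated through the per-sampling global
scale factor, which inflates the seed-to-seed variance of the significant
fraction without biasing its mean.

## Classifier and model selection

The classifier is an L2-penalized logistic regression (penalty
`(1/2C)‖w‖²`, lbfgs, tolerance 1e-8 — a deterministic convex fit).
Hyperparameters:

- `N` — number of top-ranked descriptors used (default grid
  {5, 10, 20, 40, 80, 120, 175, 250});
- `C` — inverse regularization strength (default grid: half-decade steps
  10⁻⁴ … 10¹).

Scoring is the support-weighted mean of per-class F1 (zero-denominator
class F1 defined as 0), pooled over held-out predictions. Cross-validation
is group-aware: the technical replicates of one (subject, status) sampling
always stay on the same side of any split, since replicate rows are
near-duplicates and splitting them would leak. Leave-one-out here means
leave-one-*group*-out. Within each fold, ranking, scaler fitting and SMOTE
rebalancing use the fold's training rows only.

SMOTE generates minority-class points as `x + u(x_nn − x)` with
`u ~ U(0,1)` and `x_nn` one of the k = 5 nearest minority neighbors
(k is reduced with a warning when the minority is smaller). It runs *after*
descriptor selection, in the reduced standardized space: nearest-neighbor
distances in the full 761-dimensional sparse space are unstable, and the
rebalancing is only meant to equalize class weight for the fit actually
performed. Synthetic rows are tagged and can never reach a validation or
test fold.

Among grid cells tied on CV score, the lowest-complexity model wins:
smallest N first, then smallest C. The selection is invariant to grid
enumeration order. On strongly separable synthetic cohorts many cells
saturate near score 1, and the tie-break then tends to pick small N and
very small C; one visible consequence is that the probe variable (below),
refit at that same strong regularization, may never outrank real
descriptors, so that all N descriptors are retained. This is the honest
output of the rule, not an error.

## Attribution and probe-variable relevance

For a linear decision value, Shapley attributions have the exact closed
form `φ_ij = w_j (x_ij − x̄_j)` with background mean `x̄`; additivity
`Σ_j φ_ij = f(x_i) − f(x̄)` is asserted to 1e-10 in the tests. Importance
is the per-descriptor mean |φ|; importance ties break by library order.

The probe-variable method asks which descriptors are more important than a
feature known to carry no signal. Each of R realizations appends a fresh
standard-normal probe column (scale-matched to the standardized features),
*refits* the logistic regression at the same C — the probe receives a small
fitted weight; a fixed model would pin its rank at N+1 and make the method
vacuous — and records the probe's importance rank among the N+1 columns
(importance ties go against the probe). The empirical CDF F(r) of the probe
rank yields, for risk δ, the threshold `r_δ = max{r : F(r) ≤ δ}` (0 when
even rank 1 exceeds δ). Retained at δ: descriptors ranked ≤ r_δ in the
single probe-free reference fit. Retained sets are nested in δ by
construction. Default δ grid: 5/10/20%.

The run-scale default for R is 100,000; rank CDFs at the δ grid used here
are stable well below that, and the test suite and acceptance script use
R between 500 and 2000. Uniformity of the probe rank under an
exchangeable-noise null is an ensemble property: for a single fixed
dataset the empirical CDF deviates from uniform by the order-statistic
fluctuation of the N real features (~0.15 at N = 50, independent of R), so
the calibration test pools realizations over 20 independent null datasets,
where the pooled deviation is ~0.02.

Stability between two analyses (body sites, batches, repeated runs) is the
Jaccard index of retained sets per δ, plus a Jaccard curve over top-m
importance rankings. Two empty sets compare as 1 with a warning.

## Synthetic cohort generator

The generator emulates the descriptive statistics of vectorized sweat
screens; it is the ground-truth source for every pipeline test.

- **Zero inflation** — presence × abundance. Occurrence probabilities
  follow a U-shaped law on [0,1] (Beta(0.3, 0.3) plus explicit
  never-present and always-present spikes, ~12% each), matching screens
  where some library compounds appear in every chromatogram and some in
  none. Presence per measurement is a weighted sample without replacement
  at a target count drawn uniformly inside the configured envelope —
  (77, 242) for breast, (82, 348) for hand — so per-measurement non-zero
  counts respect the envelope by construction.
- **Abundance** — log-normal (`area_log_mean = 11`, `area_log_sd = 1` in
  ln units) with a per-sampling global scale factor spanning
  `area_scale_spread = 2` orders of magnitude across measurements, a
  subject × descriptor random effect (sd 0.4) shared between a subject's
  pre and post samplings, and per-replicate jitter (sd 0.3). Replicates of
  one sampling share the sampling-level latents, so they are correlated but
  not identical; the within-sampling correlation is a free parameter, not
  an asserted value.
- **Batch effect** — a global ln-scale offset (`batch_shift`) applied to
  column2 plus per-descriptor jitter (sd = 0.1·|shift|), with a configured
  fraction of subjects per column. A large shift dominates the leading
  principal components of pooled data — the motivation for the pipeline's
  refuse-to-pool default (`--pool-batches` overrides, for demonstrating the
  confound).
- **Planted effect** — a chosen descriptor subset receives a pre-status
  ln-abundance shift of `effect_size` with a random per-descriptor sign,
  and an occurrence-probability shift of `dropout_shift` *in the same
  direction*: detection is thresholded abundance, so a compound shifted
  down must also drop out more often. (With independent directions the two
  channels cancel in the rank test and planted markers become
  undetectable.)
- **Cohort layout** — `n_subjects` pre-surgery subjects of which
  `n_post_subjects` also have a post sampling (default 21/13, the study
  envelope, giving the pre-majority imbalance that SMOTE addresses), up to
  4 technical replicates per sampling. `make_study_pair` produces a
  breast-like and a hand-like cohort whose planted sets overlap by a
  configured fraction (default 0.3).

Default effect parameters (`effect_size = 3.5` ln units,
`dropout_shift = 0.65`, 35 planted descriptors drawn from mid-occurrence
compounds) are calibrated so that the default cohort reproduces the
separability regime the method is designed for — leave-one-out CV scores
near 1 and holdout F1 ≥ 0.9 with sensitivity near 1. With
`effect_size = dropout_shift = 0` the generator is an exact null: the
significant fraction stays at/below nominal, CV and holdout scores sit in
the chance band, and probe ranks are uniform.

What the generator does **not** emulate: retention times, spectra or
co-elution structure; descriptor–descriptor biochemical correlation (beyond
the shared scale latent); age or other covariates; drift within a batch.
Passing tests therefore certify the statistical machinery — leakage-free
splitting, calibration, recovery of planted signal, confound behavior — not
chemical validity on real cohorts.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` on explicit
  seeds; identical config + seed ⇒ bit-identical outputs, including the
  full pipeline report.
- Logistic fits: lbfgs, tol 1e-8, max_iter 10,000; probe refits reuse a
  warm-started estimator (the solution is unique, warm starting only speeds
  convergence).
- A descriptor identical in both groups gets p = 1 (it carries no
  information). Empty significant sets are returned with a warning, not an
  error. Sensitivity/specificity with an empty denominator are reported as
  not-available (`None`), never as 0.
- Single-class CV training folds are skipped with a warning and recorded;
  a fully single-class batch is an error.
- The Mann–Whitney exact/asymptotic switch at group size 8 keeps
  small-cohort results enumeration-exact while remaining vectorized at
  scale.

## Problem sizes

The test suite and acceptance script run cohorts of 10–34 sampling groups,
120–761 descriptors, and probe realization counts of 100–2000 — sizes
chosen so the full validation cycle completes in a few minutes on one CPU
while every statistical property under test is still well-resolved at those
scales.

## Known limitations

- The probe-retained sets use ranks from a single probe-free reference fit;
  averaging reference ranks across realizations is a reasonable alternative
  the package does not implement.
- Occurrence fractions in the relevance report use detection (area > 0) on
  the rows provided; with few post rows those fractions are coarse.
- The CLI's `preprocess`/`interpret`/`probe` subcommands rank on all
  provided rows (an exploration mode); the `run` pipeline and `train`
  subcommand rank on learning rows only, which is the leakage-safe default
  for any reported performance number.
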