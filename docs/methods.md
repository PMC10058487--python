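# Methods

## Model

`blockpath` quantifies the influence of an input data block A on an
output C, optionally conditional on a mediating block B, on a three-vertex
directed path diagram A → C with A → B → C.  All blocks are samples ×
variables matrices sharing a sample index; C may be a block or a single
binary outcome y coded 0/1.  Every arrow is modelled by a PLS regression
(PLS1 for a univariate response, PLS2 otherwise), which tolerates the
strong collinearity and p ≈ n geometry typical of omics blocks where
ordinary regression coefficients are unstable or undefined.

With column-centered matrices, the **global effect** of A on C is the
explained variance of the regression `X_C = X_A V_AC + E_AC`, i.e.
`‖X_A V_AC‖² / ‖X_C‖²` in squared Frobenius norms.  The **partial
effect** of A on C given B removes the part of both A and C that B
explains (`X_C = X_B V_BC + E_BC`, `X_A = X_B V_BA + E_BA`) and reports
the explained variance of the residual-on-residual regression
`E_BC = E_BA V_CBA + E_CBA`, namely `‖E_BA V_CBA‖² / ‖E_BC‖²`.  The
denominator is the residual variance, not the original variance of C:
partial percentages answer "how much of what B leaves unexplained does A
explain?".

When A, B, C are single standardized variables these definitions collapse
to the squared correlation r²_AC and the squared partial correlation
r²_AC·B; the test suite verifies this equivalence to 1e-8 over random
correlation structures, which pins down the estimator's algebra
independently of the multivariate machinery.

## Estimation

Reported effects are not training ratios but cross-validated ones:
repeated stratified k-fold CV (defaults k = 10, 50 repetitions, folds
stratified on the outcome) produces, per repetition, the pooled
out-of-fold predictions, the residual sum of squares RSS_r(a) for every
component count a, and the explained-variance fraction
`1 − RSS_r(a)/TSS`.  The effect is the mean over repetitions, its SD the
repetition-level SD.  Pooling out-of-fold predictions before computing
RSS (a PRESS/Q² convention) keeps small folds from destabilizing the
ratio; TSS uses full-data response means so percentages are comparable
across repetitions (a `tss_full_data=False` switch uses per-training-fold
means instead).

Component counts are selected by the **one-standard-error rule**: with
m(a) the mean CV RSS and s the SD across repetitions at the minimizing
count a*, the smallest a with m(a) ≤ m(a*) + s is chosen.  The SD is
taken across the CV repetitions (not across folds) because the repeated
CV run is the unit of replication; fold-level spread mixes in
stratification artifacts.  Every PLS model in a path — the global model,
the two residualization models C~B and A~B, and the final
residual-on-residual model — gets its own independent selection.

Residualization is fitted once on the full data; CV randomness applies to
the final residual regression.  This mirrors treating the residual blocks
as the objects under study.  It does leak information relative to a fully
nested scheme, so `nested=True` (config key `nested_residualization`)
refits the residualization models inside every training fold, keeping the
full-data component counts; on well-behaved simulated data the two
variants agree within Monte-Carlo noise (tested).

Degenerate mediation — B reproducing A exactly, so `E_BA ≈ 0` — returns a
zero partial effect with a warning rather than an error, this being the
correct limit of the variance ratio.

## PLS implementation

PLS is fitted by classical NIPALS with deflation of X (and of Y for
PLS2): per component, the weight iteration starts from the response
column of maximal residual variance (deterministic; PLS1 converges in one
pass), tolerance 1e-12 on the weight update, at most 500 inner
iterations.  Components are nested, so one fit at the maximal count
yields predictions for every smaller count via the coefficient path —
the CV loop exploits this (one NIPALS fit per fold instead of one per
fold × component count), which is algebraically identical to refitting.
Weight norms below 1e-12 stop fitting early (no X/Y covariance left);
the realized count is recorded and downstream code treats larger models
as equal to the last realized one.  This matters for bootstrap resamples,
which can be rank-deficient.  Both X and Y are centered with training
means inside each fit; unit-variance scaling is applied once, globally,
in preprocessing (a `scale_in_fold` switch re-scales within training
folds for leakage-sensitive users).  At full rank the fit equals ordinary
least squares; against scikit-learn's PLSRegression (tight tolerance) the
fitted values agree to ~1e-5, and against the dominant-eigenvector
characterization of the first weight vector to ~1e-13.

**VIP.**  For p predictors and components a with weights w_a, scores t_a
and response loadings q_a,
`VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )` with
`SSY_a = ‖q_a‖² t_aᵀt_a`; mean squared VIP is 1 by construction, so 1 is
the natural importance reference.  Bootstrap stabilization resamples rows
with replacement, stratified on the outcome (class counts preserved — on
~100 samples unstratified resampling occasionally loses a class), refits
at the fixed selected component count, and reports per-variable mean and
SD over 500 resamples by default.  Resamples with a constant response or
no fittable component are redrawn (bounded at 100 retries, logged).  The
importance flag is `boot_mean > threshold`; the threshold is deliberately
an analyst-chosen config value (typical values 1–1.2), never derived from
the data.

**Log2 fold-changes** (case mean over control mean, log base 2) are
computed on data neither centered nor scaled: for intensity blocks this
means the zero-replaced, log-transformed values that enter the model —
a choice that changes FC magnitudes relative to raw intensities and is
therefore stated here explicitly.  No fold change is computed for
partial-effect models; residuals have no meaningful group ratio.

## Preprocessing

Intensity blocks: zeros are replaced by 80 % (configurable) of the
variable's minimum *strictly positive* intensity — the standard
below-detection convention; an all-zero variable is an error.  Then an
elementwise logarithm (base configurable, natural log by default: the
base only rescales columns, which unit-variance scaling removes for
modeling, though it does affect fold-change magnitudes).  All blocks are
scaled to unit variance (sample SD, n−1 denominator) without centering;
centering is left to the model fits so CV stays honest.  Samples with
any missing value in any block are dropped from every block consistently,
and the per-class counts of the retained samples are reported.
Explained-variance results are invariant to swapping the outcome's 0/1
coding (tested); the outcome is centered, never scaled, in all models.

## Synthetic data

The generator emulates the statistical shape of the motivating case
study — 99 samples, a 6-variable clinical-like block, a 102-variable
collinear metabolomics-like block, a balanced binary outcome — with a
latent-factor model: independent standard-normal factors F, blocks
`F Λᵀ + noise` (per-latent loading columns normalized so blocks carry
comparable signal; Gaussian noise, SD 0.5 by default), continuous score
`s = F w`, and `y = 1{s > median(s)}` (balanced classes by construction,
which the stratified-CV machinery needs; a logistic draw is available).
Three scenarios fix the population truth by construction rather than by
formula: `full_mediation` (population partial effect 0),
`independent_inputs` (partial = global), `shared_plus_unique`
(0 < partial < global).  Closed-form population effects are provided only
for the unidimensional Gaussian design, where they are the squared
(partial) correlations.

What the generator does *not* emulate: mass-spectrometry noise
heteroscedasticity, batch effects, missingness mechanisms, realistic
block-wise correlation structure beyond a low-rank factor model.  Passing
tests therefore demonstrate correctness of the estimator under the
declared model, not robustness to instrument artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run the estimator at n = 500
with 3–5 CV repetitions for the scenario sweeps, n = 1000 with 10
repetitions for the trivariate recovery, and the full study defaults
(k = 10, 50 repetitions, 500 bootstrap resamples) for the
case-study-scale run — sizes chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.  Ties in the one-SE rule resolve to the smaller
count (parsimony).  Fold construction deals shuffled within-class chunks
to a shuffled fold order, so per-fold class counts deviate from
proportionality by at most one sample.  All randomness flows from a
single integer seed: per-repetition and per-resample generators are
spawned from `SeedSequence([seed, index])`, making every reported number
bitwise reproducible and the repetitions independent streams.

## Limitations

* Three-vertex paths only; no multi-mediator DAGs and no sequential
  multi-block orthogonalization beyond this case.
* Effects are predictive variance decompositions, not causal direct or
  indirect effects; the path diagram encodes an analysis order, not a
  causal claim.
* The one-SE rule with repetition-level SD can be conservative when the
  CV curve is flat; the full CV curves are available to the caller.
* Partial-effect percentages are relative to the residual variance and
  must not be compared as shares of the original outcome variance.
* The VIP threshold is an analyst input; no significance statement is
  attached to the importance flag.
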