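# Methods

`csfomics` implements the statistical machinery used to ask whether
baseline cerebrospinal-fluid (CSF) measurements — clinical chemistry,
¹H-NMR metabolite profiles and high-dimensional protein panels — can
predict which patients with a clinically isolated syndrome (CIS) will
go on to a second demyelinating attack (clinically defined multiple
sclerosis). Cohorts in this setting are small (tens of patients),
class-imbalanced, and profiled on thousands of features, so every
design choice below is driven by one question: how much of an observed
classification performance is real, and how much is what a small cohort
hands you for free?

## OPLS-DA

The classifier is orthogonal partial least squares discriminant
analysis fitted by NIPALS with orthogonal signal correction. The
outcome is encoded y ∈ {−1, +1}; X is centered and unit-variance scaled
by default (`pareto` and `none` are available; multi-omics blocks mix
units of cells/mm³, mM and RFU-like intensities, so unscaled fits are
rarely defensible). Per orthogonal component: w ∝ Xᵀy (normalized),
t = Xw, p = Xᵀt/(tᵀt), w_orth ∝ p − (wᵀp)w, t_orth = X w_orth,
p_orth = Xᵀt_orth/(t_orthᵀt_orth), and X is deflated by t_orth p_orthᵀ.
After `n_orth` such components (default 1) a single predictive
component is fit on the deflated matrix; predicted scores are
ŷ = b·t + ȳ and a sample is called a converter when ŷ ≥ 0 (ties to the
positive class, for determinism). With `n_orth=0` the model reduces
exactly to single-component PLS1-DA; the test suite pins this
equivalence against an independent NIPALS oracle and scikit-learn's
`PLSRegression` at 1e−8.

Fit quality is reported as R²Y (training variance explained) and Q²
(1 − PRESS/TSS from an internal stratified 7-fold cross-validation —
the same fold count the elastic-net tuner uses, one internal-CV
convention across the package). Q² ≤ R²Y is asserted on ensemble
averages, not per fit: individual folds of a 40-sample cohort are noisy.

Two importance measures are deliberately kept distinct:

* **Projection VIP** (`oplsda.vip`): VIP_j = √p·|w_j| for the single
  predictive component, so mean(VIP²) = 1 exactly. Cheap, model-internal.
* **Removal importance** (`ensemble.run_ensemble` with
  `compute_importance=True`): the mean decrease in held-out accuracy
  when a feature is removed and the model refit on the same
  balance/split. This is the "mean decrease in accuracy" notion of
  importance; reports label which measure they contain.

## Ensemble validation against a permutation null

Small-cohort classifiers can reach 70%+ accuracy by chance, so a single
train/test split is never reported. Each of `n_iter` (default 1000)
iterations: (1) the majority class is randomly undersampled to the
minority count — rebalancing fresh every iteration keeps the permuted
null at exactly 50%; (2) a stratified split holds out
max(1, round(0.10·n_class)) samples per class; (3) an optional selector
(the elastic net, for protein blocks) runs on the training portion
only; (4) OPLS-DA is fit and scored on the held-out samples. The same
procedure with labels freshly permuted each iteration yields the null
ensemble, whose accuracies center on 50% for two balanced classes. The
two accuracy ensembles are compared with a two-sided two-sample
Kolmogorov–Smirnov test (asymptotic p; significant at p ≤ 0.05). A
strict repeated-stratified-k-fold mode (`mode="kfold"`) is available
behind a flag; the default is independent 90/10 resamples.

All randomness flows from one master seed through spawned
`numpy.random.SeedSequence` substreams, one per iteration, so results
are bit-identical across re-runs and independent of execution order.
Iterations whose selector returns no features are logged, counted and
skipped; more than 5% skips is a hard error for a plain ensemble
(silent bias prevention), but the pipeline relaxes the cap for
selector-equipped blocks, where an empty selection under weak or
permuted signal is a legitimate outcome — if an ensemble ends up with
no surviving iterations at all, its KS comparison is reported as
vacuously non-significant.

### What the null comparison can and cannot show

Accuracies within one ensemble are not independent: they share one
fixed cohort. The real ensemble inherits whatever chance association
that cohort carries between features and outcome; the permuted ensemble
re-randomizes it away every iteration. Two consequences, both measured
here and documented because they apply equally to any analysis of this
design:

* Under a true null the KS rejection rate exceeds its nominal 5% level,
  and the inflation grows with ensemble length (measured on no-effect
  cohorts: ≈5% with 20-iteration ensembles at 20/class, ≈22% with
  40-iteration ensembles at 20/class). The calibration test uses
  30-iteration ensembles on 50-per-class cohorts, where the measured
  rate is ≈7%.
* Removal importance on a single small cohort is dominated by a handful
  of borderline samples: at 2 pooled-SD planted effects the classifier
  saturates (~0.97 held-out accuracy) and removing one of five
  informative features flips a prediction only if the cohort happens to
  contain a sample pivotal to that feature. The top-5 recovery rate on
  a single n = 30/30 cohort is ~25–35%. The parameter-recovery
  simulation therefore averages removal importance over 20 independent
  cohorts drawn under identical conditions, which estimates the
  expectation of the importance rather than one draw's idiosyncrasy and
  recovers the planted ranking reliably.

## Elastic-net prefiltering

Protein blocks (thousands of features) are prefiltered inside each
ensemble iteration, on training data only. The ±1-encoded outcome is
regressed on standardized features under the penalty
λ[(1−α)/2‖β‖² + α‖β‖₁] (squared-error loss, matching a mean-squared-
error tuning criterion, not logistic loss). α ranges over
{0.1, 0.3, 0.5, 0.7, 0.9, 1.0} — α = 0 is excluded because ridge
produces no exact zeros and "nonzero coefficient" selection semantics
would collapse — and λ over 50 log-spaced values from λ_max
(= max|Xᵀy|/(nα), the smallest λ zeroing all coefficients) down four
orders of magnitude, warm-started high-to-low. The (α, λ) pair
minimizing stratified 7-fold CV mean squared error wins; features with
nonzero coefficients at that pair are passed on. Coordinate descent is
scikit-learn's `ElasticNet`; the path construction, stratified CV and
selection semantics are this package's.

## Univariate and ROC diagnostics

Continuous features: two-sample t-tests, Welch by default (unequal
group sizes; pooled-variance mode behind a flag). Categorical features:
Pearson chi-square without continuity correction (Yates behind a flag).
Bonferroni correction multiplies by the number of features actually
tested in the invocation and caps at 1.

ROC curves are empirical over all distinct thresholds with trapezoid
AUC; orientation is chosen so AUC ≥ 0.5 and recorded. Confidence
intervals and the p-value against AUC = 0.5 use DeLong's structural-
components estimator (implemented here; degenerate zero-variance cases
collapse the CI to a point). The reported operating threshold maximizes
accuracy over midpoints between adjacent distinct scores, ties broken
toward higher specificity and then the lower threshold — this makes the
threshold unique and shift-equivariant. A binary marker's AUC is
(sens + spec)/2, the area of its one-threshold ROC.

The diagnostic odds ratio is (TP·TN)/(FN·FP); when any cell of the 2×2
table is zero, 0.5 is added to every cell first (Haldane–Anscombe), so
a perfectly sensitive marker with an empty false-negative cell still
reports a finite OR.

## NMR binning and quantification

Processed 1D spectra (phasing, baseline and referencing are upstream
concerns, out of scope here) are bucketed into 0.02-ppm bins tiling
[0.83, 8.47) left-closed/right-open; any bin with nonzero overlap of
the residual-water region (4.13–5.22 ppm) is dropped — 327 of 382 bins
survive at the defaults, a count pinned against an exact-rational
interval oracle. Overlap smaller than 1e−9 ppm counts as touching, not
overlapping, so a bin edge landing exactly on the water boundary keeps
its bin. Integration is trapezoid on the native ppm grid with the
window endpoints linearly interpolated, so adjacent windows tile
exactly. An optional total-area normalization of retained bins is off
by default (whether bin tables should be normalized before modeling is
a genuinely open choice; the flag makes it explicit).

Absolute quantification against the internal standard (1 mM maleic
acid, a two-proton singlet near 6.01 ppm) is the proton-normalized area
ratio: conc = (A_met/H_met)/(A_ref/H_ref)·c_ref. On noise-free
synthetic spectra the round trip recovers concentrations within 1%
provided integration windows of equal width are used for analyte and
reference (equal Lorentzian capture fractions cancel in the ratio).
Method agreement between NMR and an independent assay is summarized by
Pearson correlation plus Bland–Altman bias (mean difference) and 95%
limits of agreement (bias ± 1.96·SD of differences).

## Synthetic cohorts

The generator emulates the structure of a 22-converter /
32-non-converter CIS cohort:

* **Clinical chemistry**, calibrated to published summary statistics:
  leukocytes 10.9 ± 9.1 vs 4.9 ± 4.9 cells/mm³, mononuclear 10.7 ± 8.8
  vs 4.7 ± 4.7, polynuclear = leukocytes − mononuclear (mononuclear
  clipped at the leukocyte count, so subsets never exceed the total),
  total protein 367.7/374.7 ± 96 mg/dl, CSF/serum albumin ratio
  4.9 ± 2.0 vs 5.2 ± 1.6, and oligoclonal-band positivity Bernoulli
  1.00 vs 0.69. Cell counts are truncated-normal at zero;
  `truncate_at_zero=False` gives plain normals when exact first moments
  matter more than nonnegativity.
* **Metabolites**: ~50 unit-variance Gaussian features named after the
  most abundant NMR-detectable CSF metabolites. Signed class effects in
  pooled-SD units are configuration; the default plants none, because
  reported effect directions for myo-inositol, glucose, lactate and
  creatine are internally inconsistent across published summaries of
  this design. `EXAMPLE_METABOLITE_EFFECTS` offers one coherent choice
  for demos.
* **Proteins**: log-normal (right-skewed, as aptamer-based proteomic
  intensities are), default 5000 features with 25 informative ones
  shifted by 1.0 on the log scale in converters; ground-truth
  identities are recorded on the output matrix.

Synthetic 1D spectra are sums of unit-area Lorentzians (area ∝
concentration × proton count) plus the reference singlet and optional
Gaussian noise, on a 32768-point axis over −0.5 to 10 ppm with 0.005-ppm
default linewidths — ~16 grid points per FWHM, keeping trapezoid error
well under the 1% quantification tolerance.

What the generator does **not** emulate: between-feature correlation
structure, batch effects, plate normalization, heavy-tailed outliers,
or assay-specific artifacts. Passing tests on these cohorts show the
machinery is correct and calibrated under its own assumptions, not that
real CSF data will behave as well.

## Panel search

The combined multi-omics step evaluates every combination of 1–6
candidate variables through the same ensemble validator, ranking panels
by pooled held-out ROC AUC, then ensemble mean accuracy, sensitivity,
specificity, and smaller size. Pooled (not per-iteration) AUC is used
because 10% test sets of a 44-sample balanced cohort contain ~4
samples. All panels share one resampling seed, so comparisons are
paired and a superset panel evaluated on identical resamples cannot
lose AUC to sampling luck. Exhaustive enumeration runs while
Σ_k C(n,k) fits the evaluation budget; beyond it a greedy beam search
(width configurable) takes over with a prominent log line, since a
~95-candidate pool at size 6 is combinatorially out of desk range. The
stopping rule returns the smallest size whose successor improves
neither AUC nor accuracy by more than a margin (default 0.01). One
caveat from the validation experiments: with one orthogonal component,
adding a pure-noise variable to a small panel can lift held-out
accuracy by absorbing cohort-specific orthogonal structure; when
comparing panel sizes on small cohorts, `n_orth=0` gives a more
conservative comparison.

## Pipeline

`run_pipeline` chains simulate/load → univariate screen per block →
per-block ensemble validation (elastic-net selection for protein
blocks) → shortlist (top removal-importance or selection-frequency
features per block, capped at 20 total) → panel search (reduced
iteration count) → re-validation of the selected panel at full
iteration count → report in the conventional marker-table layout
(AUC [CI], Acc, Sens, Spec, PPV, NPV, threshold, OR, p). Every
artifact carries the configuration hash and master seed; re-running a
configuration reproduces every numeric output bit-identically. Numbers
are rounded (2 decimals) only in the presentation-layer TSV; the CSV
artifacts keep full precision.

## Problem sizes in the test suite

The suite and acceptance checks run the same machinery at desk scale:
ensembles of 25–300 iterations, cohorts of 20–100 per class, protein
blocks of 25–1000 features, 100-replicate calibration loops. These
sizes were chosen so each check estimates its quantity with error well
inside the asserted tolerance; the module defaults (1000 iterations,
1000 permutations, 5000 proteins) remain the reference conditions for
real analyses.

## Known limitations

* The permutation-null comparison is anticonservative for long
  ensembles on small cohorts (see above); treat KS p-values near the
  threshold with suspicion and prefer effect sizes (mean accuracy gap).
* Removal importance on one small cohort is unstable by nature;
  replicate or bootstrap before trusting a ranking.
* Undersampling discards majority-class information; with larger
  cohorts a cost-sensitive encoding would be preferable.
* The elastic-net CV target is squared error on ±1 labels, faithful to
  the tuning criterion it mirrors, but not a calibrated probability
  model.
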