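# Methods

## The model

`diabmod` treats a clinical screening table as eight numeric features
F₁…F₈ with a binary outcome y (1 = diabetic). The framework's premise
is that on very small tables a classifier benefits from explicit,
low-order summaries of how far each informative feature deviates from
its central tendency. It therefore expands the table in three fitted
stages:

* **statistical** — per-feature mean F̄ᵢ, median FMᵢ, and standard
  deviation σᵢ. The population convention (divisor N) is used here;
  the *sample* convention (divisor n−1) is reserved for fold summaries
  and the paired test, where the five fold values are a sample.
* **relative** — absolute deviations MVR = |x − F̄|, MDR = |x − FM| and
  SDR = |x − σ| for each selected feature. SDR is deliberately the
  deviation from the value of σ itself, not a z-score; the worked
  example values this package pins in its tests (e.g. glucose 183 →
  SDR 153.1828 with σ = 29.8172) only reproduce under that reading.
* **logical** — indicators LFM = [MVR > 0], LFMD = [MDR > 0] and
  LFSD = [SDR > mean(SDR)], strict inequalities, ties → 0. LFM and
  LFMD are indicators of a nonnegative quantity being strictly
  positive, so on continuous data they are almost surely constant 1;
  they are computed verbatim for fidelity and a warning is emitted
  whenever a logical column comes out constant. The only logical
  column with real variation is LFSD, whose threshold — the mean of
  the SDR column on the fitting partition — reduces, for columns whose
  values all exceed σ, to approximately F̄ − σ.

Features enter the relative stage only if their point-biserial
correlation with the outcome ranks in the top k (default k = 4, ties
broken by canonical column order); a |r| ≥ r_min threshold rule is
available. The logical stage defaults to the same selected set so that
k = 4 yields the 8 → 20 → 32 column progression; a
`logical_feature_set="paper_literal"` switch restricts it to
{Glucose, BMI, Age}, the three features the binarization equations
name explicitly, which yields 29 columns instead.

## Imputation

Zeros in {Glucose, BloodPressure, SkinThickness, Insulin, BMI} encode
unrecorded measurements and are designated missing; Pregnancies,
DiabetesPedigreeFunction and Age are never flagged (zero pregnancies is
physiologic, the other two cannot be zero by range). Each missing cell
is replaced by the mean of the observed values of its column within the
row's outcome class (default), or of the whole column in `global` mode.
Replacement means are computed only from observed donors; a
column/class with no donor raises a named error. Imputation is
idempotent and never touches an observed cell.

Two caveats are inherent to the class-conditional rule and documented
rather than silently fixed. First, applying it to a validation or test
row requires that row's outcome label; the package fits the replacement
means on the training part only, but the transform of held-out rows
still reads their labels, exactly as the original protocol (which
imputes before any split) implies. A deployment system would need the
global mode. Second, on heavily zero-inflated columns (insulin ≈ 49%
missing) class-conditional imputation injects strong label information
into the feature, which inflates that column's apparent correlation
with the outcome — visible in the synthetic experiments, where insulin
often enters the top-4 selection through its imputed values.

## Evaluation protocol

A stratified 80/20 split holds out the test partition (768 → 614/154);
stratified 5-fold CV runs inside the training partition. The two
protocol statements (an 80/20 split *and* 5-fold CV) are composed in
the standard way: CV for model assessment inside the 80%, the 20%
touched once at the end. Within each fold, imputation means, feature
statistics, correlations, selection, LFSD thresholds and
standardization statistics are all refitted on the fold's training
part (`fit_scope="train_only"`); `"paper_literal"` instead fits
everything once on the full table, the closest reading of the original
(leaky) protocol. Standardization (zero mean, unit variance, fitted on
the training side) is applied immediately before the classifier and
never to the binary logical columns, because the relative stage must
see raw-scale values — the fitted statistics it reproduces are on the
clinical scale.

Metrics come from the confusion matrix with positive class = diabetic:
accuracy, sensitivity, specificity, precision, F-measure, FPR, FNR,
MCC, and the rank-based (Mann–Whitney) ROC area from classifier scores.
Zero-denominator metrics report 0 with a warning rather than NaN, so a
degenerate fold cannot abort a run. Fold aggregates are mean ± sample
SD (n−1); that convention is pinned by the reference fold summary
97.181 ± 0.707.

Classifier plug-ins (logistic regression, random forest, linear and
RBF SVM, single-hidden-layer perceptron) wrap scikit-learn estimators
behind a name + seeded-factory contract; any estimator with
fit/predict can be registered. No hyperparameter search is performed.

## Paired significance test

Per-fold accuracy differences D (with-modeling minus without, so
improvements are positive) give m = mean(D) and σ_diff = SD(D, n−1).
Two statistics are reported: t = m·√n/σ_diff, which drives the default
two-sided decision at α = 0.05 against the Student-t quantile at
df = n−1, and the plain ratio m/σ_diff. The declared formula and the
published reference t values for this protocol disagree by exactly √n
(e.g. m = 3.284, σ_diff = 0.379 prints as t = 8.6645 = m/σ_diff, while
the formula gives 19.37); whether the reference σ column is actually a
standard error cannot be determined, so both variants are exposed and
the discrepancy is surfaced instead of resolved. If all differences
coincide (σ_diff = 0) the statistic is reported as signed infinity with
a warning, significance following the sign of m.

## Synthetic data

The generator draws y ~ Bernoulli(268/768) and each feature from a
class-conditional Gaussian truncated to its clinical range, rounded to
clinical precision (integers for counts/pressures, 1 dp for BMI, 3 dp
for the pedigree function), with structural zeros injected at a
per-feature rate. Defaults (chosen once, before any testing): location
shifts in the documented direction of the real class differences —
glucose 110→142, BMI 30.3→35.1, age 31.2→37.1, pregnancies 3.3→4.9,
with smaller shifts elsewhere — and zero rates matching the observed
zero fractions (insulin 0.49, skin thickness 0.30, blood pressure
0.046, BMI 0.014, glucose 0.007). Sampled values that round to exactly
zero are nudged one rounding unit up so that structural zeros come only
from the zero-inflation mechanism.

What the generator does *not* emulate: inter-feature correlations,
skewness/heavy tails of the real marginals, and any nonlinearity in
the feature–outcome relation beyond a location shift. Passing tests on
synthetic data therefore demonstrate correctness of the pipeline's
arithmetic, its leakage discipline and its statistical conventions —
not that the expansion improves accuracy on the real table, which
depends on unpublished training details and is out of scope.

Moment-recovery tests compare empirical class means against the
truncated-normal mean (the truncation shifts Age upward by ≈3 units
from its nominal location), within 3 standard errors plus half a
rounding unit.

## Numerical and design choices

* Population SD (N) for the framework statistics, sample SD (n−1) for
  fold summaries and σ_diff — both pinned by exact worked-example
  anchors in the tests.
* Strict inequalities in all binarizations; ties map to 0.
* Selection ties break by canonical feature order, making selection
  deterministic on duplicated columns.
* CSV round-trips are bit-exact (pandas `round_trip` float parsing).
* All randomness flows from a single integer seed per run (split, fold
  shuffling, classifier initialisation, generator).
* Empty selection degrades gracefully: the transform is the identity
  on features, with a warning.
* Problem sizes in the test suite: full-pipeline checks use 240–768
  rows; distributional recovery uses n = 5000; null calibration of the
  paired test uses 200 seeded repetitions of 5 differences. These sizes
  make the distributional assertions stable at 3-SE/99%-binomial
  tolerances.

## Known limitations

* The class-conditional imputation label-dependence described above.
* LFM/LFMD carry no information on continuous data; they are kept for
  fidelity, warned about, and contribute two near-constant columns per
  selected feature.
* No outlier-exclusion rule is implemented (none is specified); range
  violations are reported by `validate_schema` but never dropped.
* Published real-data accuracies are not reproduction targets: they
  depend on unpublished seeds, training details and an unspecified
  CNN; the evaluation harness exposes a pluggable classifier contract
  instead.
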