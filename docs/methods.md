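# Methods

This note documents the statistical procedures implemented in `dogcog`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic test beds do and do not establish.

## Cohort data and exclusions

Input cohorts are a roster (one row per dog: demographics, program status
flags, optional graduate/release outcome, optional count of aborted battery
tasks) and a dogs × measures score matrix.  Measure names are validated
against the DCTB vocabulary (case-insensitive, whitespace-normalized);
unknown names are errors, never silently dropped columns.  Missing score
cells are empty or `NA` on read and written empty, so a load/save
round-trip preserves values, masks, and ordering.

Exclusion rules (status flags, > k aborted tasks, > k missing predictor
measures) are applied in listed order and each dog is removed by the first
rule it matches, so the removal counts always reconcile exactly:
`initial_n = final_n + Σ removed`.  Status-flag rules are conventionally
listed before data-completeness rules; when removal categories could
overlap in the source records, the report makes the chosen precedence
explicit rather than guessing.

## Preprocessing

* **Box-Cox** (`y → ((y + shift)^λ − 1)/λ`, log branch at λ = 0): λ is
  estimated by profile maximum likelihood over a continuous search
  (scipy), not a grid, for reproducibility.  Measures containing zeros or
  negatives (several battery scores are counts or proportions) are shifted
  by `1 − min` before fitting; already-positive measures are not shifted.
  Binary or near-constant measures pass through unchanged with a warning —
  a power transform is undefined or meaningless there.  Applying a frozen
  transform to an out-of-range value is an error naming the value.
* **KNN imputation** (default k = 5, exposed in config): distances are
  Euclidean over measures observed in both dogs, on per-measure
  standardized values; a missing cell becomes the unweighted mean of the
  k nearest dogs' observed values for that measure.  Observed cells are
  never altered and a complete matrix is returned unchanged.  The
  implementation delegates to scikit-learn's `KNNImputer` on standardized
  values; its nan-Euclidean distance differs from the per-shared-measure
  mean squared difference only by the constant total-feature factor, so
  neighbour rankings are identical, which the test suite verifies against
  an exhaustive hand-rolled neighbour search.
* **z-scores** use the sample (n − 1) standard deviation.
* **Quantile discretization** splits a performance measure at the median
  (two categories) or the 33.3/66.7 linear-interpolation percentiles
  (three categories); values exactly on a boundary go to the lower
  category, a rule fixed for reproducibility.  Discretization is invariant
  under strictly increasing transforms of the input.

Whether preprocessing is refit on a prospective cohort or frozen from the
exploratory fit is a logged switch.  The default refits: a frozen power
transform can be undefined on new scores outside the fitted range, while
the models themselves are always frozen between cohorts.

## Classifier ensemble and evaluation

The eight model families are realized by standard scikit-learn estimators
behind one fit/predict surface — GLM (unpenalized logistic), LDA, ridge
logistic regression, PLS discriminant scoring, Gaussian naive Bayes, KNN
(7 neighbours, the one stated hyperparameter; all others default and
logged), and random forest — plus a compact in-package adaptive regression
splines classifier (least-squares forward selection of reflected hinge
pairs at feature quantiles, logistic refit on the selected basis, the
conventional way such models handle binary outcomes).  All families see
per-feature standardized inputs.  What this package owns and contract-tests
is the evaluation machinery, not classifier internals.

* **Repeated stratified k-fold CV** (default 4 × 100): per repeat every dog
  is scored out-of-fold exactly once; each held-out fold yields accuracy,
  ROC AUC, and 1st/4th-quartile accuracies computed inside that fold.  All
  randomness derives from named seed streams; identical seeds give
  byte-identical results.  A training fold missing a class (possible only
  unstratified) is re-randomized with a logged notice.
* **Threshold rule**: predict graduate when p̂ ≥ 0.5; the tie goes to
  graduate (arbitrary, fixed, documented).
* **Quartiles of p̂** are the four near-equal strata of the stable-sorted
  probability ranking, so quartile 4 is always the highest-p̂ quarter, the
  quartiles partition every held-out set (making overall accuracy the
  size-weighted mean of the four quartile accuracies), and heavy
  probability ties cannot empty a stratum; equal probabilities spanning a
  stratum boundary are split by input position, deterministically.  A
  value-based percentile cut with a tie rule was rejected because
  degenerate probability distributions can empty the top stratum.
* **Group comparison**: Welch (unequal-variance) two-sample t-test of p̂
  between graduates and releases, with fractional Welch–Satterthwaite df
  and a one-tailed p for "graduates higher".  The t statistic is reported
  as graduates minus releases (positive when graduates score higher); some
  published tables order the groups the other way, flipping only the sign.
* **Importance**: each family's conventional raw importance (absolute
  standardized coefficients; class-mean separation for NB; model-free
  per-feature ROC distance for KNN; hinge-coefficient credit for the spline
  model; impurity importance for RF), scaled per family linearly to 0–100.
  Cross-implementation equality of raw importances is deliberately not
  promised — only the scaling and the consensus ranking are contracts.
* **Univariate screen**: one logistic regression per measure on its
  pairwise-complete dogs, Wald p, ranked ascending; constant measures and
  measures with < 2 observations in an outcome class are skipped with a
  warning, and complete separation is flagged as a degenerate p of 0
  rather than crashing.

Published per-family cross-validation tables in this design sometimes label
the quartile-accuracy rows inconsistently with their accompanying text; the
implementation follows the substantive definition throughout — the 4th
quartile is the highest predicted probability of success and is the most
accurate stratum.

## Detection-dog performance scoring

* **Training-log ratios**: weekly 0–3 prevalence scores over seven
  behavioural categories (handling, temperament, motivation, handler
  dependence, odor recognition, odor response, false responses); weeks
  reporting ≤ 2 training days are excluded from numerator and denominator;
  ratio = Σ scores / eligible weeks, higher = more problems.  Duplicating
  every eligible week leaves the ratio unchanged.
* **Duration adjustment**: ratio scores correlate with how many weeks of
  records exist, so they are regressed (OLS) on weeks scored and the
  sign-flipped residuals become the adjusted score — higher = better,
  summing to zero and empirically uncorrelated with record length.
  Whether the exploratory phase also adjusts is a config switch; the
  adjustment is always used for replication cohorts.
* **Weighted ordinal score**: percent of records at each rating times the
  weights excellent = 1, good = 0.66, fair = 0.33, poor = 0, summed —
  bounded 0 (all poor) to 100 (all excellent).  The printed two-decimal
  weights are used verbatim, not 2/3 and 1/3.
* **Post-deployment evaluations** contribute percent-passed per category.
* The assembled performance table records availability per dog/measure and
  an orientation flag (larger-is-better) per measure; lower-is-better
  measures can be sign-flipped at assembly so a "positive association"
  downstream always means higher cognition with better performance.

## Consensus screen

Each cognition × performance pair is tested on its pairwise-complete dogs:
a two-sample t-test for two-category outcomes (Welch by default; pooled
variance is a switch, as the original choice is not recorded) or a one-way
ANOVA for three-category outcomes.  Direction is positive when the
above-average-performance group has the higher cognition mean; for ANOVAs
a significant omnibus with weakly monotone ordered group means (ties
allowed, top ≠ bottom) takes the sign of top minus bottom, and anything
non-monotone is neutral.  α = 0.05 with **no multiple-testing correction**
— accepting abundant false positives and relying on their directional
randomness is the method's core logic, not an omission.  Aggregates,
their one-sample t-test against zero, and the |A| ≥ threshold (default 3)
battery selection with flagged manual includes follow directly.

A caveat established by simulation in this package: the zero-mean t-test
on aggregates is calibrated (rejection ≈ α) when cognitive measures are
mutually independent, but becomes anti-conservative when measures share
latent factors and performance measures share latent quality, because
aggregates are then positively dependent across measures.  Interpret the
consensus null test accordingly on real batteries, which are factorially
structured by design.

## Replication statistics

Standardized β is the least-squares slope between z-scored predictor and
outcome — the Pearson correlation in this single-predictor setting —
computed per pair on pairwise-complete dogs with the n used logged.  Each
predictor's β panel over the available outcome measures gets a one-tailed
one-sample t-test (t = β̄/SEM, df = n_outcomes − 1) in the direction
hypothesized from the exploratory screen; a panel opposing its hypothesis
yields p > 0.5 by construction, and the two one-tailed p values sum to 1.
Published versions of such tables may print means and SEMs rounded too
coarsely to recover t; the contract here is the formula on unrounded
inputs.  Reliability: Cohen's κ with marginal-product chance agreement
(two constant identical raters are defined as κ = 1, logged) and Pearson r.

## Synthetic cohorts

Cognitive scores follow a latent-factor model (scores = loadings·factors +
unique noise; default three factors with each measure loading 0.7 on one,
unique noise SD 0.7 — individual differences in dog cognition are
multi-factorial, and these values give the moderate inter-measure
correlations typical of battery data).  Detection-dog performance derives
from a single scalar latent quality per dog (sufficient to plant consistent
directional effects; multi-factor quality is config-optional).  A planted
effect ρ for a cognitive measure blends quality into the measure to give
correlation ρ while preserving unit variance.  Graduation outcomes come
from a logistic model on standardized measures with the intercept solved
numerically so the expected rate equals the target base rate (defaults
0.68 exploratory / 0.77 prospective, the observed program rates).  Weekly
training-log scores follow an ordered logit whose severity decreases with
quality (cutpoints −0.8/−2.0/−3.2), with 1–5 reported days per week so
some weeks fall under the 3-day scoring floor and a mean of 33 scored
weeks per dog; ordinal ratings follow an ordered logit with cutpoints
±1.2/0 and a mean of 97 records per dog.  All randomness flows from one
root seed through named substreams so each stage is independently
reproducible.

What the generator does **not** emulate: real DCTB factor loadings (not
published; loadings are user-specified), non-random missingness,
trainer/coder drift over time, cohort composition shifts beyond the base
rate, and serial correlation within a dog's weekly records.  Passing tests
therefore demonstrate that the machinery recovers structure it is pointed
at under clean conditions, not that real batteries carry that structure.

## Problem sizes and numerical choices

The test suite runs the simulation-based checks at deliberately moderate
sizes chosen to keep the whole suite interactive while leaving ample
statistical resolution: 500 replicates for the null calibrations of the
consensus and β-panel tests (binomial SE ≈ 0.01 at α = 0.05), 100
replicates for consensus effect recovery at the planted-effect settings
(ρ = 0.6, n = 150, 8 outcome measures), 20 replicate cohorts (4 × 3 CV)
for logit-signal recovery, and 12 independent cohorts for the null-AUC
check — a single null cohort retains its own chance association, so
calibration is assessed across cohorts.  Degenerate inputs fail loudly:
constant sequences cannot be Box-Cox'd or z-scored, all-equal
probabilities have no quartiles, zero-SEM panels and zero-variance
aggregate columns are errors rather than infinities.

## Known limitations

Beyond the generator caveats above: the consensus aggregate treats every
performance measure as exchangeable (no weighting by reliability or
sample size, matching the method being implemented); the β panels are
unweighted samples (no meta-analytic precision weighting); separation in
the univariate screen is flagged, not resolved (no penalized fallback);
and the spline-based classifier family is a deliberately small adaptive
hinge model, adequate for ensemble membership and importance consensus
but not a full reimplementation of multivariate adaptive regression
splines (no interactions, no pruning pass).
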