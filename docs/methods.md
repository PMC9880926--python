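# Methods

## Scope and data model

The package analyzes multi-site smartphone digital-phenotyping cohorts
for psychotic-relapse prediction. All data are daily aggregates per
participant: six active survey scores (PHQ-9, GAD-7, psychosis,
sociability, sleep, medication adherence), three passive features
derived from sensors (sleep duration, time at home, screen duration,
hours), and two computed data-quality ratios (fraction of active /
passive values present that day). Features belong to exactly one
collection channel (active, passive, quality) and one clinical group
(symptoms, sociability, medication, sleep, home-time & screen,
engagement). Monthly clinician/self-report instruments (PANSS and
seven others) ride alongside. Relapse events carry one of four
criteria: a ≥25% PANSS increase between consecutive non-missing visits
(boundary inclusive), hospitalization, suicidality, or sudden symptom
escalation.

Because no public data of this kind exist, the synthetic generator is a
first-class module and defines the study conditions; everything
downstream is generic.

## Synthetic cohorts

Composition defaults to the three-site design: 132 participants
(33/49/50 per site), relapsed (R) 9/8/3, non-relapsed (NR) 17/17/22,
controls (C) 7/24/25. Enrollment spans are truncated-normal
(mean 156 d, SD 65 d, minimum 30 d). Daily streams are stationary AR(1)
series around per-stream baselines (φ = 0.3 by default — modest
day-to-day persistence typical of behavioral aggregates), plus a stable
per-participant baseline offset (SD 0.8× the within-person SD) giving
the between-person heterogeneity any real cohort has. Each active value
is independently missing with probability 1 − 0.285 and each passive
value with 1 − 0.574, matching the active/passive data-quality targets;
the quality channel is computed from the realized missingness, never
sampled. Monthly scores are draws around group-level means within each
instrument's range.

### Relapse signature

Each R participant receives one relapse, uniform on [30, enrollment).
The injected signature has two components, matching how relapse
presents to the two detectors:

* **Sustained** (drives changepoints and monthly means): per-feature
  mean shifts over ±14 days — passive features ±0.75 SD, survey
  features only ±0.15–0.2 SD — with within-window variation rescaled by
  √1.5. Survey shifts sit near the monthly-mean noise floor on purpose:
  self-report is a weak relapse signal in this population, which is
  precisely why a survey-only baseline underperforms.
* **Acute** (drives anomalies): each in-window day is a crisis day with
  probability 0.2; on crisis days each shifted feature independently
  (probability 0.5) deviates by 4 SD. Excursion direction is nearly
  symmetric (probability 0.55 toward deterioration) because self-report
  during florid psychosis is unreliable; a sign-agnostic day-level
  detector sees these excursions while a 30-day mean cancels them.

The monthly PANSS at the visit containing a relapse is raised to ≥125%
of the previous visit, so PANSS-based relapse labeling recovers the
event.

### Sub-threshold episodes

SZ participants (R and NR) additionally experience transient
exacerbations (Poisson, mean spacing 75 d) carrying the same signature
scaled by a per-episode strength ~ U(0.4, 1.2) — full-magnitude
non-adherence without relapse happens — but with the acute component
damped by a further factor 0.15, since a sudden escalation requiring
intervention would, by definition, have been a relapse. Episodes are
what make the problem hard: they give the naive baseline confusable
months and the anomaly stage false positives away from relapse, so most
flagged anomalies are *not* near a relapse, as in real deployments.

## Anomaly model

Per participant and channel, features are standardized (making output
invariant to affine rescaling of inputs), then each day *t* is scored
against reference days [*t*−W, *t*+W]\{*t*} with Gaussian kernel
weights (W = 30, h = 10):

1. **Robust moments.** Reference cells beyond 3 robust SDs
   (median/MAD) are trimmed and the variance rescaled by the Gaussian
   truncation constant, so nearby outliers cannot mask the day being
   scored. Pairwise-complete weighted means/covariances handle missing
   cells; the pairwise estimate is eigenvalue-floored (ridge 10⁻⁶).
2. **Tail.** If the minimum pairwise Kish effective sample size m can
   support a covariance (m ≥ f + 3), the squared Mahalanobis distance
   is referred to the Hotelling T² → F transform with m as the Wishart
   degrees of freedom and the leave-one-out variance factor (1 + 1/m).
   Otherwise (sparse channels — e.g. surveys at 28.5% completeness)
   each feature's residual is normalized exactly through a
   Student-t → normal score and the sum of squares referred to χ²_f,
   ignoring cross-feature correlation.
3. Days with no observed channel feature, or fewer than 5 usable
   reference days, emit nothing. Flags are *p* ≤ α (0.005, boundary
   inclusive). Attribution ranks clinical groups by the maximum
   absolute locally-standardized deviation among observed member
   features, ties broken by the canonical group order.

Calibration, measured on white noise: complete channels are KS-uniform
with flag rates 0.005–0.0066; heavily missing channels hold the flag
rate (≤ ~1.3× nominal) though the p-value *shape* is approximate. Two
documented approximations remain: (a) day-to-day autocorrelation
violates the local exchangeability assumption — at φ = 0.3 the passive
base flag rate roughly doubles (both enrichment numerator and
denominator inflate, so rate *ratios* move much less); (b) strongly
correlated features under heavy missingness fall back to the
correlation-blind sparse path. A plain χ² tail is available via
`AnomalyParams(tail="chi2")` for comparison.

The spec-level alternative of a fixed large covariance ridge (0.1) with
a plain χ² tail was measured at roughly 3× the nominal flag rate on
null data and is not the default for that reason.

## Analytic enrichment oracle

`expected_flag_enrichment` predicts the inside/outside flag-rate ratio
from the generator configuration alone: per day-offset it combines the
kernel-weighted contamination of the reference window by in-effect days,
the sustained shift and variance inflation, the crisis-day mixture, and
per-value missingness (joint binomial over observed shifted/unshifted
features), pushing each case through the same tail family the scorer
uses (noncentral F for the covariance path; numerically convolved
squared t→normal scores for the sparse path). Its intercept — the
scorer's actual null flag rate, which differs from nominal α through
the trim, fallbacks and edge windows — is measured once per channel on
seeded white noise cut to the cohort's typical enrollment length,
independent of any cohort being evaluated. The oracle assumes
independent days (φ = 0) and treats the local moments as known; it is
validated against Monte-Carlo replicate cohorts under those conditions.

## Changepoints

PELT with L2 cost minimizes Σ within-segment squared deviation +
β·(#changepoints), exactly (pruning is lossless for L2). Missing days
are compressed out and indices mapped back — interpolating across gaps
would manufacture changepoints. Default β = 2σ̂² log n per series with
σ̂ from the MAD of first differences (robust to level shifts). The
correlation stage pairs each monthly score (or score change, optional)
with an indicator of any changepoint within ±10 days of the visit day;
Pearson r with the two-sided t-transform p-value, plus
Benjamini–Hochberg q-values as a labeled extension.

## Naive comparator

Months are consecutive 30-day blocks from enrollment start (calendar
months would be nondeterministic across participants). One row per
enrolled month: age, sex, education (one-hot, first level reference),
monthly means of the medication and psychosis surveys; label 1 iff a
relapse day falls in the block; months with no completed predictor
surveys are dropped. The fit is plain maximum likelihood (IRLS via
statsmodels GLM) — deliberately unregularized and evaluated in-sample.
Quasi-separation (|coef| > 15) is flagged and clipped. Confusion counts
use threshold 0.5, per site and pooled (the pooled "Total" is an
independent refit, not a sum). The *enrichment* comparison uses the
prevalence threshold instead: an in-sample-calibrated model almost
never crosses 0.5 at a ~3% base rate, which would leave the comparison
degenerate at zero-to-three calls; at the prevalence threshold the
comparator commits to calls and its enrichment is stable. Note the
comparator retains enrichment ≈ 2 even with no survey signal at all —
in-sample overfitting on rare labels with ~10 parameters — which is the
honest floor any such baseline enjoys.

## Evaluation

* Confusion at (day × channel) units: a flag within ±30 days of any
  relapse is a TP; unflagged in-window scored units are FN. Scored
  units only — missing days are unobservable and enter no denominator.
  rmse = √((FP+FN)/n), sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP); zero denominators mark a metric undefined,
  never zero.
* Rate ratios: mode `pre` uses the 30 days before each relapse
  (relapse day excluded); `pre_post` ±30 days. Ratio of per-unit flag
  rates inside vs outside.
* Site chi-square: Pearson, no continuity correction.
* Freeman–Halton: exact conditional p by full enumeration of tables
  with fixed margins (≤4×4, total ≤200), p = Σ probabilities ≤ the
  observed table's; a seeded Monte-Carlo mode (scipy `random_table`)
  covers larger tables. 2×2 reduces to Fisher's exact.
* Control-FPR permutation test: per site, FPR(c) = fraction of control
  day-channel p-values ≤ c on a logspaced grid [10⁻⁴, 0.05] (50
  points); trapezoid area over grid points with FPR ≤ 0.25, normalized
  by the grid span. Observed spread = range of per-site areas (variance
  available as an option); control participants' site labels are
  permuted preserving per-site counts; p = proportion of permuted
  spreads ≥ observed (plain proportion, no add-one correction —
  degenerate ties give a conservative p = 1).

## Problem sizes and defaults used in the shipped checks

The test suite validates calibration on 3000–5000-day null matrices,
oracle equivalence on 50–100 randomized instances, permutation size on
200 replicates of 15 synthetic controls, and signal recovery on six
replicate scaled-down cohorts (66 participants, 120 ± 40 d, φ = 0 — the
oracle's stated conditions). The acceptance script runs the full
132-participant pipeline once. These sizes were chosen so the whole
suite exercises every claim at useful power while staying quick to run.

## Known limitations

* Gaussian streams are not range-clipped (a simulated sleep duration
  can stray outside [0, 24]); the analysis treats values abstractly.
* The anomaly p-values assume locally exchangeable, conditionally
  Gaussian days; autocorrelation and correlated-plus-missing features
  degrade calibration as quantified above.
* Missingness is independent Bernoulli by default; a burst-missingness
  (phone-off) mode is not implemented, so engagement-driven gaps are
  only represented through the quality channel's level.
* In-sample evaluation throughout — there is no holdout, and the
  comparator's apparent skill includes an overfitting component by
  design.
* The raw-event feature derivations (home anchor by nighttime density
  clustering, sleep from low-activity screen-off runs, screen sessions)
  are reconstructions fixed for testability, not published definitions.
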