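# relapsekit

Tools for studying whether smartphone digital phenotyping can anticipate
psychotic relapse. The package simulates multi-site longitudinal cohorts
of people with schizophrenia and healthy controls — daily survey scores,
passive sensor aggregates (sleep, time at home, screen use), and
data-quality ratios, with realistic missingness and injected relapse
signatures — and runs the full analysis such data calls for:

* **Daily multivariate anomaly detection.** Every participant-day, per
  collection channel (active surveys / passive sensors / data quality),
  is scored against a kernel-weighted local Gaussian model of the
  surrounding ±30 days. The squared Mahalanobis distance of the day's
  observed feature sub-vector is converted to a finite-sample-calibrated
  p-value; days with *p* ≤ 0.005 are formal anomalies, attributed to
  clinical feature groups (symptoms, sociability, medication, sleep,
  home-time & screen, engagement).
* **Changepoint detection.** Each passive stream is segmented exactly by
  PELT with an L2 cost; changepoint presence within ±10 days of a
  monthly questionnaire is correlated (Pearson) with the survey score.
* **A naive comparator.** A logistic regression on participant-months
  (demographics + monthly means of the medication-adherence and
  psychosis surveys) predicting whether a relapse fell in each 30-day
  block.
* **Evaluation statistics.** Windowed confusion matrices at
  (day × channel) units with a ±30-day true-positive window,
  RMSE/sensitivity/specificity, anomaly-rate enrichment before and
  around relapses, relapse labeling from ≥25% PANSS increases, the
  site chi-square, the Freeman–Halton exact test, and a permutation
  test comparing truncated control false-positive-rate curves across
  sites.

The model at the core: for day *t* with observed features
*x<sub>t</sub>* ⊂ ℝ<sup>f</sup>, reference days *s* ∈ [*t*−W, *t*+W]\{*t*}
weighted *w<sub>s</sub>* = exp(−(s−t)²/2h²) give robust (outlier-trimmed)
moments μ̂<sub>t</sub>, Σ̂<sub>t</sub>;
*d²<sub>t</sub>* = (x<sub>t</sub>−μ̂<sub>t</sub>)ᵀΣ̂<sub>t</sub>⁻¹(x<sub>t</sub>−μ̂<sub>t</sub>)
is referred to a Hotelling-T²→F tail with the kernel's effective sample
size (or exact per-feature t→normal scores and a χ²<sub>f</sub> tail
when missingness is too heavy for a covariance estimate). Defaults:
W = 30 d, h = 10 d, α = 0.005.

## Worked example

```python
import relapsekit as rk

report = rk.run_pipeline(rk.RunConfig(seed=1, outdir="demo_run",
                                      n_perm=1000, make_plots=False))
print(report["n_scored_units"], report["n_anomalies"])
print(round(report["rate_ratio_pre"], 2), round(report["rate_ratio_pre_post"], 2))
print(report["anomaly"]["Total"]["metrics"])
print(round(report["permutation"]["p"], 3))
```

prints (seed 1, default 132-participant three-site cohort):

```
60135 534
3.16 3.51
{'rmse': 0.243, 'sensitivity': 0.028, 'specificity': 0.992}
0.134
```

Read: the anomaly stage scored 60,135 participant-day-channels and
flagged 534 anomalies at *p* ≤ 0.005. Flags were 3.16× more frequent in
the 30 days before a relapse (3.51× in the month either side) than in
relapse-free time — the injected behavioral signature is recovered. The
windowed confusion metrics show the characteristic regime of this
design: near-perfect specificity, tiny per-day sensitivity (anomalies
are rare point events inside long relapse windows). The permutation
*p* = 0.134 means the spread of per-site control FPR areas is
unremarkable under site-label exchange — detection behaves comparably
at all three sites, as built.

A command-line interface mirrors the library:

```bash
relapsekit simulate --seed 1 --out run/          # write cohort CSVs
relapsekit detect   --seed 1 --out run/          # anomalies.csv
relapsekit run-all  --seed 1 --out run/ --n-perm 1000
```

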