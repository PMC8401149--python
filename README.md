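# frailmark

Selection of a minimal set of pendant-sensor physical-activity features
("digital biomarkers") that identify physical frailty and its phenotypes.
The package implements the full analysis pipeline as tested, reusable code:

* **`synthetic_cohort`** — seedable generator of participant tables with a
  robust vs pre-frail/frail two-group structure, five binary phenotype flags,
  and twelve activity features (walking cadence, postural-transition counts
  and durations, walking bouts and steps, and the four posture percentages,
  which respect the compositional constraint of a 24-h day). Per-group means
  and SDs match the configured targets via moment-matched truncated-normal,
  log-normal and censored-Gaussian marginals; a shared severity factor makes
  the joint separability of the feature set tunable.
* **`descriptives`** — two-group comparisons with Shapiro–Wilk normality
  screening (t test or exact/asymptotic rank-sum), BMI-adjusted
  least-squares group effects, chi-square for gender, and standardized
  mean differences (unweighted pooled SD) with magnitude bands.
* **`logit_core`** — self-contained binary logistic regression (IRLS with
  automatic ridge fallback on separation, instrumented fit counter),
  rank-based ROC AUC, confusion-matrix metrics (sensitivity, specificity,
  accuracy, PPV, NPV), and the fixed-coefficient four-feature frailty scorer.
* **`phenotype_models`** — the five fixed-feature-set logistic models
  (physical frailty, slowness, weakness, exhaustion, inactivity) with
  in-sample AUCs.
* **`rfe_bootstrap`** — balanced bootstrap training/out-of-bag pairs
  (majority class subsampled to the minority size, stratified resampling),
  recursive feature elimination by mean AUC over pairs (leave-one-out or
  univariate criterion), metric curves with 95% CIs along the ranking,
  band-constrained optimal-set selection with phenotype-class coverage, and
  out-of-bag validation.
* **`cli_io`** — cohort CSV readers/writers with schema and invariant
  validation, YAML configuration, CSV/JSON report assembly, and the CLI.

## CLI

```sh
frailmark simulate --seed 1 --out cohort.csv
frailmark describe --cohort cohort.csv --out results/describe
frailmark phenotype-models --cohort cohort.csv --out results/models
frailmark rfe --cohort cohort.csv --seed 1 -b 2000 --out results/rfe
frailmark validate --cohort cohort.csv -b 2000 \
    --features standing_pct,walking_pct,walking_cadence,longest_walking_bout \
    --out results/validation
frailmark score --standing-pct 17.9 --walking-pct 6.8 \
    --cadence 115.3 --longest-bout 1372.7
```

Every subcommand that writes output emits CSV tables plus a `manifest.json`
echoing the seed and configuration, so runs are bit-for-bit reproducible.
`--cohort` may be omitted to run on a synthetic default cohort (73 robust +
186 frail participants). The full `rfe` run at `-b 2000` performs exactly
130,000 logistic fits (2000 pairs × Σ k for k = 11 … 2) and takes a few
minutes on one CPU.

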