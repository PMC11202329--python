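# Methods

## The problem

Hospitals are commonly reimbursed through case-mix tools that collapse the
diagnoses and procedures of a hospitalization into a manageable number of
payment groups. Two families of groupers are compared here on episode-level
cost data:

- **DRG-severity**: the Cartesian combination of a base diagnosis-related
  group and a 1–4 severity level (the grouper used by APR-DRG-style
  payment systems).
- **The Queralt system**: additive complexity indices — QID = QIDP + QIDA +
  QIDC for diagnoses (main diagnosis, comorbidities on admission,
  in-hospital complications) and QIP = QIPP + QIPS for procedures — whose
  distributions are cut into ordered complexity strata (D_strata,
  P_strata) and combined into an exhaustive Cartesian DP stratification
  (DP_strata, on the order of 600 groups under the default 30 × 20 grid).

Real episode-level hospital cost data are confidential, so the package
pairs the comparison machinery with a synthetic-episode generator that
reproduces the statistical structure such an analysis faces. Every result
the package reports is computed, at run time, on that synthetic population
(or on any episode CSV with the same schema).

## The synthetic cost model

Each episode carries demographics, a base diagnostic group, a severity
level, five complexity sub-indices and a cost. Log cost is additive:

```
log C = m + b_g + s·(sev − 1) + p·z(QIP) + log(a_age · a_sex) + ε,   ε ~ N(0, σ²)
```

| parameter | default | units | role |
|---|---|---|---|
| `global_log_mean` (m) | 7.836 | log-euros | intercept; calibrated so the default median cost lands near €2,616 |
| `base_effect_sd` (sd of b_g) | 0.37 | log-euros | spread of the 300 base-group effects, drawn N(0, sd) per group |
| `severity_effect` (s) | 0.26 | log-euros/level | cost increment per severity level above 1 |
| `procedure_effect` (p) | 0.52 | log-euros | coefficient on the standardized procedure index z(QIP) |
| `noise_sd` (σ) | 0.40 | log-euros | residual spread within cells |
| `zipf_exponent` | 1.1 | — | base-group frequencies ∝ rank^−1.1 (a few dominant groups, a long tail of rare ones) |
| `severity_decay` | 0.55 | — | P(severity = l) ∝ 0.55^(l−1): mild admissions vastly outnumber severe ones |
| `severity_index_gradient` | 0.8 | — | gamma scale of every sub-index grows by 80% per severity level |
| `indirect_fraction` | 0.2554 | — | target indirect share of total cost, Beta-jittered per episode (concentration 50) |

Sub-indices are gamma-distributed (shapes 1.2–2.0), rounded to integer
index points, with severity-increasing scale — non-negative, right-skewed,
and correlated with severity, as additive complexity scores are. Age/sex
enter as multiplicative cost factors shaped like published demographic
cost tables (peak at 60–69, male above female); admission frequencies by
decade skew old with a paediatric bump.

**Calibration.** The defaults were fixed once, before any downstream
result was inspected, from two targets: a median episode cost of ≈ €2,616
and a mean of ≈ €4,935. Their ratio (1.886) pins the total log-scale
dispersion (≈ 1.27 under a pure lognormal; the skew of the gamma-driven
QIP term supplies part of it, so the Gaussian components are budgeted
smaller), and the intercept was then set by matching the simulated median
at n = 200,000. The observed mixture departs from a single lognormal —
severity is discrete and z(QIP) is right-skewed — which is why the
intercept was calibrated numerically rather than set to log 2616.

**What the generator does not emulate.** No ICD-code-level structure (the
sub-indices are drawn directly, not computed from code lists); no
per-service cost ledger (only the episode-level direct/indirect split); no
true APR-DRG assignment logic (base groups are labels); no between-hospital
heterogeneity, seasonality, length-of-stay mechanics, or cost-data errors.
Passing tests therefore show that the comparison machinery is correct and
that the qualitative grouper rankings emerge from this hierarchical cost
structure — not that any specific hospital system would show the same
numbers.

## Groupers and filters

- Strata are cut at the interior quantiles of the observed index
  distribution (a fixed-cut-point mode is available for externally defined
  grids). Intervals are half-open `[low, high)`; stratum 1 is the least
  complex. Tied cut-points — common for heavily discrete indices — are
  merged with a warning, collapsing to fewer strata rather than producing
  empty ones. On the default population the rounded QID yields 26 rather
  than 30 D-strata for exactly this reason.
- The default 30 × 20 D×P grid targets a DP stratification of ≈ 600
  groups; with merged D cut-points the default run observes 518.
- Eligibility mirrors payment-analysis practice: groups with fewer than 25
  episodes are removed (per analysis grouper), and episodes without an
  assignable label are removed and counted separately. The filter is
  idempotent, and removed + retained counts always reconstruct the input.

## Comparison statistics

- **Efficiency**: groups sorted descending by total cost (or episode
  count); the curve of cumulative cost (episode) share against cumulative
  group share. The companion concentration index is the area between the
  curve and the diagonal normalized by the maximum achievable area for
  that group count: 0 = perfectly proportional coverage, → 1 = one group
  carries everything.
- **Homogeneity**: per-group coefficient of variation, sample SD (n − 1)
  over mean. Singleton groups get CV 0 with a flag.
- **Reduction in variance**: one-way ANOVA R² = 1 − SS_within/SS_total,
  computed on raw euros by default with a log-scale option. Raw-scale R²
  on heavy-tailed costs is dominated by the most expensive episodes and is
  noticeably seed-sensitive; the log-scale values are far more stable, and
  the analysis scripts report both. Refinements can only increase RV, so
  DP_strata ≥ max(D_strata, P_strata) holds identically.

## Predictive models

- **High cost** is cost strictly above the 80th/90th/95th percentile
  cut-off (linear-interpolation quantiles; ties at the cut-off count
  negative). The classifier is the logistic regression with the grouper as
  its only categorical predictor — the saturated model, fitted in closed
  form as the per-group empirical rate (identical to the iterative GLM fit,
  which the tests verify). Separated groups (rate 0 or 1) keep the
  empirical rate and are flagged; an add-½ smoothing option exists because
  predictions, not coefficients, are the object of interest. Numeric-index
  predictors (QID/QIP as continuous covariates) use a conventional GLM.
- **Ranking quality**: AUROC as the trapezoid area (equivalently the
  concordance probability with ties counted ½) and AUPRC as the area under
  the step-interpolated PR curve (average precision); linear interpolation
  in PR space is deliberately avoided as biased.
- **Actual cost**: lognormal regression — per-group mean log cost with a
  pooled residual log-SD σ (n − G degrees of freedom) and expected cost
  exp(μ_g + σ²/2), the lognormal mean. The naive exp(μ_g) back-transform
  (the lognormal median) is exposed as an option, as is a plain linear
  (euro-scale group mean) model. Observed and expected distributions are
  compared by a decile + tail quantile table and a two-sample
  Kolmogorov–Smirnov statistic; both vectors are rounded to micro-euros
  first so that float log/exp round-trip noise cannot register as
  distributional distance.
- **Stratification**: because severity levels only mean something within a
  base group, all analyses can be repeated per base group (after the
  25-episode filter) and pooled by treating (base, inner) pairs as the
  groups of a single combined analysis; an episode-weighted mean of the
  within-base RVs is reported alongside.

## Problem sizes and determinism

The analysis scripts and the acceptance script run at n = 200,000 episodes
with the calibrated defaults; unit tests use 8,000–120,000 where the
property under test needs them, and the parameter-recovery check uses
500,000 episodes over 16 DRG-severity cells (≈ 10,000 in the rarest) so
each fitted group mean can be compared to the truth at 3 standard errors.
A single integer seed drives every random draw; identical config + seed
reproduces the episode table and the serialized report byte-for-byte (the
report JSON excludes the output path and carries the config hash, seed and
package version).

## Known limitations

- Raw-euro RV is unstable under the heavy cost tail (see above); compare
  groupers on it only within a run.
- The quantile strata grid is an assumption: the 30 × 20 default reproduces
  the ≈ 600-group scale of a combined DP stratification but is not an
  externally validated cut-point set; `fixed_cutpoints` accepts one when
  available.
- In-sample evaluation only: the models are fitted and scored on the same
  episodes, as payment-grouper assessments conventionally are; no
  cross-validation is attempted.
- The D_strata signal in the synthetic population flows only through the
  severity–index correlation, so its RV is lower than a real diagnostic
  grouper would achieve; the qualitative ordering (DP > P > D) is the
  meaningful output, not the levels.
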