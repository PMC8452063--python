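# Methods

## Estimand and estimators

The target is the genetically moderated treatment effect (GMTE): the average
causal contrast between receiving the genotype-enabled ("full") effect of a
binary treatment and receiving its reduced/absent effect, `β1 − β0` in the
linear interaction outcome model

    Y = γ_Y0 + β1·T·G + β0·T·(1−G) + γ_YG·G + γ_YZ·Z + γ_YU·U + ε_Y.

Five estimators are implemented, each the coefficient of one derived
regressor in an additive model (see the README table).  Identification rests
on different subsets of: PG1 (genotype independent of treatment given
unmeasured confounders), PG2 (genotype independent of confounders), PG3
(genotype independent of outcome given treatment and confounders), Hom (no
treatment effect in the `G = 0` group) and NUC (no unmeasured confounding).
GMTE(0) — the genotype contrast among the *untreated* — targets zero and
serves as a falsification/bias estimate rather than a GMTE estimate; RGMTE
subtracts it from GMTE(1) to cancel shared genotype-outcome bias.

Measured covariates enter every fitted model additively.  Standard errors
are model-based (a heteroskedasticity-robust option exists behind
`EstimandSpec(robust=True)`); p-values are two-sided normal.  The MR second
stage treats the genotype-predicted moderator `T̂* = Ê[T*|G]` as known, so
its SE ignores first-stage uncertainty — anti-conservative in small samples
and flagged (a warning fires below 10 treated carriers; the ratio is never
silently truncated).

### The RGMTE difference/regression identity

`RGMTE = GMTE(1) − GMTE(0)` and "coefficient of `T*` in
`Y ~ T + T* + T̂* + Z`" are algebraically identical when no covariates are
fitted, because the designs then decompose into disjoint treated/untreated
blocks (the test suite asserts equality to 1e-8 relative).  With a *pooled*
additive covariate the two differ by an O(1/n) term (the pooled `Z` slope
couples the blocks); both estimate the same quantity and the package tests
that the gap stays far inside the estimate's standard error.  The regression
form is the default.

## Outcome adapters

All scales are collapsible differences so estimates can be pooled:

- **continuous** — OLS mean differences;
- **binary** — risk differences: logistic regression with the average
  marginal (discrete-contrast) effect and delta-method SE by default, a
  linear-probability fallback behind a flag; separation raises a coded error
  advising the fallback;
- **time-to-event** — additive hazard differences per year from the
  semiparametric additive hazards model with time-constant coefficients,
  fitted by the closed-form Lin–Ying estimating equations with a sandwich
  covariance.  This is hand-implemented (no installed package offers the
  constant-coefficient form; time-varying cumulative-coefficient fits are a
  different estimand) and is validated against the occurrence/exposure
  closed form and exponential-data oracles.  The baseline hazard is profiled
  out; left truncation/delayed entry is not modelled — time runs from each
  subject's own origin.  A percent rendering (×100, SEs alike) is a display
  transform only, and mixing percent with raw scales in a combination is a
  coded error.

Non-collapsible scales (odds ratios, Cox hazard ratios) are deliberately
out of scope.

## Combination rule

Inverse-variance weights `w_i = 1/se_i²`; pooled `β̄ = Σw_iβ_i/Σw_i`,
`se = (Σw_i)^{-1/2}`, heterogeneity `Q = Σw_i(β_i − β̄)² ~ χ²_{k−1}` under
homogeneity; a combination is flagged usable when `Q`'s p-value ≥ α
(default 0.05, configurable; failing combinations are still reported with
their Q, mirroring the pass/fail colour coding of the forest plot).  Only
approximately uncorrelated components are enumerated: RGMTE/MR, CAT with
each of GMTE1/RGMTE/MR, and CAT/RGMTE/MR.  RGMTE and MR are strongly
correlated with GMTE(1) and are never pooled with it.  The CAT–MR
correlation is non-zero when the genotype predicts treatment but is ignored
as practically negligible; the known consequence is mild undercoverage
(≈0.91–0.93) of CAT/MR-containing combinations in scenarios with a strong
genotype-treatment path, which is accepted.  Component correlation is also
ignored when computing combined-estimate coverage in the simulator.

## Confounder diagnostics

Each estimator is re-run with a candidate confounder as the outcome
(continuous recipe), the variable excluded from its own adjustment set; a
significant coefficient marks a bias channel.  The verdict *warns* rather
than forces adjustment.  No multiplicity correction by default; a
Bonferroni option exists.  For CAT, the genotype itself is testable, since
carrier-share imbalance between treated and untreated directly biases CAT.

## Simulator: model, presets and magnitudes

The generator follows the structural model in the module docstring: binary
genotype (carrier frequency 0.3), standard-normal measured and unmeasured
confounders (optionally shifted by genotype), logistic-type treatment
assignment with a latent noise term, linear interaction outcome.  The
unmeasured confounder is kept in `dataset.truth` for oracle tests and never
shown to estimators.  One seeded generator drives a run; per-replicate
substreams are spawned deterministically, so equal seeds give bit-identical
summaries.

Scenario presets (true GMTE fixed at −0.5):

| # | violated | active switches |
|---|----------|-----------------|
| 1 | PG3 | `γ_YG = −0.25` |
| 2 | NUC | `γ_TU = 0.5` |
| 3 | PG1 | `γ_TG = 2.0` |
| 4 | PG1, NUC | `γ_TG = 2.0, γ_TU = 1.0` |
| 5 | PG2, Hom | `γ_ZG = 1.0, β0 = 0.25, β1 = −0.25` |
| 6 | all but PG1 | `γ_YG = −0.25, γ_ZG = 1.0, γ_TU = 0.5, β0 = 0.25, β1 = −0.25` |

Shared settings: `γ_T0 = −2.6` (≈9–12% of the cohort treated — a realistic
prescribing rate, and the precision ordering of the five estimators under it
matches the published application of the framework), `γ_TZ = γ_YZ = 0.5`,
`γ_YU = 0.5` fixed non-zero throughout, unit-variance noise everywhere.

Two structural choices deserve note:

- **PG2 is violated through a genotype-linked *confounder*.**  A
  genotype→U path with U not influencing treatment is not confounding at
  all — it is simply an extra genotype-outcome pathway (PG3-type), and it
  would bias GMTE(1)/GMTE(0) outright.  The presets therefore route the PG2
  violation through the *measured* confounder (`γ_ZG`: genotype shifts Z,
  which drives both treatment and outcome).  Covariate adjustment then
  rescues GMTE(1), GMTE(0) and RGMTE exactly, while MR remains biased
  because its fixed first stage (`T̂* = Ê[T*|G]`, no covariates) does not,
  and CAT is biased by the Hom violation — reproducing the canonical bias
  pattern for this scenario.  A genotype→U switch (`γ_UG`) is still
  available to users who want the pure pleiotropy-like path.
- **Magnitudes.**  Violation magnitudes are not identified by any published
  table and only move the biased estimators, so they were fixed once at
  design time from large-sample structural calculations: strong
  genotype-treatment and confounder-treatment effects in scenarios 3/4 so
  the collider-induced RGMTE bias under simultaneous PG1+NUC violation
  (≈ −0.04) is clearly resolvable at 500 replicates, and a negative
  genotype-outcome effect of −0.25 in scenarios 1/6.

In the Monte-Carlo bias-pattern check, an estimator counts as unbiased when
its mean is within `max(2.5% of |GMTE|, 3 MC standard errors)` of the truth.
The practical-equivalence margin absorbs a genuine but negligible O(1)
asymptotic leakage (≈ −0.004) that the pooled-covariate CAT recipe exhibits
when the genotype strongly predicts treatment, while remaining small enough
to detect every structurally biased estimator.

What the simulator does *not* emulate: binary or survival outcomes (those
adapters are validated on dedicated small oracles instead), selection/loss
to follow-up, measurement error, related individuals or population
structure, and multi-valued genotypes.  Passing the scenario suite shows the
estimators behave as the assumption algebra predicts under this linear
Gaussian-confounder world; it does not certify performance under model
misspecification beyond it.

## Reporting conventions

Avoided events: `count = round(β%/100 × person-years)`, rounded half away
from zero at the final integer step only; the 95% interval transforms
`β ∓ 1.96·se` the same way.  The signed count is kept alongside a magnitude
field for prose-style statements.  Forest plots colour singles and passing
combinations in one class, failing combinations in a second, and GMTE(0) in
red as the falsification estimate; rendering is deterministic (fixed layout,
timestamp-free metadata).  The pipeline emits a schema-checked JSON bundle
plus CSV, and identical inputs yield identical bundles.

## Default problem sizes

Monte-Carlo checks run 500 replicates of n = 10,000 (the scenario suite) —
enough for three-decimal means and ±0.03 coverage resolution; the
allele-frequency sweep uses 60 replicates per grid point, which resolves the
precision orderings it asserts.  The acceptance script reruns three
scenarios at the full 500 × 10,000.

## Known limitations

- Single binary genotype contrast; multi-group analyses are expressed as
  repeated pairwise runs against a reference group.
- MR first-stage uncertainty ignored (by recipe); weak instruments warn.
- Additive-hazards coefficients are time-constant by design.
- The heterogeneity gate controls per-combination error only; no
  family-wise control across the nine results.
- Cohort construction (prescription curation, ancestry QC, genotype calling)
  is upstream of this package.
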