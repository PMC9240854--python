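# Methods

`cogcourse` implements the standard analysis chain for a two-wave
neuropsychological follow-up study of a patient cohort (first-episode
schizophrenia spectrum) against healthy controls: normative z-scoring and
domain composites, random-intercept linear mixed growth models,
regression-based reliable change indices (RCI), and
clinically-significant-impairment prevalence and transition analysis. A
seeded synthetic cohort generator provides data with the statistical
structure the downstream stages assume, so the whole chain is testable
without access to clinical data.

## Normative scoring

Raw subtest scores are converted to z-scores against the healthy-control
baseline sample: for subtest *k* with control-baseline mean *m_k* and SD
*s_k* (sample SD, n−1 denominator),

    z = (x − m_k) / s_k        (higher-is-better measures)
    z = (m_k − x) / s_k        (timed, lower-is-better measures)

so a higher z always means better performance. Direction is explicit
per-subtest metadata (the four Color-Word tasks are completion times and
are flipped), never inferred from the data. Follow-up scores are
standardized against the *baseline* control norms — not refreshed
follow-up norms — which is what makes 10-year change and cross-wave
prevalence comparable on one scale.

Eight theory-based domain scores are means of member-subtest z-scores
(learning, memory, attention, psychomotor speed, mental speed, working
memory, verbal fluency, cognitive control; three domains have a single
indicator). The cognitive composite is the mean of the domain scores. A
domain with all members missing is missing, never zero; by default the
composite requires all eight domains observed (the strict composite that
feeds the RCI and impairment analyses), with a configurable relaxed
minimum. Norms export/import as CSV so external normative tables can be
substituted.

Exact properties used as test oracles: the norm sample self-normalizes to
mean 0 / SD 1 per subtest, and z-scores are invariant under any positive
affine rescaling of a subtest's raw scale.

## Growth models

Per domain (and the composite) the group model is

    Y_ij = b1 + u_j + b2·time + b3·group + b4·age + b5·time:group
           + b6·time:age + e_ij

with a subject random intercept u_j (a single variance component —
scaled-identity G matrix), fitted by maximum likelihood (statsmodels
`MixedLM`, `reml=False`). Coding choices:

- group: 0 = control, 1 = patient, so b3 and b5 are patient effects;
- time: years since baseline (0 and ~10);
- age: baseline age, time-invariant, mean-centered on the analysis sample.
  With two waves a within-subject ageing term would be collinear with the
  time effect, so age enters only as a baseline covariate. Whether to
  center age is genuinely open in this design; centering makes the
  intercept the control mean at average age and is what the estimated-
  marginal-mean identities assume.
- p-values: residual-df Wald t (df = n_obs − n_fixed). Satterthwaite or
  Kenward-Roger df are not implemented; at these sample sizes the
  difference is in the third decimal of p.

Per-group growth curves refit the model without the two group terms within
each group, sharing the full-sample age center so intercepts are
comparable. Estimated marginal means are linear combinations of the fixed
effects at requested covariate values; requests outside the observed time
range warn rather than fail.

Degenerate inputs: when the data admit an exact linear fit (zero residual
and intercept variance), the ML variance components are unidentifiable and
the optimizer's Hessian is singular; the fixed effects then fall back to
least squares on the same design (which the ML estimates coincide with)
and the fit is flagged `converged=False`.

## Regression-based reliable change

Within each group and measure, change (follow-up − baseline) is regressed
on baseline by OLS. In centered form the prediction for a subject with
baseline x is

    predicted_change(x) = Ȳ + B·(x − X̄)

with Ȳ the group mean change (absorbing the practice effect), X̄ the group
baseline mean, and B the slope (regression toward the mean). The
individual RCI limits are predicted_change(x) ∓ z_crit·SEE, where SEE is
the residual standard error of the change regression and z_crit the
two-sided standard-normal quantile of the confidence level (1.645 at the
default 90 %). The SEE (not the leverage-adjusted prediction SE) is the
default half-width scale; the leverage-adjusted variant
(`method="prediction"`) is provided for sensitivity analyses. Observed
change strictly below the lower limit is a reliable decrease, strictly
above the upper a reliable increase; boundary ties are conservatively
stable. A regression direction note: we model change on baseline (not
baseline on change); each group gets its own model because patient and
control practice effects differ.

Null calibration is the key operating characteristic: when data are
generated exactly from a group's fitted model with Gaussian residuals, the
expected flag rate is 1 − ci_level, split equally between tails. This is
verified by Monte-Carlo at n = 10,000 within 3 binomial SEs. A model with
SEE = 0 (up to 1e-12 roundoff on the z scale) is flagged `degenerate`:
its limits collapse onto the prediction.

Summaries report, per group × measure, Ȳ, B and the percentage of
complete cases decreasing / increasing (1-decimal), with stability as the
exact complement computed before rounding. Incomplete pairs are counted
and reported, never silently dropped.

## Impairment classification

A domain is impaired when z < −1.5 (strict inequality, control-baseline
scale); a subject is clinically impaired when ≥ 2 domains are impaired.
Both thresholds are configurable. The composite is excluded from the
domain count — it averages the domains, so counting it would double-weight
them. Missing domains are excluded from the impaired count (visible via
`n_observed`); a subject with fewer observed domains than the completeness
rule requires gets a missing status. No age or education correction is
applied to the flags.

The transition analysis stratifies complete two-wave cases by baseline
status. Domain-level moves: "improved beyond threshold" = impaired at
baseline, not at follow-up (decline symmetric). Subject-level: "no longer
impaired" / "became impaired" by the clinical criterion; "all domains at
follow-up" = every considered domain impaired. All percentages are of the
respective baseline stratum. Note one traced corner: a subject impaired on
exactly {learning, memory} at baseline and {learning} at follow-up counts
both as improved-on-a-domain and as no longer clinically impaired. Two
logical invariants are brute-force checked in tests: no-longer-impaired
implies improved on ≥1 domain, and became-impaired implies declined on ≥1
domain.

## Synthetic cohort generator

Each subject's scores are generated on the control-baseline z-scale and
mapped to the raw scale of each subtest:

    latent = −deficit·1[patient] − extra·1[impaired subgroup] + u_j
             + age_slope·(age − age_ref) + time·practice[group] + ε
    raw    = m_k ± latent·s_k          (sign per scoring direction)

with u_j ~ N(0, σ_b²) shared across all subtests of a subject (inducing
the cross-domain correlation the impairment analysis relies on) and
ε ~ N(0, σ_e²) independent per subtest × wave. Defaults emulate the target
study design: 75 patients / 108 controls, baseline ages 26.0 (7.7) vs
31.0 (7.4) years, a 10-year retest interval, a 1 SD global patient deficit
on every subtest, practice effects of 0.03 (controls) and 0.02 (patients)
SD/year — giving 10-year mean changes of ~0.2–0.3 z, the order reported in
long-interval retest studies — an age slope of −0.02 SD per year of
baseline age around a 29-year reference, σ_b = 0.8, σ_e = 0.5, and a
patient subgroup (25 %) carrying an extra 1.0 SD global deficit. All
defaults are overridable; attrition is off by default (the generated
cohort represents the completer sample) but a `random` or
`worst_baseline` wave-2 attrition mechanism is available for bias
experiments, as is a per-subtest MCAR missingness rate.

Two deliberate simplifications, and what they imply for test evidence:

- The within-subject covariance is exactly the random-intercept +
  independent-residual structure the growth model assumes, and effects are
  linear and Gaussian. Passing parameter-recovery and calibration tests
  therefore shows the estimators are correct under their own model, not
  that the model fits real cognitive data (real batteries show
  domain-specific retest correlations, floors/ceilings, and non-Gaussian
  tails).
- The configured `control_baseline_sd` is the latent scale unit; the
  marginal control-baseline SD is √(σ_b² + σ_e²)·s_k (≈ 0.94·s_k at the
  defaults). Downstream z-scoring standardizes by the sample SD, so
  analyses are unaffected; generator-scale effect sizes translate to
  observed-z effect sizes by the factor 1/√(σ_b² + σ_e²).

## Summary statistics

Demographic-table comparisons use the pooled-variance two-sample t from
summary statistics (Welch optional), Pearson chi-square on 2×2 counts
without continuity correction (correction optional), and the paired t on
complete-case differences (zero-variance, nonzero differences are returned
flagged as degenerate rather than as an infinite statistic). No
multiple-testing correction is applied anywhere; p-values are unadjusted.

## Problem sizes used in the shipped checks

The test suite and the acceptance script size their simulations for
precision per unit cost: n = 10,000 for RCI null calibration (binomial SE
0.3 percentage points), n = 400 subjects for growth-model parameter
recovery, 20 replicate seeds of n = 1,000 for the effect-size calibration
of the generator, and the default 183-subject cohort for the end-to-end
run. Full runs complete in well under a minute on one CPU.

## Known limitations

- Two waves only; the linear time effect is unidentifiable from
  nonlinearity with this design, and random slopes are deliberately not
  offered.
- The RCI was designed for shorter retest intervals; over a decade it
  conflates practice with development. This is a property of the method,
  reproduced faithfully.
- Chi-square and paired-t helpers consume already-scored columns; no
  clinical instrument scoring is implemented.
- Wald residual-df p-values are anti-conservative relative to
  Satterthwaite at small n; with ~180 subjects the effect is negligible.
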