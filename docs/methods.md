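# Methods

## Estimands and models

The causal question is how much of the association between a childhood
exposure `A` (abuse or neglect, scored from a five-item childhood-trauma
screener) and an adult disease `Y` runs through a binary lifestyle
mediator `M` (smoking or overweight) whose onset predates the diagnosis.
Identification follows the standard regression-based natural-effects
framework with an exposure–mediator interaction: conditional on
covariates `C` (baseline age, sex, study center, education years), the
exposure is assumed unconfounded with mediator and outcome, the
mediator–outcome relation unconfounded given `(A, C)`, and no
mediator–outcome confounder is itself affected by the exposure.  None of
these assumptions is testable from the data; the time-sequencing rules
below remove one specific violation (reverse causation from diagnosis to
mediator) and nothing more.

Binary outcomes use a log-link model with a Poisson working likelihood
("modified Poisson regression"), so exponentiated coefficients are risk
ratios without a rare-outcome approximation; its variance misspecification
on 0/1 data is absorbed by the HC0 sandwich covariance.  Binary mediators
use logistic regression.  With

```
log E[Y|a,m,c]   = θ0 + θ1 a + θ2 m + θ3 am + θ4'c
logit P(M=1|a,c) = β0 + β1 a + β2'c
p(x) = expit(β0 + β1 x + β2'c)
```

the counterfactual mean is integrated exactly over the binary mediator:

```
Q(a, a*) = exp(θ0 + θ1 a + θ4'c) · [(1 − p(a*)) + p(a*) exp(θ2 + θ3 a)]
```

Two-way decomposition: `RR_PDE = Q(1,0)/Q(0,0)`, `RR_TIE = Q(1,1)/Q(1,0)`,
`RR_TE = RR_PDE · RR_TIE`, `PM = RR_PDE(RR_TIE − 1)/(RR_TE − 1)`.
`PM` is undefined (flagged, reported as NaN) when `RR_TE = 1`.

Four-way decomposition, with `R(a,m)` the model risk and `D = Q(0,0)`:

```
ERR_CDE    = (R(1,0) − R(0,0)) / D
ERR_INTref = (Q(1,0) − Q(0,0)) / D − ERR_CDE
ERR_PIE    = (R(0,1) − R(0,0)) (p(1) − p(0)) / D
ERR_INTmed = (Q(1,1) − Q(1,0)) / D − ERR_PIE
```

These are the potential-outcome components (CDE = E[Y(1,0) − Y(0,0)],
INT_ref = E[(Y11 − Y10 − Y01 + Y00) M0], and so on) rescaled by
E[Y(0, M(0))], so they sum exactly to `RR_TE − 1`, and
`ERR_CDE + ERR_INTref = RR_PDE − 1` while
`ERR_PIE + ERR_INTmed = RR_PDE (RR_TIE − 1)`.

One subtlety deserves emphasis: the two interaction components measure
**additive** interaction on the risk scale — they are proportional to
`RR11 − RR10 − RR01 + 1` (the relative excess risk due to interaction,
RERI) — and therefore do *not* vanish when the multiplicative product
term `θ3` is zero while both main effects are non-null.  What does hold
at `θ3 = 0` is the multiplicative statement `RR_PDE = exp(θ1) = RR_CDE`.
The unit tests assert both the correct additive-null condition
(`θ3 = log(e^θ1 + e^θ2 − 1) − θ1 − θ2` zeroes the components exactly)
and this multiplicative collapse.

For the age-at-diagnosis outcome (affected participants only) the linear
analogue is used: `Q_lin(a, a*) = φ0 + φ1 a + φ4'c + (φ2 + φ3 a) p(a*)`,
with effects on the mean-difference scale.

## Interval estimation

Default inference is the multivariate delta method over the stacked
coefficient vector `(θ, β)` with a block-diagonal joint covariance:
sandwich (HC0) for the outcome fit, model-based for the logistic
mediator fit, matching separate-equation estimation.  Gradients are
central finite differences with relative step `1e-6` (analytic gradients
would have to match these to 1e-6 relative to be admitted).  Risk ratios
get normal intervals on the log scale; `PM` and the ERR components get
identity-scale intervals, which can legitimately cross 0% or exceed
100% when the total effect is near null — such intervals are reported,
not truncated.  A row-resampling bootstrap (refitting both models per
resample, percentile intervals) is available and captures the
cross-model covariance the block-diagonal approximation ignores; on
correctly specified simulations the two agree (the test suite requires
the delta SE of `PM` within 10% of the bootstrap SD).

A Monte-Carlo potential-outcome oracle (`monte_carlo_oracle`) simulates
`M(a*)` and `Y(a, m)` directly from the two models and averages over
independent batches; it is the independent check for every closed form.

## Time-sequencing and derivation rules

* **Exposure scoring.**  Abuse = emotional or physical abuse item ≥ 3,
  or sexual abuse item ≥ 2; neglect = emotional or physical neglect
  item ≤ 2 (the neglect items are positively phrased).  Records with any
  missing or out-of-range item are excluded, never imputed.
* **Reference age.**  Cases use the age at first diagnosis of the
  disease under analysis; non-cases use the baseline age.  The data
  define timing only relative to a diagnosis, so the baseline-age
  convention for unaffected participants is a documented assumption.
* **Tie-break.**  "Before" is a strict inequality: initiation or a
  milestone at exactly the reference age does not count.
* **Smoking.**  Never smokers are the reference (0).  `ever_smoking` is
  1 iff initiation age < reference age; initiation at or after it codes
  0.  Under the `current_smoking` sensitivity variant, smokers who quit
  before the reference age are excluded, leaving a never-vs-current
  comparison.  An ever smoker without an initiation age is excluded.
* **Overweight.**  Milestones are the assessment ages themselves
  (10: higher weight than peers; 18/30/50: BMI ≥ 25, inclusive, using
  the measured baseline height).  `early_overweight` uses ages {10, 18};
  the `early_overweight_18plus` variant drops the age-10-only route;
  `late_overweight` uses {30, 50}.  Weights at 30/50 are structurally
  absent for participants younger than those ages and then simply cannot
  qualify.
* **Exclusion ledger.**  One reason per row, attributed in a fixed
  order: missing CTS, missing smoking information, missing weight
  history, missing disease history, missing education, then missing age
  at diagnosis, diagnosis before 18, and the variant-specific
  quit-before-diagnosis rule.  The ledger reconciles exactly
  (input = retained + Σ excluded) on every run.
* **Cancer subtypes.**  The first-tumour site maps to smoking-related
  and obesity-related cancer via fixed site lists; breast counts as
  smoking-related only for women; unknown sites classify as neither and
  are counted in the run log.  Participants with a cancer of the other
  subtype remain in the risk set as non-cases of the subtype analysed.
  Colorectal sites are carried as the single vocabulary term
  `intestines`.

## Synthetic cohort generator

The generator emulates the baseline table of a large adult population
cohort (ages 19–75) with the exact causal structure the analysis
assumes: correlated Bernoulli exposures; one logistic mediator-status
model per mediator; one log-linear Bernoulli disease model per disease
driven by a single mediator with interaction.  Outcomes are Bernoulli
draws with mean `exp(linear predictor)` — the Poisson likelihood is an
estimation device, not a data model — and configurations whose supremum
risk exceeds 1 are rejected by `validate_config`.

Histories are generated *backwards* from the mediator status so the
derivation recovers it: an ever smoker receives an integer initiation
age from a truncated normal (mean 17.9, SD 3) strictly below every
diagnosis age and below baseline; overweight participants qualify via
the age-10 report (45.5% of them, so the 18+ variant retains ≈ 9.3% of
the cohort) or via BMI 25–32 at 18.  Diagnosis ages are truncated-normal
integers (mean 48, SD 10) in [19, baseline age]; the lower bound of 19
keeps every milestone-at-18 strictly before every diagnosis, which is
what makes the round-trip (derived mediator ≡ generative mediator) exact
under the defaults.  A config switch injects initiation-after-diagnosis
records to exercise the timing filter, and per-field-group
missing-completely-at-random rates exercise the ledger.

Default calibration reproduces the published study conditions at the
margins: abuse 16.32% and neglect 14.93% with a phi-correlation fixed by
the 25.82% either-exposure margin; ever smoking 52.80% with exposure
RR 1.23; early overweight 17.09% with RR 1.24; per-disease prevalence,
total-effect RR and proportion mediated solved exactly (closed form plus
one Brent root-find per disease) from the reported values — e.g. MI:
prevalence 1.33%, RR_TE 1.26, PM 36.88%; type 2 diabetes via overweight:
3.97%, 1.33, 13.69%.  The interaction coefficient defaults to 0.05
throughout, matching the reported smallness of interaction effects.
Covariates (age, sex, center, education) match the published marginal
distributions but carry zero generative coefficients by default, so the
adjusted and unadjusted estimands coincide; the estimation side still
adjusts for all of them.  `true_mediation_effects` evaluates the closed
forms on the generative coefficients and is the ground truth for all
recovery experiments.

What the generator does **not** emulate: sampling weights and
recruitment bias, center-level effect heterogeneity, measurement error
in the screener or the weight history, age-dependent disease risk
(diagnosis ages are therefore younger on average than in a real ageing
cohort), dose/intensity of smoking, and any direct generative effect of
the second (non-driving) exposure.  Passing tests show the estimators
recover the assumed data-generating process; they cannot validate the
identification assumptions on real data.

## Numerical choices

* IRLS from zero coefficients with the intercept at the link-transformed
  response mean; step-halving (up to 30 halvings) on working-likelihood
  increase; convergence when the maximum absolute score falls below
  `1e-8 · max(1, n/1000)` — the score is a sum over rows, so its
  numerical floor grows with n while the induced coefficient error stays
  orders of magnitude below coefficient precision.  Hard failure after
  100 iterations, with the score trace attached.
* Logistic fits whose linear predictor exceeds 15 in absolute value are
  declared separated (the score vanishes numerically while the MLE
  diverges) and raise a convergence error.
* HC0 sandwich by default (`hc1=True` applies n/(n−p)); linear fits
  report classical SEs by default and carry HC0 alongside.
* Categorical covariates are reference-coded against the first level in
  sorted order; rank deficiency is detected from the QR diagonal and
  reported with the offending column names.
* Natural effects are conditioned at the covariate means of the analysis
  table of the stratum being analysed (including indicator means),
  overridable through `MediationSpec.c`.
* Cells with fewer than 10 cases, a constant exposure or a constant
  mediator are reported as "not estimable" rather than fitted.
* Study-grid determinism: no randomness enters the delta-method path, so
  identical cohort + configuration yield byte-identical report CSVs
  (floats written with `%.10g`).

## Design choices on open points

* Reference age for non-cases = baseline age (see above).
* The whole-sample and birth-cohort strata adjust for sex; sex strata
  drop it.  Birth cohorts split at birth year 1970.
* No multiple-testing adjustment; the substantive-effect screen
  (RR < 0.9 or RR > 1.1, |β| > 1 year) is the interpretation filter, and
  a cell's gate opens only when all three paths pass it.
* Age-at-diagnosis mediation is implemented (`mediate_linear_outcome`)
  but not part of the default grid, mirroring the decision to stop at
  screening when total effects on diagnosis age are below one year.
* Delta-method inference is the default; whether the original analyses
  used delta or bootstrap intervals is not documented, and both are
  provided.

## Problem sizes

The test suite runs cohorts up to 120,000 participants (margins,
round-trip), 200 + 200 recovery replicates at n = 20,000, 1,000-replicate
Wald-coverage simulations at n = 5,000, 50 coefficient sets against a
10⁶-draw oracle, and a 50,000-participant full-grid determinism run; the
acceptance script uses n = 150,000 for the headline cells and 100
recovery replicates.  These sizes put Monte-Carlo noise well inside the
asserted bands while keeping a full run in minutes on one core.

## Known limitations

* The block-diagonal joint covariance ignores the (usually small)
  cross-model correlation; use the bootstrap when it matters.
* PM is a ratio estimand: near-null total effects make it unstable, and
  its identity-scale intervals can be extremely wide — that is a feature
  of the estimand, not a numerical defect.
* The generator's single-driving-exposure design means ground truth is
  defined for the driving exposure only; the second exposure inherits
  association purely through their correlation.
* Only one mediator at a time; joint multi-mediator decompositions,
  survival outcomes and mediator–outcome confounding sensitivity
  analyses (E-values) are out of scope.
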