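# Methods

## The stated world

The generator's default configuration is the package's definition of
the study population, and every test interprets results against it.
Covariate marginals: rural residence 64%, facility delivery 84% (15% of
facility births private), partnered 86%, no education 14%, wealth band
"less poor" 53%, maternal age Normal(27.3, 6.5) truncated to [13, 49]
years.  Marginals that the source register never published are fixed at
plausible values for the setting and are fully configurable: multiple
births 3%, previous newborn/pregnancy loss 10%, birth-order bands
20/55/25% (1st / 2nd–4th / 5th+), sexes 50/50, birth quarters and the
calendar years 2011–2015 uniform.  Birth order and maternal age are
drawn independently, a simplification (parity rises with age in any
real register) that leaves all marginal and model-based checks intact
because no structural model conditions on their joint distribution.

Structural slopes are the natural logs of the fully adjusted odds
ratios of the three published models (LBW, perinatal, late-neonatal).
Only log-odds make the product-of-coefficients mediation formulas
dimensionally coherent, so the coefficient maps store log-ORs
throughout.  Two quirks of the printed tables are resolved here:

* The late-neonatal table prints education with "no education" as the
  reference and OR 1.24 on "primary+", contradicting the running text
  (at least primary education is protective everywhere else).  The
  labels are read as swapped: 1.24 is attached to the `education_none`
  flag, keeping one education coding across all three models.
* The perinatal table also lists first-order×age interactions; the
  generator and the default fully adjusted model omit them so that the
  data-generating model and the recovery model share one structural
  form.

LBW prevalence is not printed anywhere; the default target is 10%,
typical of published estimates for rural Ugandan birth cohorts.

## Outcome generation

Stillbirth (12/1000 total births), early neonatal death (days 0–6) and
late neonatal death (days 7–27, among first-week survivors) are drawn
sequentially.  Stillbirth is a separate Bernoulli draw per birth, but
its logistic model shares the perinatal slopes (with its own calibrated
intercept): the perinatal outcome *includes* stillbirths, so if
stillbirth were covariate-independent the fitted LBW→perinatal odds
ratio would be attenuated by the stillbirth share and the generating
OR of 2.55 would be unrecoverable by construction.  With shared slopes
the combined rare outcome's log-odds equal the stated values to first
order (exactly, in the rare-outcome limit), and the parameter-recovery
suite confirms it empirically.

Death days within the early window are allocated by the configured
split 0.62 / 0.255 / 0.125 over {days 0–1, days 2–6, days 7–27},
renormalized over the first two bins (the third bin's mass emerges from
the late-neonatal model calibrated to NMR 22/1000 live births).  Within
day 0–1 deaths fall on day 0 with probability 0.75; within bins days
are uniform.  Only the bins enter any analysis.

Birth weight is drawn conditional on the LBW flag: truncated normal
(2.15, 0.30) on [0.80, 2.50) kg for LBW, truncated normal (3.25, 0.45)
on [2.50, 5.50] kg otherwise — means and spreads in line with birth
weight distributions in East African facility data, with the truncation
making weight and flag exactly consistent.

### Internal inconsistencies of the published summary numbers

The published trio PMR 31, SBR 12, NMR 22 together with the day-bin
split implies a 24-hour perinatal share of (12 + 0.62·22·0.988)/31 =
82.2%, not the printed 83%; the printed "14 per 1000 live births on
days 7–27" is inconsistent with NMR 22 and the 62% day-0–1 share and is
not targeted (calibration yields ≈2.8/1000); and truncating age to
[13, 49] shifts the mean to 27.52 versus the printed 27.3.  The
acceptance tests therefore check simulated shares and the mean age
against the analytically consistent stated-world values (with a small
second-order allowance of 0.5 pp on shares for selection effects the
closed form ignores) *and* require proximity to the printed numbers
(1.5 pp on the share, 1% on the age).  The source's overlapping
"days 1–6 = 30.8%" bin is not reproduced; the generator uses disjoint
bins.

## Calibration

`calibrate_intercepts` tunes any intercept by bisection on Monte-Carlo
rate estimates under common random numbers (the same simulation seeds
at every bisection step), which makes the estimated rate a
deterministic monotone step function of the intercept, in structural
order: LBW prevalence → stillbirth rate → perinatal rate → neonatal
rate → the two missingness marginals.  Default tolerances: ±1/1000 on
mortality rates, ±0.5 pp on prevalences and missing fractions.  A
target at or below the simulable floor drives the intercept to the
bracket's lower end (rate ≈ 0); an unreachable target raises a
calibration error naming the rate.  The intercepts frozen in the
default configuration were solved once more precisely against
Rao-Blackwellized expected rates (outcome probabilities averaged over
two million covariate draws, root-found to 1e-8), which is the same
calibration with the outcome-draw noise integrated out; the test suite
verifies the frozen values reproduce every target within Monte-Carlo
error at the study size.

## Missingness and imputation

Birth weight is masked MAR with log-odds +1.5 for community delivery
and +1.0 for perinatal death; wealth with +1.0 for maternal age < 20 —
chosen directions and magnitudes matching the diagnostic the analysis
reports, with intercepts calibrated to the 27% / 19% marginals.  The
LBW flag is missing wherever weight is.

Imputation is by chained equations over the two incomplete variables.
Birth weight uses predictive-mean matching (k = 5 donors, Bayesian
draws of the regression parameters, donors found among the nearest
observed predictions): PMM preserves the empirical weight distribution
near the 2.5 kg threshold that the LBW flag depends on, where a
normal-linear draw would smear it.  The binary wealth band uses
posterior-perturbed logistic draws (Firth-fitted for stability inside
chains).  Predictors are all covariates plus the outcome indicators
(stillbirth, early and late death) as auxiliaries; outcomes themselves
are never imputed.  Defaults: m = 100 in the pipeline's terminology
follows the study scale, but the package default and tests run m = 10
and m = 3–5 respectively with 3–10 sweeps — enough for the two-variable
pattern here, where chains mix in 2–3 sweeps.  Pooling is by Rubin's
rules with the small-sample degrees of freedom
(m−1)(1 + W/((1+1/m)B))².

In this stated world the complete-case bias in overall LBW prevalence
is real but small (~0.1 pp, driven by preferentially missing perinatal
deaths whose LBW prevalence is ~22%): the tests therefore check the
mechanism where it is strong (imputed LBW among missing death records
far exceeds the observed-case prevalence) and the marginal direction
only as an average over replicates.

## Estimation numerics

Maximum-likelihood fits delegate to IRLS (statsmodels GLM,
binomial/logit; dispersion fixed at 1), covariance = inverse observed
information, convergence at score < 1e-8; a fit whose largest |log-odds|
exceeds 15 is flagged non-converged with a pointer to the Firth method.
The Firth estimator maximizes ℓ(β) + ½ log det I(β) by Newton steps
with the hat-diagonal score correction h_i(½ − μ_i) and step-halving on
the penalized likelihood (≤ 100 iterations, ≤ 25 halvings); its Wald
covariance is the inverse penalized information.  Singular information
falls back to a pseudo-inverse with the fit flagged.  All intervals are
Wald (the published intervals are symmetric on the log scale); pooled
intervals use t quantiles at the Rubin degrees of freedom.  Complete-
case estimation is the default, with `n_used` always reported.

The late-neonatal model is a genuinely rare outcome in this world
(~30 events per 10 758-birth cohort against 14 terms): maximum
likelihood there is unstable and its replicate-averaged multiple-birth
OR lands well off the generating value, while the Firth fit recovers it
— so the recovery suite and the acceptance script refit that model with
the Firth penalty, mirroring the rare-events sensitivity rationale.
The perinatal model (~330 events) is refit by plain maximum likelihood.

## Mediation and moderation conventions

The proportion mediated takes its magnitude from |indirect/total| and
its sign from the indirect effect.  This convention reproduces the
published negative percentage for partnered mothers, where both paths
are protective and a plain ratio would be positive; a structurally
absent direct path gives exactly ±100%.  A zero total effect leaves the
proportion undefined (NaN with a warning) — it is a ratio to nothing.
Proportions exceed 100% when the paths oppose; rows are reported sorted
by |proportion|.  Uncertainty is by nonparametric case-resampling
bootstrap with percentile intervals (default B = 500; BCa adds little
at this B and costs stability); resamples that leave an outcome
single-classed or a fit non-converged are dropped and counted, with a
warning above 10%.

The moderation label reads the LBW×facility interaction: "substantial"
if its CI excludes 1, "modest" if |log-OR| < 0.2 with a CI spanning 1,
otherwise "inconclusive".

## What the synthetic cohort does and does not establish

The generator emulates marginal structure, three conditional outcome
models, and a two-variable MAR pattern.  It deliberately omits
village/cluster structure (the source found cross-cluster homogeneity),
migration, gestational age, morbidity, and any covariate-covariate
dependence beyond what the models induce.  A green parameter-recovery
test therefore establishes that the estimation pipeline is consistent
for data generated by the stated models — not that the models are true
of any real register; and calibration checks establish internal
consistency with the published marginals, not external validity.  VIF
screening on synthetic covariates is near-trivial by construction
(independent draws), so the VIF < 10 check guards the implementation,
not the data.

## Known limitations

* Mediation is the classical product-of-coefficients on the log-odds
  scale; with a non-rare outcome, odds-ratio non-collapsibility would
  distort the decomposition (outcomes here are ≤3%, where the effect is
  negligible).  No counterfactual (natural effects) decomposition and
  no exposure–mediator interaction in the decomposition.
* The proportion mediated is unstable when the total effect is near
  zero; bootstrap intervals for it can be enormous (the point is
  visible in the README's adolescent row).
* The wealth-index PCA utility is faithful to the described
  construction but the original asset items are unpublished, so it is
  exercised on synthetic asset tables only.
* No MNAR sensitivity analysis; the MAR mechanisms are the stated
  world's truth, not an estimate.
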