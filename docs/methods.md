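# Methods

This note documents the model, its parameters and defaults, the synthetic
data it runs on, and the numerical and design choices a maintainer would
want to know.  Nothing here states an empirical result the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data situation

The package models five NCDs (CVD, type 2 diabetes, asthma/COPD, breast
cancer, colorectal cancer) in the Gazan population aged 40–80 over a
10-year policy horizon, per 10,000 adults, and compares nine WHO-list
interventions judged locally feasible (WHO ids 1.4, 2.11, 2.13, 3.1, 3.2,
6.2, 6.3, 6.4, 7.3).  The source household-survey microdata are not public,
and the per-intervention effect sizes used in the original assessment were
published only in supplementary material.  The package therefore rests on
three classes of inputs:

1. **Survey marginals** (`data/survey_marginals.yaml`): sex-stratified
   prevalences and moments for a 2020 survey of 4,576 adults (2,103 men,
   2,473 women), feeding the synthetic-population generator.
2. **A published burden panel** (`data/burden_panel.yaml`): per-condition
   10-year incidence, mortality and DALYs per 10,000 at baseline, plus each
   intervention's change-from-baseline, with 95% intervals.  The baseline
   block is the default calibration target set; the change blocks configure
   delta-based cost-effectiveness runs and serve as reference values.
3. **Printed unit costs** (`data/interventions.yaml`) in 2023 international
   dollars, and the $10,992 (= 3 × GDP per capita) willingness-to-pay
   ceiling (`data/economics.yaml`).

Shipped effect-size rate ratios are literature-informed *defaults*, clearly
replaceable; quantitative cost-effectiveness checks use the burden-panel
deltas, not these defaults.

## Synthetic population

Within each sex stratum, a latent Gaussian vector with a configured
rank-correlation matrix drives all variables: continuous variables are
transformed through moment-matched truncated-normal marginals (lognormal
for triglycerides and creatinine, whose survey SDs imply strong right
skew), and booleans are thresholded latent normals at the prevalence
quantile.  Moment matching (a two-parameter root-find on the truncated
moments) makes the realized mean/SD equal the survey values despite the
bounds — without it, the age marginal (females 55.4 ± 10.5 on [40, 80])
would be biased upward by ≈1.3 years.  Sex is binomial (female fraction
2,473/4,576); treatment flags are Bernoulli draws conditional on diagnosis
(95%+ treatment rates for diabetes/hypertension; 79.6% statin use among
dyslipidemia).  HbA1c is generated conditionally on diabetes diagnosis
(13.3%/11.5% for diabetic men/women, ≈5.4% otherwise) because the survey
measured it almost exclusively among the diagnosed.

Two deliberate deviations from the raw survey table: statin use is capped
by dyslipidemia diagnosis (the printed statin marginals slightly exceed the
diagnosis prevalence, which cannot coexist with the treatment⇒diagnosis
invariant the records enforce), and the three blood-pressure readings are
collapsed to a single SBP value since only means are reported.  The default
dependence entries encode only relationships the survey tables imply
(age/BMI → diagnoses and SBP, diagnosis comorbidity, lipid-panel
correlations, smoking concentrated in men); the matrix is validated
symmetric positive semidefinite at load time.  Waterpipe use is generated
but unused by risk scores (tobacco smoking is the modeled exposure).

The laboratory block (lipids, creatinine, HbA1c) can be masked
all-or-none per record at the survey's observed fraction (1,938/4,576) and
re-completed by chained-equations imputation: per-variable regression
sweeps with predictive-mean matching, five chains pooled by averaging.
Matching is by *rank* of the predicted value within each set, which
absorbs the variance mismatch between observed-row and missing-row
predictions (missing rows predict from partially imputed covariates) and
preserves the observed marginal under MCAR; donated values are always
inside the observed range, and observed records are returned bit-exactly.
A regression-tree strategy (`strategy="cart"`) is available; calibration
downstream absorbs small differences between imputation engines.

What the generator does *not* emulate: household/cluster sampling
structure, survey weights, informative lab missingness (the real subset was
selected by care-seeking), within-person measurement error, and any joint
structure beyond the configured latent correlations.  Passing tests
therefore demonstrate correct machinery on a faithful *marginal* emulation,
not validity of the original survey's joint distribution.

## Risk scores and calibration

Score families map a profile to an annual hazard; 10-year risks are
converted by the constant-hazard identity h = −ln(1 − p₁₀)/10.  The CVD
model averages three country-specific 10-year risks (Jordan, Lebanon,
Syria) computed from one linear predictor (age, sex, SBP, total
cholesterol, diabetes, smoking) — the averaging is at the probability
level and is configurable.  FINDRISC is the additive point table; waist
circumference was not surveyed, so the BMI category carries the waist
points (<25 → 0, 25–30 → 1+3, >30 → 3+4) and unsurveyed items (activity,
diet, family history) sit at the population-average of zero extra points.
The asthma/COPD model multiplies an age-trended baseline hazard by
prior-diagnosis and smoke-exposure rate ratios; breast cancer is an
age-band baseline for women times configurable relative risks; colorectal
cancer an age-trended baseline with sex/smoking/BMI multipliers.

Because calibration rescales every condition's hazard level to the burden
targets, results depend on the shipped coefficients only through the
*relative* gradient across individuals.  Calibration solves for one
multiplicative hazard scale per condition by log-scale bisection (50
iterations, default relative tolerance 2%, bracket-shrink asserted), then
one case-fatality scale with the incidence scale held fixed — incidence is
independent of fatality in the engine (fatality removes active cases, who
are no longer at risk), so the two fits decouple cleanly.  The objective is
the engine's expectation mode (below), so it is smooth, deterministic and
strictly monotone until saturation, and an unreachable target (e.g. more
breast-cancer cases than there are women) is reported with the attainable
maximum.

## Simulation engine

Annual cycles, mortality first: an active case faces its condition's
annual case fatality competing with other-cause mortality (hazards
summed; death probability 1 − e^(−Σh); cause allocated ∝ hᵢ), a
disease-free person faces other-cause mortality only; incidence is then
drawn among surviving disease-free individuals.  Other-cause mortality is
a Gompertz curve fitted to the shipped life table's qx column with sex
multipliers (1.2 male / 0.85 female).  The life table
(`data/daly_parameters.yaml`) is a *synthetic*, Gompertz-derived stylized
regional table — not an official extract — and is replaceable.  Surveyed
diabetes and asthma/COPD diagnoses mark prevalent cases at entry (they
accrue YLD and case fatality from year 0); CVD and the cancers start with
no prevalent pool.

**Cause-deleted threads.** Conditions evolve as parallel cause-specific
threads sharing the demographic mortality stream and all underlying
uniforms.  Two requirements force this choice: scenario deltas must be
*exactly* zero for untouched conditions under common random numbers (the
published intervention panels show exact zero rows), and calibration needs
a closed-form expected outcome.  A jointly-competing engine can satisfy
neither (death-timing feedback perturbs other conditions' tallies and
couples the expectation across conditions).  The cost is that
cross-condition survivorship feedback is excluded: a person can in
principle die of CVD in the CVD thread and of diabetes in the diabetes
thread; condition-specific tallies are cause-deleted quantities, and the
totals row is their exact sum.  Other-cause deaths are counted once, from
the shared demographic stream.  The general competing-allocation primitive
(`step_individual` / `competing_death_draw`) handles any number of causes
and is verified against the closed-form allocation formula at 10⁶ draws.

**Expectation mode** propagates per-person state probabilities through the
identical recursion (no Monte-Carlo noise); a Monte-Carlo run at the same
inputs centers on it exactly, which the suite verifies as a dual-route
check.  In expectation mode, reach enrollment is applied as a per-year
coverage weight rather than persistent Bernoulli enrollment — identical at
rate ratio 1 and to first order elsewhere; Monte Carlo is the reference
for scenario point estimates.

**Common random numbers.** One uniform block per decision point (death,
cause, per-condition incidence, reach) is drawn identically in every run
at a given seed, so scenario-minus-baseline differences carry no
between-run noise, scenario hazards are monotone in any scale under fixed
uniforms, and reruns are bit-identical.  A side effect is that deaths are
positively correlated *across* condition threads within a run (the same
death uniform serves every thread), which leaves marginals unbiased but
makes prevalence-driven conditions co-fluctuate across seeds.

**DALYs.** YLD accrues the disability weight for each year lived with the
condition from the onset year, discounted at the configured rate (default
3%, applied to both DALYs and dollars; discrete annual discounting,
annuity(10, 3%) = 8.7861).  The onset year accrues full weight by default
(`onset_weight=1.0`; a half-cycle correction is available via 0.5) and the
death year accrues nothing.  YLL is the discounted remaining life
expectancy at the age of a condition-attributed death, discounted back to
the simulation start.  Disability weights and case fatalities are GBD-style
per-condition defaults collapsed to a single "with condition" state; they
shape DALY levels but no quantitative check depends on their exact values
— burden DALY totals are not calibrated, only incidence and mortality are.

## Interventions, costs, economics

Interventions act multiplicatively on incidence or case-fatality hazards
(or shift a risk factor additively) among reached, eligible individuals.
Reach ramps linearly from zero to the final coverage (default 64%) over
the horizon — reach(t) = final × (t+1)/horizon — with `immediate` and
custom schedules available; enrollment is persistent (a reached individual
stays reached).  Eligibility: whole population for the population-level
interventions; women 50–69 for mammography; diagnosed asthma/COPD for
asthma treatment; incident cases for the two cancer-treatment
interventions (their mortality effect applies only while a case is
active, which makes incident-only eligibility automatic).

Cost bases follow each printed cost sentence: per-person-year across the
whole living population (1.4, 2.11, 2.13, 3.1, 3.2, and 6.2, whose $20
figure is already averaged over sex and the biennial frequency);
per-person-year among reached, living, diagnosed asthma/COPD for 7.3; once
per reached incident case for 6.3/6.4.  Population-wide policy costs do
not scale with reach (everyone bears an enforcement/campaign cost), so the
ICER-invariance-under-reach property applies to the per-reached-person
cost bases, where both numerator and denominator scale linearly.

ICER = discounted incremental cost / discounted DALYs averted, with
dominance labels when either sign flips; classification bands at 1× and
3× GDP per capita ($3,664 / $10,992; boundary in the lower band).  The
delta-configured mode takes scenario DALY reductions directly from the
burden panel and accrues printed unit costs over 10,000 adults
(per-incident-case costs spread evenly over the horizon for discounting;
the eligible fraction for 7.3 defaults to the 9.8% diagnosis prevalence).
Under that arithmetic the smoking ban computes to ≈$41 per DALY averted —
inside the published 95% interval ($17–$50) though above the published $34
point estimate, whose exact cost denominator is not reconcilable from the
printed inputs.  Mammography computes above the ceiling, as published.
The package classifies strictly by the numeric rule; two published prose
classifications ($17,054 and $14,840 described as below the ceiling)
disagree with their own numbers and are not reproduced.

## Uncertainty

PSA is parametric: each parameter gets a (truncated) normal — rate ratios
and cost multipliers on the log scale so draws stay positive, a deliberate
tightening of a plain-normal description that cannot guarantee
admissibility — and the cost-effectiveness computation is re-run per draw,
with common random numbers inside each draw.  Summaries are the mean and
2.5th/97.5th percentiles of the same draw set.  The shipped default
distributions resample each intervention's total DALYs averted (sd from
the published interval width / 3.92) and a lognormal unit-cost multiplier
(CV 20%).  The desk-scale default is 500 draws on the delta-configured
pipeline; full-simulation PSA at the original 10,000 draws is supported
through the same `run_psa` interface with a simulation-backed evaluator.

The reach sweep re-runs baseline and scenario at several final coverage
fractions with a shared seed; DALYs averted and reach-proportional costs
scale linearly within tolerance, leaving the ICER unchanged.

## Problem sizes and defaults

Defaults chosen for desk-scale reproducibility: 2,000 generated records
resampled to 10,000 simulated agents (the reporting denominator), 10-year
horizon, 3% discounting, calibration tolerance 2%, 500 PSA draws.  The
test suite uses 200–20,000 agents depending on the property under test
(20,000 where Monte-Carlo noise must sit well inside published intervals,
with calibration tightened to 0.2% there).  All sizes are configuration,
not constants.

## Known limitations

- Cause-deleted threads exclude cross-condition survivorship feedback
  (intervention spillover onto other conditions' incidence is structurally
  zero, matching the published panels but understating real interactions).
- Condition severity is a single state; no remission, staging or
  complication substates; cancer stage I–II eligibility for 6.3/6.4 is
  approximated by all incident cases.
- The mortality target is interpreted as condition case fatality, not
  attributable excess all-cause mortality (the source is silent).
- Burden DALY totals are emergent, not calibrated; they depend on the
  disability-weight and life-table fixtures.
- The generator emulates marginals plus a configured dependence sketch,
  not the true survey joint distribution; effect-size defaults are
  placeholders pending the original supplementary values.
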