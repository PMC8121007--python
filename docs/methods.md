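# Methods

## Model structure

`htnsim` is a discrete-time individual-level state-transition model with a
one-month cycle. Each simulated person carries fixed attributes (sex,
baseline age, baseline systolic blood pressure, BMI, smoking status) and an
evolving state: one of WELL, ACUTE_MI, ACUTE_STROKE, POST_MI, POST_STROKE,
POST_MULTI, DEAD, plus a lifetime CVD event count. Acute states last exactly
one cycle and house the 30-day probabilities (case fatality, early
reinfarction/stroke); survivors settle into the chronic state matching their
history. POST_MULTI is a bookkeeping refinement for people with two or more
lifetime events: it carries its own disability weight (0.242 chronic, 0.985
during an acute month), a 1.5× relative risk of fatality, and inherits its
chronic mortality/recurrence/outpatient-cost rows from the most recent event
type. DEAD is absorbing.

Within a cycle events resolve in a fixed order: (1) non-CVD death, (2) CVD
death — 30-day fatality in acute states, cause-specific chronic mortality
otherwise, (3) first or recurrent CVD event, (4) risk-factor update (age
advances by 1/12 year every cycle; SBP rises by a per-sex,
per-baseline-SBP-band linear slope once every 12 cycles). Mortality-first
ordering makes acute fatality well defined within the acute month.

## Event probabilities

Ten-year first-event risk follows a proportional-hazards surface:
`risk = 1 − S₀(age, sex)^exp(β·(x − x_ref))` with log-hazard coefficients
for SBP (0.016/mmHg), BMI (0.015 per kg/m²) and smoking (0.30). The
baseline surface S₀ is a synthetic calibration chosen once so that mean
10-year risk by age and sex lands in magnitudes plausible for Indian adults
(≈2.5% at 40–44 rising to ≈40% by the oldest band for men, ~30% lower for
women); it is a documented stand-in for a published office-based risk
equation and is fully swappable through the `risk_model` config block. The
10-year risk converts to a monthly probability under a constant hazard,
`p = 1 − (1 − p₁₀)^(1/120)`, and splits into MI vs stroke by an age/sex
table spanning 37.6–66.7% MI share (declining with age, higher for men).

Chronic recurrence risks (0.079 and 0.014 from post-MI; 0.043 and 0.037
from post-stroke) are implausibly large as monthly probabilities and are
interpreted as **annual**, converted by `1 − (1 − p)^(1/12)`; a config flag
(`chronic_recurrence_is_annual`) disables the conversion for tables already
monthly. Non-CVD death uses annual age/sex rates (geometric ramp 0.005 →
0.176 across 5-year bands, held flat at the top), converted the same way;
ages beyond any table's top band clamp to the top band.

## Treatment

Eligibility: the simplified protocol treats at SBP ≥ 140 mmHg; the NPCDCS
guideline at SBP ≥ 180 mmHg or 10-year risk > 20%. Initiation is restricted
to hypertensive (baseline SBP ≥ 140) eligible individuals. The drug ladder
maps baseline SBP bands 140/160/180 to three steps whose annual costs pin
the published public ($0.88–17.90) and private ($5.42–125.14) endpoints,
with the middle step at the logarithmic midpoint.

Medication multiplies the monthly *first-event* probability by a relative
risk looked up by current age band × baseline-SBP band; tables interpolate
bilinearly between the published corner values (strongest effect young/high
SBP: IHD 0.32, stroke 0.20; weakest old/low SBP: 0.89 both). Treatment
effect on recurrence is not modelled — recurrence probabilities are used as
published. Partial adherence scales efficacy linearly with the compliance
fraction c = 0.503: `RR_partial = 1 − c·(1 − RR_full)`. The RR multiplies
the monthly probability directly rather than acting on the hazard scale; at
monthly probabilities ≪ 1 the two differ negligibly and the direct product
matches the relative-risk semantics of the underlying meta-analysis.

## Care cascade

Coverage (fraction of eligible hypertensives initiated) factors as
awareness × initiation from the baseline pair (0.408, 0.777); adherence
(fraction of initiated who are persistent beyond year 1 *and* highly
compliant) factors as persistence × compliance from (0.61, 0.503). A target
product scales both factors by the common multiplier √(target/(a·b)) —
ratio-preserving on the log scale — capping a factor at 1 and loading the
remainder on the other when it saturates. Cascade positions are drawn once
at baseline (steady-state coverage, no churn); non-persistent individuals
receive drug cost and the *partial*-adherence effect for their first 12
months, then revert to untreated; persistent non-compliant individuals keep
full drug cost (drugs are dispensed regardless of consumption) with the
partial effect. No re-initiation after drop-out. Sector (public/private) is
Bernoulli with the scenario's public fraction and prices both
antihypertensive and secondary medication.

## Costs and DALYs

Costs accrue monthly in US dollars (an INR config divides by the configured
₹70/$ rate at load): ladder-step drug cost and outpatient consultations
(default 4 visits/year, config) while on treatment, a one-time $2.27
diagnostic work-up at initiation, $1,040/$940 inpatient cost per acute
MI/stroke, secondary-prevention medication by dose tier (low for
single-event states, high for POST_MULTI) and sector, condition-specific
outpatient follow-up ($45 IHD, $67 stroke per year), and a flat $0.13 per
cohort member per year of programmatic running cost. The programmatic cost
applies to arms operating the intervention programme — it is constant in
coverage and adherence but absent from the pre-intervention status quo, so
it enters incremental costs (and is what the quadrupled-programmatic-cost
sensitivity scales).

Both costs and DALYs discount at 3%/yr with monthly compounding,
`(1+r)^(−k/12)` at cycle k; no half-cycle correction is applied. YLD =
disability weight × person-months/12 (acute MI 0.432, acute stroke 0.570,
acute second-plus 0.985, chronic IHD 0.08, chronic stroke 0.135, chronic
multi 0.242). YLL attributes the residual life expectancy at the age of
death (per-sex lifetable, India-plausible values, config-replaceable) at
the death cycle, discounted within the remaining lifespan as a continuous
annuity and counted in full even past the simulation horizon, which is
standard practice. The optional daily-medication disutility (0.049 ×
person-years on treatment) is a scenario switch; a YLD-only analysis is
obtained by zeroing the lifetable.

## Scenarios, CRN, and sensitivity analyses

Every random decision is addressed by (master seed, cycle, slot,
individual) through counter-style streams, so arms sharing a seed consume
identical uniforms: the status-quo contrast isolates the intervention, a
zero-effect zero-cost scenario reproduces the comparator's event log
exactly, and raising a coverage or adherence target enrolls a superset of
individuals.

The PSA re-samples, per draw, exactly the parameters shipped with 95%
confidence intervals, independently (no correlation structure is imposed),
from beta distributions moment-matched to mean = point and
sd = CI width/3.92; infeasible moments fall back to the point estimate with
a warning. One published interval (the 0.985 acute second-plus disability
weight) is internally inconsistent as printed; the package uses a symmetric
95% CI (0.981–0.989) with the same spread. Each draw reruns both arms under
a per-draw CRN seed; the probability of cost saving is the fraction of
draws in the dominant quadrant.

The one-way suite holds eight named transforms: doubled antihypertensive
medication cost, quadrupled programmatic cost, 20% lower baseline risk
(multiplicative on the 10-year risk before monthly conversion), the NPCDCS
protocol for the intervention arm, medication disutility on, 10- and
40-year horizons, and an 80% private-sector mix. The ICER is suppressed
whenever a transform averts no DALYs.

The threshold (surcharge) analysis finds the largest uniform multiplicative
surcharge on the intervention arm's total cost that keeps the ICER at the
half-GDP threshold; the ICER is linear in the surcharge, so the bisection
(scipy `brentq`) converges to the closed-form root. Budget impact scales
per-capita deltas linearly to a national 40–69 population (default 267.4
million) per year of horizon.

## Synthetic cohort generator

The generator emulates the risk-factor structure the model consumes: per
sex, ages uniform within 5-year bands over 40–69, truncated-normal SBP
(bounds 80–240 mmHg), normal BMI, Bernoulli smoking (5% female, 32% male).
When a hypertension-prevalence target is set (default 33%, a realistic
figure for Indian adults of these ages), the SBP location parameter is
re-solved analytically so P(SBP ≥ 140) under the truncated distribution
hits the target — comfortably inside the 0.005 calibration tolerance. The
generator does not reproduce survey weights, within-person covariance
beyond the configured marginals, measurement error, or secular trends, so
passing tests demonstrate internal consistency of the model machinery, not
calibration to any real population; plugging in observed profiles via the
cohort CSV interface is the intended route for applied work (profiles are
then used once each, not resampled).

## Numerical and design choices

- **Flat worlds as oracles.** `make_flat_world` zeroes age/sex dependence
  and early/chronic recurrence, making the seven states an exact cohort
  Markov chain; microsimulation means are verified against matrix powers.
  The per-cell "3 standard errors" bound is applied at probe cycles; across
  all ~1,400 (cycle, state) cells the within-3-SE fraction is checked
  against its nominal rate, since the maximum over that many draws exceeds
  3 by chance alone.
- **Reduced-scale presets.** The test suite runs 1,000 individuals per sex
  (and small PSA draw counts); the study-scale configuration is 10,000 per
  sex with 1,000 PSA draws. The directional contrast between coverage and
  adherence increments is small relative to pairing noise at reduced scale
  and is therefore averaged over replicate master seeds.
- **Relative-risk lookups** use the *current* age band (efficacy declines
  with age) and the *frozen* baseline SBP band.
- **1.5× multi-event fatality** applies to chronic mortality and to the
  30-day fatality of second-or-later events.
- Headline study-scale outcomes (probability of cost saving, exact DALY and
  cost deltas) depend on the synthetic risk surface and banded-table
  interiors standing in for proprietary and appendix-level calibrations;
  the package reproduces the qualitative structure of the results (grid
  monotonicity, adherence-vs-coverage asymmetry, sensitivity orderings)
  rather than those exact figures.

## Known limitations

No serious adverse events of treatment, no chronic kidney disease, no
productivity or out-of-pocket costs, no screening logistics or ramp-up
dynamics (cascade changes are instantaneous), no treatment effect on
recurrence, independence of PSA draws, and a stylised SBP trajectory
(linear in age). All are deliberate scope choices mirroring the model's
published framing or gaps in available data.
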