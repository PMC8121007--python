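"""Generate a synthetic cohort and inspect its risk-factor structure.

Builds the default two-sex cohort (here scaled down to 2,000 per sex) of
adults aged 40-69 with truncated-normal systolic blood pressure calibrated so
33% are hypertensive (SBP >= 140 mmHg), then prints the marginal summaries
the downstream risk model consumes.
"""

from htnsim import RiskModel, generate_cohort, make_default_config

bundle = make_default_config()
bundle.population.cohort_size = 2_000
cohort = generate_cohort(bundle.population, seed=1)

df = cohort.to_dataframe()
print(f"cohort size: {len(cohort)} ({(cohort.sex == 0).sum()} female, "
      f"{(cohort.sex == 1).sum()} male)")
print(f"hypertension prevalence (SBP >= 140): {cohort.hypertensive.mean():.3f}")
print(df.groupby("sex")[["age", "sbp", "bmi", "smoker"]].mean().round(2))

risk = RiskModel(bundle.risk_model).ten_year_risk(
    cohort.age, cohort.sex, cohort.sbp, cohort.bmi, cohort.smoker)
print(f"mean 10-year CVD risk: {risk.mean():.3f} "
      f"(females {risk[cohort.sex == 0].mean():.3f}, "
      f"males {risk[cohort.sex == 1].mean():.3f})")
# The prevalence line is the denominator every coverage target refers to;
# the 10-year risks drive both NPCDCS eligibility and monthly event hazards.
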