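"""Eligibility filtering and the score–status correlation.

A country's guideline score can only be expected to predict its median
urinary iodine concentration (mUIC) when iodized salt actually reaches
households, so before correlating we require: ≥70% household coverage
of iodized salt, measured 1–5 years before the mUIC assessment and
more than a year after the standard was issued.
"""

from saltiod import (
    CoverageRecord,
    IodineSpec,
    SaltStandard,
    StatusRecord,
    classify_muic,
    is_eligible,
)

standard = SaltStandard(
    country="XXA", issue_year=2000,
    spec=IodineSpec(form="range", low=30, high=50),
    compounds=("potassium_iodate",),
)
coverage = CoverageRecord(
    country="XXA", pct_households_any_iodized=81.5,
    survey_start_year=2012, survey_end_year=2013,
)
status = StatusRecord(
    country="XXA", muic_ug_L=150.0, assessment_year=2017,
    population="school_age_children",
)

res = is_eligible(standard, coverage, status)
print(f"standard issued {standard.issue_year}, survey "
      f"{coverage.survey_start_year}-{coverage.survey_end_year} at "
      f"{coverage.pct_households_any_iodized}%, mUIC assessed "
      f"{status.assessment_year}")
print(f"eligible: {res.eligible}  (failed criteria: {[c.value for c in res.failed_criteria]})")
print(f"mUIC {status.muic_ug_L} ug/L -> {classify_muic(status.muic_ug_L).value}")

low = CoverageRecord(country="XXA", pct_households_any_iodized=69.9,
                     survey_start_year=2012, survey_end_year=2013)
res = is_eligible(standard, low, status)
print(f"at 69.9% coverage: eligible={res.eligible}, "
      f"failed={[c.value for c in res.failed_criteria]}")
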