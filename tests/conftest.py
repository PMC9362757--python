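import pandas as pd
import pytest

from saltiod import RunConfig, SyntheticConfig, generate


@pytest.fixture(scope="session")
def worked_example_tables():
    """Single-country fixture mirroring the documented worked example:
    a 30–50 ppm range standard, 10 g/day salt intake, standard issued
    2000, coverage survey 2012–2013 at 81.5%, mUIC assessed 2017."""
    standards = pd.DataFrame(
        [
            dict(
                country="XXA", issue_year=2000, iodine_form="range",
                iodine_low=30.0, iodine_high=50.0, iodine_value="",
                basis="iodine", basis_compound="",
                compounds="potassium_iodate;potassium_iodide", scope="both",
            )
        ]
    )
    intake = pd.DataFrame([dict(country="XXA", salt_intake_g_day=10.0)])
    coverage = pd.DataFrame(
        [
            dict(
                country="XXA", pct_households_any_iodized=81.5,
                survey_start_year=2012, survey_end_year=2013,
            )
        ]
    )
    status = pd.DataFrame(
        [
            dict(
                country="XXA", muic_ug_L=150.0, assessment_year=2017,
                population="school_age_children",
            )
        ]
    )
    return standards, intake, coverage, status


@pytest.fixture(scope="session")
def noise_free_bundle():
    """110 synthetic countries with the forward model noise switched off."""
    return generate(SyntheticConfig(n_countries=110, seed=20260920, noise_sigma=0.0))


@pytest.fixture
def table_mode_config():
    return RunConfig(who_mode="table")
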