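"""The synthetic country-table generator and its forward model."""

import numpy as np
import pytest
from scipy import stats

from saltiod import (
    ConfigError,
    IodineSpec,
    SyntheticConfig,
    classify_muic,
    extract_midpoint,
    generate,
    recover,
)
from saltiod.synth import (
    COVERAGE_COLUMNS,
    INTAKE_COLUMNS,
    STANDARDS_COLUMNS,
    STATUS_COLUMNS,
)


def _deterministic_config(**kw):
    base = dict(n_countries=40, seed=123)
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerate:
    def test_zero_countries_yields_empty_tables_with_headers(self, tmp_path):
        bundle = generate(SyntheticConfig(n_countries=0, seed=0))
        paths = bundle.write(tmp_path)
        for name, cols in [
            ("standards", STANDARDS_COLUMNS), ("intake", INTAKE_COLUMNS),
            ("coverage", COVERAGE_COLUMNS), ("status", STATUS_COLUMNS),
        ]:
            text = paths[name].read_text().strip()
            assert text == ",".join(cols)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = _deterministic_config()
        p1 = generate(cfg).write(tmp_path / "a")
        p2 = generate(cfg).write(tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seed_differs(self):
        a = generate(_deterministic_config(seed=1))
        b = generate(_deterministic_config(seed=2))
        assert not a.standards.equals(b.standards)

    def test_closed_form_forward_model(self):
        """compliance 1, multiplier ≡ 1, intake ≡ 10, no noise:
        mUIC = 0.90 × (10 × 19.5 × 0.7) / 1.0 = 122.85 μg/L, adequate."""
        cfg = SyntheticConfig(
            n_countries=5, seed=0, salt_intake_mean=10.0, salt_intake_sd=0.0,
            multiplier_low=1.0, multiplier_high=1.0, compliance=1.0,
            noise_sigma=0.0,
        )
        bundle = generate(cfg)
        muic = bundle.status["muic_ug_L"].to_numpy()
        assert muic == pytest.approx(np.full(5, 122.85), rel=1e-12)
        assert all(classify_muic(m).value == "adequate" for m in muic)

    def test_generated_ranges_contain_their_midpoint(self):
        bundle = generate(_deterministic_config(n_countries=60))
        truth = bundle.truth.set_index("country")
        ranges = bundle.standards[bundle.standards["iodine_form"] == "range"]
        assert len(ranges) > 0
        for _, row in ranges.iterrows():
            low, high = float(row["iodine_low"]), float(row["iodine_high"])
            mid_true = truth.loc[row["country"], "midpoint_mg_kg"]
            assert low < mid_true < high
            spec = IodineSpec(form="range", low=low, high=high)
            assert extract_midpoint(spec) == pytest.approx(mid_true, rel=1e-12)

    def test_muic_linear_in_compliance(self):
        cfg_full = _deterministic_config(noise_sigma=0.0, compliance=1.0)
        cfg_half = _deterministic_config(noise_sigma=0.0, compliance=0.5)
        full = generate(cfg_full).status["muic_ug_L"]
        half = generate(cfg_half).status["muic_ug_L"]
        assert half.median() == pytest.approx(full.median() / 2, rel=1e-12)
        assert np.allclose(half, full / 2)

    def test_baseline_diet_iodine_shifts_muic(self):
        cfg0 = _deterministic_config(noise_sigma=0.0)
        cfg1 = _deterministic_config(noise_sigma=0.0, baseline_diet_iodine_ug=50.0)
        m0 = generate(cfg0).status["muic_ug_L"].to_numpy()
        m1 = generate(cfg1).status["muic_ug_L"].to_numpy()
        # + baseline × excreted_fraction / urine_volume = +45 μg/L
        assert np.allclose(m1 - m0, 45.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(compliance=1.5)
        with pytest.raises(ConfigError):
            SyntheticConfig(noise_sigma=-0.1)
        with pytest.raises(ConfigError):
            SyntheticConfig(multiplier_low=2.0, multiplier_high=1.0)
        with pytest.raises(ConfigError):
            SyntheticConfig(form_probs=(0.5, 0.5, 0.5))

    def test_fraction_above_guideline_matches_uniform_probability(self):
        """With multipliers uniform on [0.68, 3.50], P(m > 1) = 2.5/2.82;
        the empirical fraction at n = 110 sits within 3 binomial SDs."""
        bundle = generate(SyntheticConfig(n_countries=110, seed=5))
        frac = (bundle.truth["multiplier"] > 1).mean()
        p = 2.5 / 2.82
        sd = np.sqrt(p * (1 - p) / 110)
        assert abs(frac - p) <= 3 * sd

    def test_adequate_fraction_matches_lognormal_closed_form(self):
        """With compliance 1 and multiplier ≡ 1 the noiseless mUIC is
        122.85 μg/L; under lognormal noise with σ = 0.15 the adequate
        probability is Φ(ln(122.85/100)/σ) ≈ 0.915 (the 300 μg/L tail is
        negligible).  The pooled empirical fraction across seeds matches
        that closed form within 3 binomial SDs."""
        p_adequate = stats.norm.cdf(np.log(122.85 / 100.0) / 0.15) - stats.norm.cdf(
            np.log(122.85 / 300.0) / 0.15
        )
        n_per, seeds = 110, range(8)
        adequate = total = 0
        for seed in seeds:
            cfg = SyntheticConfig(
                n_countries=n_per, seed=seed, multiplier_low=1.0, multiplier_high=1.0,
                compliance=1.0,
            )
            muic = generate(cfg).status["muic_ug_L"]
            adequate += ((muic >= 100) & (muic < 300)).sum()
            total += n_per
        frac = adequate / total
        sd = np.sqrt(p_adequate * (1 - p_adequate) / total)
        assert abs(frac - p_adequate) <= 3 * sd


class TestRecover:
    def test_noise_free_round_trip_recovers_multipliers(self, noise_free_bundle):
        rep = recover(noise_free_bundle)
        assert rep.max_rel_error < 1e-9
        assert rep.category_counts_match

    def test_round_trip_with_noise_still_recovers_scores(self):
        # mUIC noise never touches the standards, so scores stay exact
        rep = recover(generate(_deterministic_config(noise_sigma=0.3)))
        assert rep.max_rel_error < 1e-9

    def test_designed_eligibility_matches_pipeline(self, noise_free_bundle):
        from saltiod import RunConfig, read_tables, run_pipeline

        tables = read_tables(
            noise_free_bundle.standards, noise_free_bundle.intake,
            noise_free_bundle.coverage, noise_free_bundle.status,
        )
        report = run_pipeline(RunConfig(), tables)
        eligible_design = set(
            noise_free_bundle.truth.loc[
                noise_free_bundle.truth["eligible_design"], "country"
            ]
        )
        assert set(report.linkage["country"]) == eligible_design

    def test_compliance_positively_correlates_scores_with_muic(self):
        """With uniform full compliance, countries requiring more iodine
        excrete more: r(percent_met, mUIC) > 0 for n ≥ 50."""
        from saltiod import RunConfig, read_tables, run_pipeline

        positives = 0
        for seed in range(5):
            bundle = generate(
                SyntheticConfig(n_countries=60, seed=seed, compliance=1.0)
            )
            tables = read_tables(
                bundle.standards, bundle.intake, bundle.coverage, bundle.status
            )
            report = run_pipeline(RunConfig(), tables)
            corr = report.correlations["post_legislation_sac"]
            assert "r" in corr
            positives += corr["r"] > 0
        assert positives == 5
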