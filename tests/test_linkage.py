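"""mUIC classification, eligibility filtering, and correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from saltiod import (
    CoverageRecord,
    DomainError,
    EligibilityCriterion,
    InsufficientDataError,
    IodineSpec,
    MuicClass,
    SaltStandard,
    StatusRecord,
    UndefinedCorrelationError,
    ValidationError,
    classify_muic,
    correlate,
    is_eligible,
    percent_guidelines_met,
)


def _standard(country="XXA", issue_year=2000):
    return SaltStandard(
        country=country, issue_year=issue_year,
        spec=IodineSpec(form="range", low=30, high=50),
        compounds=("potassium_iodate",),
    )


def _coverage(country="XXA", pct=81.5, start=2012, end=2013):
    return CoverageRecord(
        country=country, pct_households_any_iodized=pct,
        survey_start_year=start, survey_end_year=end,
    )


def _status(country="XXA", muic=150.0, year=2017, population="school_age_children"):
    return StatusRecord(
        country=country, muic_ug_L=muic, assessment_year=year, population=population
    )


class TestClassifyMuic:
    @pytest.mark.parametrize(
        "muic,expected",
        [
            (150.0, MuicClass.ADEQUATE),
            (99.9, MuicClass.INSUFFICIENT),
            (100.0, MuicClass.ADEQUATE),
            (299.0, MuicClass.ADEQUATE),
            (300.0, MuicClass.EXCESSIVE),
            (0.0, MuicClass.INSUFFICIENT),
        ],
    )
    def test_boundaries(self, muic, expected):
        assert classify_muic(muic) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_muic(-1.0)

    @given(st.floats(min_value=0.0, max_value=1e4))
    @settings(max_examples=200, derandomize=True)
    def test_total_exclusive_partition(self, muic):
        cls = classify_muic(muic)
        expected = (
            MuicClass.INSUFFICIENT if muic < 100
            else MuicClass.ADEQUATE if muic < 300
            else MuicClass.EXCESSIVE
        )
        assert cls == expected


class TestEligibility:
    def test_worked_example_is_eligible(self):
        """Standard 2000, survey 2012–2013 at 81.5%, mUIC 2017: the
        assessment gap is 4 y ∈ [1, 5] and the survey ran 13 y after the
        standard — eligible on every criterion."""
        res = is_eligible(_standard(), _coverage(), _status())
        assert res.eligible
        assert res.failed_criteria == ()

    def test_coverage_just_below_threshold(self):
        res = is_eligible(_standard(), _coverage(pct=69.9), _status())
        assert not res.eligible
        assert res.failed_criteria == (EligibilityCriterion.COVERAGE_BELOW_70,)

    def test_survey_too_old_for_window(self):
        res = is_eligible(_standard(), _coverage(start=2010, end=2010), _status())
        assert not res.eligible
        assert res.failed_criteria == (EligibilityCriterion.WINDOW_VIOLATION,)

    def test_survey_too_soon_after_standard(self):
        res = is_eligible(
            _standard(issue_year=2012), _coverage(start=2013, end=2013), _status(year=2015)
        )
        assert not res.eligible
        assert res.failed_criteria == (EligibilityCriterion.PRE_STANDARD_SURVEY,)

    def test_failures_enumerated_not_short_circuited(self):
        res = is_eligible(
            _standard(issue_year=2013), _coverage(pct=40.0, start=2013, end=2014),
            _status(year=2016),
        )
        assert set(res.failed_criteria) == {
            EligibilityCriterion.COVERAGE_BELOW_70,
            EligibilityCriterion.PRE_STANDARD_SURVEY,
        }

    @pytest.mark.parametrize("gap,ok", [(0, False), (1, True), (5, True), (6, False)])
    def test_window_inclusive_at_both_ends(self, gap, ok):
        res = is_eligible(_standard(), _coverage(), _status(year=2013 + gap))
        assert (EligibilityCriterion.WINDOW_VIOLATION not in res.failed_criteria) is ok

    def test_country_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            is_eligible(_standard(country="XXB"), _coverage(), _status())

    @given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_coverage(self, p1, p2):
        lo, hi = sorted((p1, p2))
        res_lo = is_eligible(_standard(), _coverage(pct=lo), _status())
        res_hi = is_eligible(_standard(), _coverage(pct=hi), _status())
        if res_lo.eligible:
            assert res_hi.eligible

    def test_reference_year_rule_configurable(self):
        # with the start-year rule the 2012–2013 survey anchors at 2012,
        # putting the 2017 assessment 5 y out — still inside the window
        res = is_eligible(_standard(), _coverage(), _status(), reference_year_rule="start")
        assert res.eligible
        res = is_eligible(
            _standard(), _coverage(), _status(year=2018), reference_year_rule="start"
        )
        assert EligibilityCriterion.WINDOW_VIOLATION in res.failed_criteria


def _scores_from_percents(percents):
    # build ScoreResults whose percent_met equals the requested values
    out = []
    for i, p in enumerate(percents):
        mid = p / 100.0 * 19.5  # continuous WHO amount at 10 g/d
        code = "".join(chr(ord("A") + (i // 26 ** k) % 26) for k in (2, 1, 0))
        out.append(percent_guidelines_met(mid, 10.0, country=code))
    return out


def _statuses_for(scores, muics, population="school_age_children", year=2015):
    return [
        _status(country=s.country, muic=m, year=year, population=population)
        for s, m in zip(scores, muics)
    ]


class TestCorrelate:
    def test_perfect_correlation(self):
        scores = _scores_from_percents([80, 120, 200, 300])
        statuses = _statuses_for(scores, [s.percent_met for s in scores])
        res = correlate(scores, statuses)
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_perfect_anticorrelation(self):
        scores = _scores_from_percents([80, 120, 200, 300])
        statuses = _statuses_for(scores, [400 - s.percent_met for s in scores])
        res = correlate(scores, statuses)
        assert res.r == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        """Pearson r and its t-transform p-value agree with the textbook
        covariance / (σx σy) formula computed from scratch."""
        rng = np.random.default_rng(42)
        percents = rng.uniform(68, 350, size=10)
        muics = rng.uniform(40, 320, size=10)
        scores = _scores_from_percents(percents)
        statuses = _statuses_for(scores, muics)
        res = correlate(scores, statuses)

        x = np.array([s.percent_met for s in scores])
        y = muics
        n = len(x)
        r_oracle = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        t = r_oracle * math.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2 * stats.t.sf(abs(t), n - 2)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    @given(
        st.floats(min_value=0.1, max_value=10.0),
        st.floats(min_value=0.0, max_value=50.0),  # keep rescaled mUIC ≥ 0
    )
    @settings(max_examples=50, derandomize=True)
    def test_affine_invariance_of_r(self, a, b):
        scores = _scores_from_percents([80, 120, 200, 300, 150])
        muics = [110.0, 190.0, 90.0, 260.0, 140.0]
        base = correlate(scores, _statuses_for(scores, muics)).r
        rescaled = correlate(
            scores, _statuses_for(scores, [a * m + b for m in muics])
        ).r
        assert rescaled == pytest.approx(base, rel=1e-9)

    def test_insufficient_pairs_rejected(self):
        scores = _scores_from_percents([80, 120])
        with pytest.raises(InsufficientDataError):
            correlate(scores, _statuses_for(scores, [100, 200]))

    def test_zero_variance_rejected(self):
        scores = _scores_from_percents([100, 100, 100])
        with pytest.raises(UndefinedCorrelationError):
            correlate(scores, _statuses_for(scores, [110, 150, 190]))

    def test_strict_filter_keeps_only_eligible_countries(self):
        scores = _scores_from_percents([120, 200, 250, 300])
        standards = [_standard(country=s.country, issue_year=2000) for s in scores]
        coverages = [
            _coverage(country=s.country, pct=(90.0 if i != 1 else 50.0))
            for i, s in enumerate(scores)
        ]
        statuses = _statuses_for(scores, [120, 150, 180, 210], year=2017)
        res = correlate(
            scores, statuses, filter="strict_eligibility",
            coverages=coverages, standards=standards,
        )
        assert res.n == 3
        assert scores[1].country not in set(res.table["country"])

    def test_post_legislation_filter_requires_sac_after_issue(self):
        scores = _scores_from_percents([120, 200, 250, 300, 150])
        standards = [_standard(country=s.country, issue_year=2000) for s in scores]
        statuses = _statuses_for(scores, [120, 150, 180, 210, 140], year=2017)
        # one WRA-only country and one pre-legislation assessment drop out
        statuses[0] = _status(country=scores[0].country, muic=120, year=2017,
                              population="women_reproductive_age")
        statuses[1] = _status(country=scores[1].country, muic=150, year=1999)
        res = correlate(
            scores, statuses, filter="post_legislation_sac", standards=standards
        )
        assert res.n == 3
        assert set(res.table["population"]) == {"school_age_children"}
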