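"""Unit and property tests for the single-scenario Bayesian chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screenrisk import (
    DegeneratePopulationError,
    ImpossibleResultError,
    InconsistentParametersError,
    ProtectiveMarkerWarning,
    ScreeningError,
    ScreeningScenario,
    TestPerformance,
    UndefinedPrevalenceError,
    disease_given_result,
    evaluate_scenario,
    marker_given_result,
    marker_prevalence,
    prob_positive,
    risk_without_marker,
)
from conftest import random_valid_scenarios


class TestConstruction:
    def test_probabilities_validated(self):
        with pytest.raises(ScreeningError):
            TestPerformance(1.2, 0.9)
        with pytest.raises(ScreeningError):
            TestPerformance(0.9, -0.1)
        with pytest.raises(ScreeningError):
            ScreeningScenario(1.5, 1.0, 1.0, TestPerformance(0.9, 0.9))

    def test_zero_penetrance_rejected(self, stre_test):
        with pytest.raises(UndefinedPrevalenceError):
            ScreeningScenario(0.01, 0.5, 0.0, stre_test)

    def test_inconsistent_triple_rejected(self, stre_test):
        # P(D)*P(M|D) = 0.45 > penetrance 0.3 would put P(M) above 1
        with pytest.raises(InconsistentParametersError):
            ScreeningScenario(0.9, 0.5, 0.3, stre_test)

    def test_implied_no_marker_risk_above_one_rejected(self, snv_test):
        # P(M) <= 1 holds but P(D|M') = P(D)(1-P(M|D))/(1-P(M)) would exceed 1
        with pytest.raises(InconsistentParametersError):
            ScreeningScenario(1.0, 0.743, 0.892, snv_test)

    def test_protective_marker_warns_but_builds(self, stre_test):
        with pytest.warns(ProtectiveMarkerWarning):
            sc = ScreeningScenario(0.5, 0.05, 0.05, stre_test)
        assert sc.penetrance < sc.prior_disease

    def test_unknown_variant_type_rejected(self, stre_test):
        with pytest.raises(ScreeningError):
            ScreeningScenario(0.01, 1.0, 1.0, stre_test, variant_type="SV")


class TestElementaryOperations:
    @pytest.mark.parametrize(
        ("prior", "mfa", "pen", "expected"),
        [
            (0.000410, 1.0, 1.0, 0.000410),  # universal fully penetrant marker
            (0.5, 1.0, 1.0, 0.5),
            (0.00333, 0.0635, 0.439, 4.816743e-4),
        ],
    )
    def test_marker_prevalence(self, stre_test, prior, mfa, pen, expected):
        sc = ScreeningScenario(prior, mfa, pen, stre_test)
        assert marker_prevalence(sc) == pytest.approx(expected, rel=1e-4)

    def test_risk_without_marker(self, stre_test, snv_test):
        htt = ScreeningScenario(0.000410, 1.0, 1.0, stre_test)
        assert risk_without_marker(htt, marker_prevalence(htt)) == 0.0
        c9 = ScreeningScenario(0.00333, 0.0635, 0.439, stre_test)
        assert risk_without_marker(c9, marker_prevalence(c9)) == pytest.approx(
            3.120048e-3, rel=1e-6
        )
        # marker absent from all affected: risk is P(D)/(1 - P(M)) = P(D)
        no_marker = ScreeningScenario(0.01, 0.0, 0.5, snv_test)
        assert risk_without_marker(no_marker, marker_prevalence(no_marker)) == pytest.approx(0.01)

    def test_risk_without_marker_degenerate_population(self, stre_test):
        sc = ScreeningScenario(0.5, 1.0, 0.5, stre_test)  # P(M) = 1
        with pytest.raises(DegeneratePopulationError):
            risk_without_marker(sc, 1.0)

    def test_prob_positive(self, stre_test):
        assert prob_positive(stre_test, 0.000410) == pytest.approx(0.1003649, abs=1e-10)
        assert prob_positive(TestPerformance(1.0, 1.0), 0.3) == pytest.approx(0.3)
        assert prob_positive(TestPerformance(0.0, 1.0), 0.7) == 0.0

    def test_marker_given_result(self, stre_test):
        p_t = prob_positive(stre_test, 0.000410)
        assert marker_given_result(0.000410, stre_test, p_t, "positive") == pytest.approx(
            0.004044243, rel=1e-6
        )
        perfect = TestPerformance(1.0, 1.0)
        assert marker_given_result(0.3, perfect, 0.3, "positive") == 1.0
        assert marker_given_result(0.3, perfect, 0.3, "negative") == 0.0
        # uninformative test: posterior equals prior
        flat = TestPerformance(0.4, 0.6)
        p_t = prob_positive(flat, 0.2)
        assert marker_given_result(0.2, flat, p_t, "positive") == pytest.approx(0.2)

    def test_marker_given_result_impossible_branches(self):
        with pytest.raises(ImpossibleResultError):
            marker_given_result(0.0, TestPerformance(0.0, 1.0), 0.0, "positive")
        with pytest.raises(ImpossibleResultError):
            marker_given_result(1.0, TestPerformance(1.0, 0.0), 1.0, "negative")
        with pytest.raises(ValueError, match="positive"):
            marker_given_result(0.5, TestPerformance(0.9, 0.9), 0.5, "both")

    def test_disease_given_result_is_convex_combination(self):
        assert disease_given_result(1.0, 0.0, 0.004044) == pytest.approx(0.004044)
        assert disease_given_result(1.0, 0.0, 1.0) == 1.0
        lo, hi = sorted((0.3, 0.8))
        assert lo <= disease_given_result(0.8, 0.3, 0.37) <= hi


class TestEvaluateScenario:
    def test_c9orf72_screening(self, c9_screening):
        res = evaluate_scenario(c9_screening)
        assert res.disease_given_positive == pytest.approx(5.189702e-3, rel=1e-6)
        assert res.disease_given_negative == pytest.approx(3.122382e-3, rel=1e-6)

    def test_htt_targeted(self, htt_targeted):
        res = evaluate_scenario(htt_targeted)
        assert res.disease_given_positive == pytest.approx(0.9082569, rel=1e-6)
        assert res.disease_given_negative == pytest.approx(0.01098901, rel=1e-6)
        assert res.relative_risk == pytest.approx(82.65138, rel=1e-6)

    def test_sod1_all(self, snv_test):
        sc = ScreeningScenario(0.00333, 0.0188, 0.701, snv_test)
        res = evaluate_scenario(sc)
        assert res.disease_given_positive == pytest.approx(0.1089779, rel=1e-6)
        assert res.relative_risk == pytest.approx(33.3499, rel=1e-5)

    def test_uninformative_test_returns_prior(self, snv_test):
        sc = ScreeningScenario(0.01, 0.3, 0.6, TestPerformance(0.25, 0.75))
        res = evaluate_scenario(sc)
        assert res.disease_given_positive == pytest.approx(0.01, abs=1e-12)
        assert res.disease_given_negative == pytest.approx(0.01, abs=1e-12)
        assert res.relative_risk == pytest.approx(1.0, abs=1e-9)

    def test_infinite_relative_risk_sentinel(self):
        # universal fully penetrant marker with a perfect test: P(D|T') = 0
        sc = ScreeningScenario(0.1, 1.0, 1.0, TestPerformance(1.0, 1.0))
        res = evaluate_scenario(sc)
        assert res.disease_given_negative == 0.0
        assert math.isinf(res.relative_risk)


class TestInvariants:
    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        pen=st.floats(1e-3, 1.0),
        prior_frac=st.floats(1e-6, 0.999),
        mfa=st.floats(0.0, 1.0),
        sens=st.floats(0.0, 1.0),
        spec=st.floats(1e-3, 0.999),
    )
    def test_total_probability_conservation(self, pen, prior_frac, mfa, sens, spec):
        """The three total-probability identities hold to 1e-12."""
        sc = ScreeningScenario(pen * prior_frac, mfa, pen, TestPerformance(sens, spec))
        r = evaluate_scenario(sc)
        p_d = sc.prior_disease
        assert (
            abs(sc.penetrance * r.marker_prevalence
                + r.risk_without_marker * (1 - r.marker_prevalence) - p_d) < 1e-12
        )
        assert (
            abs(r.marker_given_positive * r.prob_positive
                + r.marker_given_negative * (1 - r.prob_positive) - r.marker_prevalence) < 1e-12
        )
        assert (
            abs(r.disease_given_positive * r.prob_positive
                + r.disease_given_negative * (1 - r.prob_positive) - p_d) < 1e-12
        )
        for value in (
            r.marker_prevalence, r.risk_without_marker, r.prob_positive,
            r.marker_given_positive, r.marker_given_negative,
            r.disease_given_positive, r.disease_given_negative,
        ):
            assert -1e-15 <= value <= 1.0 + 1e-15

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        pen=st.floats(1e-3, 1.0),
        prior_frac=st.floats(1e-6, 0.999),
        mfa=st.floats(0.0, 1.0),
        sens=st.floats(0.0, 1.0),
        spec=st.floats(1e-3, 0.999),
    )
    def test_informative_test_brackets_prior(self, pen, prior_frac, mfa, sens, spec):
        """P(D|T') <= P(D) <= P(D|T) whenever sensitivity + specificity > 1."""
        sc = ScreeningScenario(pen * prior_frac, mfa, pen, TestPerformance(sens, spec))
        if sc.test.sensitivity + sc.test.specificity <= 1.0:
            return
        r = evaluate_scenario(sc)
        assert r.disease_given_negative <= sc.prior_disease + 1e-12
        assert r.disease_given_positive >= sc.prior_disease - 1e-12

    def test_perfect_test_limit(self, c9_screening):
        """Perfect analytic validity leaves penetrance as the only moderator."""
        sc = c9_screening.with_test(TestPerformance(1.0, 1.0))
        r = evaluate_scenario(sc)
        assert r.marker_given_positive == 1.0
        assert r.disease_given_positive == sc.penetrance

    def test_monotone_in_specificity_and_prior(self, c9_screening):
        from screenrisk import sweep

        grid = sweep(c9_screening, {"specificity": np.linspace(0.5, 0.9999, 40)})
        pdt = grid.disease_given_positive
        assert np.all(np.diff(pdt) >= -1e-15)
        grid = sweep(c9_screening, {"prior_disease": np.linspace(1e-5, 0.4, 40)})
        pdt = grid.disease_given_positive
        assert np.all(np.diff(pdt) >= -1e-15)

    def test_conservation_on_random_scenarios(self):
        for sc in random_valid_scenarios(200, seed=11):
            r = evaluate_scenario(sc)
            assert abs(
                r.disease_given_positive * r.prob_positive
                + r.disease_given_negative * (1 - r.prob_positive)
                - sc.prior_disease
            ) < 1e-12
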