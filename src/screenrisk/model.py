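"""Closed-form Bayesian model of post-test disease risk in genetic screening.

The model relates five input probabilities for a disease D, a genetic marker
M, and a test T that asserts the presence of M:

* ``P(D)``      — pre-test (prior) probability of having or later manifesting D;
* ``P(M|D)``    — frequency of the marker among people affected by D;
* ``P(D|M)``    — penetrance: probability of manifesting D for carriers of M;
* ``P(T|M)``    — analytic sensitivity of the assay for detecting M;
* ``P(T'|M')``  — analytic specificity for calling the absence of M.

From these the marker prevalence ``P(M) = P(D) P(M|D) / P(D|M)`` and the
no-marker risk ``P(D|M') = P(D)(1 - P(M|D)) / (1 - P(M))`` follow by Bayes'
theorem, the positive-test rate ``P(T)`` by total probability over marker
status, and the post-test risks ``P(D|T)`` and ``P(D|T')`` as convex
combinations of penetrance and no-marker risk weighted by the posterior
marker probabilities.  Disease is conditionally independent of the test
result given marker status; all events are binary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "TestPerformance",
    "ScreeningScenario",
    "PosteriorResult",
    "ScreeningError",
    "InconsistentParametersError",
    "UndefinedPrevalenceError",
    "DegeneratePopulationError",
    "ImpossibleResultError",
    "ProtectiveMarkerWarning",
    "VARIANT_TYPES",
    "marker_prevalence",
    "risk_without_marker",
    "prob_positive",
    "marker_given_result",
    "disease_given_result",
    "evaluate_scenario",
]

#: Slack used when checking the consistency constraint P(D)·P(M|D) ≤ P(D|M),
#: absorbing binary floating-point representation error.
CONSISTENCY_TOL = 1e-12

VARIANT_TYPES = ("SNV", "indel", "STRE", "CNV-del", "CNV-dup", "other")


class ScreeningError(ValueError):
    """Base class for invalid screening-model inputs."""


class InconsistentParametersError(ScreeningError):
    """P(D)·P(M|D) exceeds P(D|M): the implied marker prevalence would be > 1."""


class UndefinedPrevalenceError(ScreeningError):
    """Penetrance is zero, so P(M) = P(D)·P(M|D)/P(D|M) is undefined."""


class DegeneratePopulationError(ScreeningError):
    """P(M) = 1: everyone carries the marker and P(D|M') is undefined."""


class ImpossibleResultError(ScreeningError):
    """Conditioning on a test outcome that occurs with probability zero."""


class ProtectiveMarkerWarning(UserWarning):
    """Penetrance below the prior: the marker is protective or null."""


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ScreeningError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TestPerformance:
    """Analytic validity of a genotyping or confirmatory assay.

    Parameters
    ----------
    sensitivity : float
        True-positive rate P(T|M) for detecting the marker, in [0, 1].
    specificity : float
        True-negative rate P(T'|M') for calling its absence, in [0, 1].
    label : str
        Free-text assay name.
    """

    sensitivity: float
    specificity: float
    label: str = ""

    __test__ = False  # not a test case despite the class name

    def __post_init__(self) -> None:
        _check_unit(self.sensitivity, "sensitivity")
        _check_unit(self.specificity, "specificity")

    @property
    def is_informative(self) -> bool:
        """True when a positive result raises the odds of carrying the marker."""
        return self.sensitivity + self.specificity > 1.0


@dataclass(frozen=True)
class ScreeningScenario:
    """One screening or targeted-testing scenario: the five model inputs.

    Construction validates each probability and the consistency constraint
    ``prior_disease * marker_freq_affected <= penetrance`` (otherwise the
    implied marker prevalence would exceed 1).  A penetrance below the prior
    describes a protective or null marker; the model remains well defined, so
    such scenarios are accepted with a :class:`ProtectiveMarkerWarning`.
    """

    prior_disease: float
    marker_freq_affected: float
    penetrance: float
    test: TestPerformance
    label: str = ""
    variant_type: str = "other"

    def __post_init__(self) -> None:
        _check_unit(self.prior_disease, "prior_disease")
        _check_unit(self.marker_freq_affected, "marker_freq_affected")
        _check_unit(self.penetrance, "penetrance")
        if self.variant_type not in VARIANT_TYPES:
            raise ScreeningError(
                f"variant_type must be one of {VARIANT_TYPES}, got {self.variant_type!r}"
            )
        if self.penetrance == 0.0:
            raise UndefinedPrevalenceError(
                "penetrance P(D|M) = 0 leaves the marker prevalence "
                "P(M) = P(D)*P(M|D)/P(D|M) undefined"
            )
        if self.prior_disease * self.marker_freq_affected > self.penetrance + CONSISTENCY_TOL:
            raise InconsistentParametersError(
                f"P(D)*P(M|D) = {self.prior_disease * self.marker_freq_affected:.6g} "
                f"exceeds penetrance {self.penetrance:.6g}: implied P(M) > 1"
            )
        p_m = min(self.prior_disease * self.marker_freq_affected / self.penetrance, 1.0)
        if p_m < 1.0:
            implied_rw = self.prior_disease * (1.0 - self.marker_freq_affected) / (1.0 - p_m)
            if implied_rw > 1.0 + CONSISTENCY_TOL:
                raise InconsistentParametersError(
                    f"implied no-marker risk P(D|M') = {implied_rw:.6g} > 1: the "
                    "parameter triple is not a valid joint distribution over (M, D)"
                )
        if self.penetrance < self.prior_disease:
            warnings.warn(
                f"penetrance {self.penetrance:.6g} is below the prior "
                f"{self.prior_disease:.6g}: marker is protective or null",
                ProtectiveMarkerWarning,
                stacklevel=3,
            )

    def with_prior(self, prior_disease: float) -> "ScreeningScenario":
        """Return a copy with a new pre-test disease probability."""
        return replace(self, prior_disease=prior_disease)

    def with_test(self, test: TestPerformance) -> "ScreeningScenario":
        """Return a copy evaluated under a different assay."""
        return replace(self, test=test)


@dataclass(frozen=True)
class PosteriorResult:
    """All quantities derived from one scenario, at full double precision.

    ``relative_risk`` is P(D|T)/P(D|T'); it is ``inf`` when the
    negative-branch risk is exactly zero while the positive branch is not,
    and ``nan`` when both branches are zero.
    """

    marker_prevalence: float
    risk_without_marker: float
    prob_positive: float
    marker_given_positive: float
    marker_given_negative: float
    disease_given_positive: float
    disease_given_negative: float
    relative_risk: float
    scenario: ScreeningScenario = field(repr=False)

    def as_dict(self) -> dict[str, float]:
        """Derived probabilities keyed by conventional symbol."""
        return {
            "P(M)": self.marker_prevalence,
            "P(D|M')": self.risk_without_marker,
            "P(T)": self.prob_positive,
            "P(M|T)": self.marker_given_positive,
            "P(M|T')": self.marker_given_negative,
            "P(D|T)": self.disease_given_positive,
            "P(D|T')": self.disease_given_negative,
            "RR": self.relative_risk,
        }


# ---------------------------------------------------------------------------
# Elementary operations.  Each implements one step of the Bayesian chain and
# accepts plain floats; evaluate_scenario composes them.

def marker_prevalence(scenario: ScreeningScenario) -> float:
    """Population marker prevalence P(M) = P(D)·P(M|D)/P(D|M)."""
    if scenario.penetrance == 0.0:
        raise UndefinedPrevalenceError("penetrance is zero")
    p_m = scenario.prior_disease * scenario.marker_freq_affected / scenario.penetrance
    if p_m > 1.0 + CONSISTENCY_TOL:
        raise InconsistentParametersError(
            f"derived P(M) = {p_m:.6g} > 1; P(D)*P(M|D) exceeds penetrance"
        )
    return min(p_m, 1.0)


def risk_without_marker(scenario: ScreeningScenario, p_m: float) -> float:
    """Disease risk among non-carriers, P(D|M') = P(D)(1−P(M|D))/(1−P(M))."""
    if p_m >= 1.0:
        raise DegeneratePopulationError(
            "P(M) = 1: every individual carries the marker, P(D|M') undefined"
        )
    rw = scenario.prior_disease * (1.0 - scenario.marker_freq_affected) / (1.0 - p_m)
    if rw > 1.0 + CONSISTENCY_TOL:
        raise InconsistentParametersError(f"P(D|M') = {rw:.6g} > 1")
    return min(rw, 1.0)


def prob_positive(test: TestPerformance, p_m: float) -> float:
    """Total probability of a positive result, P(T) = sens·P(M) + (1−spec)(1−P(M))."""
    return test.sensitivity * p_m + (1.0 - test.specificity) * (1.0 - p_m)


def marker_given_result(
    p_m: float, test: TestPerformance, p_t: float, result: str
) -> float:
    """Posterior marker probability P(M|T) or P(M|T') by Bayes' theorem.

    ``result`` is ``"positive"`` or ``"negative"``; the corresponding branch
    denominator (P(T), resp. 1−P(T)) must be non-zero.
    """
    if result == "positive":
        if p_t == 0.0:
            raise ImpossibleResultError("P(T) = 0: cannot condition on a positive result")
        return p_m * test.sensitivity / p_t
    if result == "negative":
        if p_t == 1.0:
            raise ImpossibleResultError("P(T) = 1: cannot condition on a negative result")
        return p_m * (1.0 - test.sensitivity) / (1.0 - p_t)
    raise ValueError(f"result must be 'positive' or 'negative', got {result!r}")


def disease_given_result(
    penetrance: float, risk_without: float, marker_given_result: float
) -> float:
    """Post-test disease risk: penetrance and no-marker risk mixed by P(M|result).

    Disease is conditionally independent of the test given marker status, so
    P(D|T) = P(D|M)·P(M|T) + P(D|M')·(1 − P(M|T)), and likewise for T'.
    """
    return penetrance * marker_given_result + risk_without * (1.0 - marker_given_result)


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return math.nan if num == 0.0 else math.inf
    return num / den


def evaluate_scenario(scenario: ScreeningScenario) -> PosteriorResult:
    """Run the full Bayesian chain for one scenario.

    Returns every derived quantity at full floating precision; any display
    rounding is left to the reporting layer.
    """
    p_m = marker_prevalence(scenario)
    p_d_not_m = risk_without_marker(scenario, p_m)
    p_t = prob_positive(scenario.test, p_m)
    p_m_pos = marker_given_result(p_m, scenario.test, p_t, "positive")
    p_m_neg = marker_given_result(p_m, scenario.test, p_t, "negative")
    p_d_pos = disease_given_result(scenario.penetrance, p_d_not_m, p_m_pos)
    p_d_neg = disease_given_result(scenario.penetrance, p_d_not_m, p_m_neg)
    return PosteriorResult(
        marker_prevalence=p_m,
        risk_without_marker=p_d_not_m,
        prob_positive=p_t,
        marker_given_positive=p_m_pos,
        marker_given_negative=p_m_neg,
        disease_given_positive=p_d_pos,
        disease_given_negative=p_d_neg,
        relative_risk=_ratio(p_d_pos, p_d_neg),
        scenario=scenario,
    )
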