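"""Chained (sequential) testing: a confirmatory assay after a positive screen.

A positive screening result is confirmed by re-running the Bayesian chain
with the screen's posterior disease risk P(D|T) as the new prior, keeping
the marker frequency among affected and the penetrance fixed, and swapping
in the confirmatory assay's sensitivity and specificity.  The two tests are
assumed conditionally independent given marker status — the arithmetic of
multiplying posteriors through is exactly that assumption, and it fails for
assays sharing error modes (e.g. two short-read callers tripping over the
same repeat structure).

The chain is always computed from unrounded stage posteriors: chaining the
rounded value changes the cross-stage relative risk in its third figure.

The cross-stage ("omega") relative risk divides the final-stage positive
risk by the *first* stage's negative-branch risk: the risk ratio between a
person positive on every test and a person dismissed at the initial screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import (
    InconsistentParametersError,
    PosteriorResult,
    ScreeningScenario,
    TestPerformance,
    evaluate_scenario,
)

__all__ = ["ChainResult", "InconsistentChainError", "chain_confirmatory", "chain_external_prior"]


class InconsistentChainError(InconsistentParametersError):
    """A chained prior made P(D)·P(M|D) exceed the penetrance at some stage."""


@dataclass(frozen=True)
class ChainResult:
    """Ordered cascade of test stages.

    ``stages[k]`` is evaluated with its prior equal to ``stages[k-1]``'s
    ``disease_given_positive`` (at full precision).  For a cascade whose
    first test is external to the model (e.g. a metabolic screen), only the
    modelled genetic stage appears in ``stages`` and the first stage enters
    through the prior and the negative-branch risk used for omega.

    ``omega_relative_risk`` = final-stage P(D|T) / first-stage P(D|T');
    ``inf`` when the first-stage negative risk is exactly zero.
    """

    stages: tuple[PosteriorResult, ...]
    omega_relative_risk: float

    @property
    def final(self) -> PosteriorResult:
        return self.stages[-1]


def _omega(final_positive: float, first_negative: float) -> float:
    if first_negative == 0.0:
        return math.nan if final_positive == 0.0 else math.inf
    return final_positive / first_negative


def chain_confirmatory(
    base: ScreeningScenario, *confirm_tests: TestPerformance
) -> ChainResult:
    """Screen with ``base``, then confirm each positive with further assays.

    Each confirmatory stage re-evaluates the model with the previous stage's
    unrounded P(D|T) as prior, the same marker frequency and penetrance, and
    that stage's assay.  Raises :class:`InconsistentChainError` if a chained
    prior violates the consistency constraint (possible only for protective
    parameter corners).
    """
    if not confirm_tests:
        raise ValueError("at least one confirmatory test is required")
    stages = [evaluate_scenario(base)]
    for i, test in enumerate(confirm_tests, start=2):
        prior = stages[-1].disease_given_positive
        try:
            scenario = base.with_prior(prior).with_test(test)
        except InconsistentParametersError as err:
            raise InconsistentChainError(
                f"stage {i} prior {prior:.6g} is inconsistent with "
                f"P(M|D)={base.marker_freq_affected:.6g}, "
                f"penetrance={base.penetrance:.6g}"
            ) from err
        stages.append(evaluate_scenario(scenario))
    return ChainResult(
        stages=tuple(stages),
        omega_relative_risk=_omega(
            stages[-1].disease_given_positive, stages[0].disease_given_negative
        ),
    )


def chain_external_prior(
    prior_after_first_test: float,
    neg_first_test_risk: float,
    genetic: ScreeningScenario,
) -> ChainResult:
    """Genetic confirmation of a positive result from a non-genetic first test.

    The first test (e.g. tandem-mass-spectrometry metabolic screening) is not
    modelled; it enters only through its positive-branch posterior, used as
    the genetic stage's prior, and its negative-branch risk, used as the
    omega denominator.

    Parameters
    ----------
    prior_after_first_test : float
        Disease probability given a positive first-stage result, in [0, 1].
    neg_first_test_risk : float
        Disease probability given a negative first-stage result, in [0, 1];
        zero yields an infinite omega sentinel.
    genetic : ScreeningScenario
        The genetic confirmation scenario; its ``prior_disease`` is replaced.
    """
    for name, value in (
        ("prior_after_first_test", prior_after_first_test),
        ("neg_first_test_risk", neg_first_test_risk),
    ):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    try:
        scenario = genetic.with_prior(prior_after_first_test)
    except InconsistentParametersError as err:
        raise InconsistentChainError(
            f"external prior {prior_after_first_test:.6g} is inconsistent with "
            f"P(M|D)={genetic.marker_freq_affected:.6g}, "
            f"penetrance={genetic.penetrance:.6g}"
        ) from err
    stage = evaluate_scenario(scenario)
    return ChainResult(
        stages=(stage,),
        omega_relative_risk=_omega(stage.disease_given_positive, neg_first_test_risk),
    )
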