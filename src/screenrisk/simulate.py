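"""Monte Carlo population simulator: the brute-force oracle for the model.

The generative factorisation mirrors the analytic chain exactly:

1. marker status  M ~ Bernoulli(P(M)),   with P(M) from the prevalence identity;
2. disease        D|M ~ Bernoulli(P(D|M)),  D|M' ~ Bernoulli(P(D|M'));
3. test result    T|M ~ Bernoulli(sens),    T|M' ~ Bernoulli(1 − spec),
   conditionally independent of D given M.

Generation is vectorised per stratum: a binomial draw for the marker count,
then binomial draws for disease and test counts within each stratum.  The
distribution over the 2×2×2 count table is identical to per-individual
simulation but runs in O(1) random draws, so populations of 1e8 are cheap.

Empirical conditional probabilities are exact ratios of cell sums, with
``nan`` as the explicit undefined sentinel when a conditioning event has
zero count (never 0/0 → 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ScreeningScenario,
    TestPerformance,
    marker_prevalence,
    risk_without_marker,
)

__all__ = ["SimulationResult", "TwoTestSimulationResult", "simulate_population", "simulate_two_tests"]


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


@dataclass(frozen=True)
class SimulationResult:
    """Population counts over (marker, disease, test) and empirical estimates.

    ``counts[m, d, t]`` is the number of individuals with marker status m,
    disease status d and test result t (0/1 indexing along each axis).
    ``empirical`` maps estimator names (``"P(M)"``, ``"P(D|T)"``, ...) to
    exact cell-sum ratios; an estimate conditioned on a zero-count event is
    ``nan``.
    """

    counts: np.ndarray = field(repr=False)
    n: int
    seed: int
    empirical: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """One row per (marker, disease, test) cell, exportable as CSV."""
        m, d, t = np.indices(self.counts.shape).reshape(3, -1)
        return pd.DataFrame(
            {"marker": m, "disease": d, "test": t, "count": self.counts.reshape(-1)}
        )


@dataclass(frozen=True)
class TwoTestSimulationResult(SimulationResult):
    """Adds a conditionally independent second test applied to everyone.

    ``counts2[m, d, t1, t2]`` extends the count table; ``empirical`` gains
    ``"P(D|T1,T2)"`` (disease risk among double positives) and
    ``"P(D|T1')"`` (risk after a negative first test).
    """

    counts2: np.ndarray = field(repr=False, default=None)


def _empirical(counts: np.ndarray) -> dict[str, float]:
    n = int(counts.sum())
    n_m = int(counts[1].sum())
    n_d = int(counts[:, 1].sum())
    n_t = int(counts[:, :, 1].sum())
    return {
        "P(M)": _ratio(n_m, n),
        "P(D)": _ratio(n_d, n),
        "P(D|M)": _ratio(int(counts[1, 1].sum()), n_m),
        "P(D|M')": _ratio(int(counts[0, 1].sum()), n - n_m),
        "P(T)": _ratio(n_t, n),
        "P(M|T)": _ratio(int(counts[1, :, 1].sum()), n_t),
        "P(D|T)": _ratio(int(counts[:, 1, 1].sum()), n_t),
        "P(D|T')": _ratio(int(counts[:, 1, 0].sum()), n - n_t),
    }


def _draw_counts(
    scenario: ScreeningScenario, n: int, rng: np.random.Generator
) -> np.ndarray:
    p_m = marker_prevalence(scenario)
    p_d_not_m = 0.0 if p_m >= 1.0 else risk_without_marker(scenario, p_m)
    sens, spec = scenario.test.sensitivity, scenario.test.specificity

    counts = np.zeros((2, 2, 2), dtype=np.int64)
    n_m = int(rng.binomial(n, p_m))
    for m, n_stratum, p_d in ((1, n_m, scenario.penetrance), (0, n - n_m, p_d_not_m)):
        n_dis = int(rng.binomial(n_stratum, p_d))
        p_pos = sens if m else 1.0 - spec
        for d, n_cell in ((1, n_dis), (0, n_stratum - n_dis)):
            n_pos = int(rng.binomial(n_cell, p_pos))
            counts[m, d, 1] = n_pos
            counts[m, d, 0] = n_cell - n_pos
    return counts


def simulate_population(
    scenario: ScreeningScenario, n: int, seed: int
) -> SimulationResult:
    """Simulate ``n`` individuals under the scenario's generative model.

    Reproducible for a fixed seed; as ``n`` grows every empirical estimate
    converges to its analytic counterpart from :func:`evaluate_scenario`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _draw_counts(scenario, n, rng)
    return SimulationResult(counts=counts, n=n, seed=seed, empirical=_empirical(counts))


def simulate_two_tests(
    scenario: ScreeningScenario,
    confirm_test: TestPerformance,
    n: int,
    seed: int,
    *,
    resample_marker: bool = True,
) -> TwoTestSimulationResult:
    """Simulate a screen followed by a confirmatory assay.

    Two generative readings of "confirm each positive" exist and they are
    **not** equivalent:

    ``resample_marker=True`` (default)
        The stage-wise reading used by the chained calculator: the screen
        positives form a fresh risk group whose disease prevalence is their
        empirical post-test risk, and marker status within that group is
        re-derived from the prevalence identity before the second assay is
        applied.  Empirical ``P(D|T1,T2)`` then converges to
        :func:`screenrisk.sequential.chain_confirmatory`'s stage-2 posterior.

    ``resample_marker=False``
        The joint model: each individual keeps their marker status and the
        second test is drawn conditionally independent of the first given M
        (T2|M ~ Bernoulli(confirm sens), T2|M' ~ Bernoulli(1 − confirm
        spec)).  Proper sequential Bayes on this model multiplies likelihood
        ratios and yields a *higher* double-positive risk than the chained
        calculator — the two coincide only for an uninformative first test.

    The empirical map gains ``P(D|T1,T2)`` (disease risk among double
    positives) and ``P(D|T1')`` (risk after a negative screen); their ratio
    to each other and to the screen's negative branch estimates the
    cross-stage relative risks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _draw_counts(scenario, n, rng)
    empirical = _empirical(counts)
    n_t1 = int(counts[:, :, 1].sum())

    if resample_marker:
        counts2 = np.zeros((2, 2, 2, 2), dtype=np.int64)
        if n_t1 > 0 and not math.isnan(empirical["P(D|T)"]):
            stage2 = scenario.with_prior(empirical["P(D|T)"]).with_test(confirm_test)
            counts2[:, :, 1, :] = _draw_counts(stage2, n_t1, rng)
        # screen negatives are not re-tested; park them at T2 = 0
        counts2[:, :, 0, 0] = counts[:, :, 0]
        n_pp = int(counts2[:, :, 1, 1].sum())
        empirical["P(D|T1,T2)"] = _ratio(int(counts2[:, 1, 1, 1].sum()), n_pp)
    else:
        counts2 = np.zeros((2, 2, 2, 2), dtype=np.int64)
        for m in (0, 1):
            p_pos2 = confirm_test.sensitivity if m else 1.0 - confirm_test.specificity
            for d in (0, 1):
                for t1 in (0, 1):
                    n_cell = int(counts[m, d, t1])
                    n_pos2 = int(rng.binomial(n_cell, p_pos2))
                    counts2[m, d, t1, 1] = n_pos2
                    counts2[m, d, t1, 0] = n_cell - n_pos2
        n_pp = int(counts2[:, :, 1, 1].sum())
        empirical["P(D|T1,T2)"] = _ratio(int(counts2[:, 1, 1, 1].sum()), n_pp)

    n_t1_neg = n - n_t1
    empirical["P(D|T1')"] = _ratio(int(counts[:, 1, 0].sum()), n_t1_neg)
    return TwoTestSimulationResult(
        counts=counts, n=n, seed=seed, empirical=empirical, counts2=counts2
    )
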