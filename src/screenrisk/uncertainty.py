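"""Uncertainty propagation and penetrance estimation.

Input parameters such as the marker frequency among affected people and the
penetrance are typically estimated from modest cohorts and are printed with
95% confidence intervals.  This module propagates those intervals through
the Bayesian chain by Monte Carlo: each uncertain parameter is sampled on
the logit scale from a normal whose mean is the logit of the point estimate
and whose spread is set so the 2.5% and 97.5% quantiles reproduce the stated
bounds.  The logit-normal respects the [0, 1] support of every parameter;
parameters are sampled independently (any covariance between marker
frequency and penetrance estimated from the same cohorts is ignored).

Draws violating the consistency constraint P(D)·P(M|D) ≤ P(D|M) are
discarded and counted, not clipped — clipping would pile mass on the
constraint boundary and bias the output interval.

The module also inverts the marker-prevalence identity to estimate
penetrance from a population marker frequency:
``P(D|M) = P(D)·P(M|D)/P(M)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .model import (
    CONSISTENCY_TOL,
    InconsistentParametersError,
    ScreeningScenario,
    evaluate_scenario,
)

__all__ = [
    "IntervalParam",
    "PropagationSummary",
    "UnstablePropagationError",
    "estimate_penetrance",
    "propagate_interval",
]

#: Scenario fields an IntervalParam may attach to.
UNCERTAIN_PARAMS = (
    "prior_disease",
    "marker_freq_affected",
    "penetrance",
    "sensitivity",
    "specificity",
)

_Z975 = norm.ppf(0.975)


class UnstablePropagationError(RuntimeError):
    """More than half of the Monte Carlo draws violated the model constraints."""


@dataclass(frozen=True)
class IntervalParam:
    """A point estimate with 95% confidence bounds, all in [0, 1]."""

    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.point <= self.upper <= 1.0):
            raise ValueError(
                f"require 0 <= lower <= point <= upper <= 1, got "
                f"({self.lower}, {self.point}, {self.upper})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.lower == self.point == self.upper


@dataclass(frozen=True)
class PropagationSummary:
    """Percentile summary of P(D|T) under input-parameter uncertainty."""

    lower: float  # 2.5th percentile
    median: float
    upper: float  # 97.5th percentile
    n_valid: int
    n_discarded: int
    seed: int


def estimate_penetrance(
    prior_disease: float,
    marker_freq_affected: float,
    marker_freq_population: float,
) -> float:
    """Penetrance implied by disease prevalence and marker frequencies.

    Inverts P(M) = P(D)·P(M|D)/P(D|M) to P(D|M) = P(D)·P(M|D)/P(M).  Raises
    :class:`InconsistentParametersError` when the result exceeds 1, i.e. the
    marker is rarer in the population than the disease arithmetic allows.
    """
    if marker_freq_population <= 0.0:
        raise ValueError("marker_freq_population must be > 0")
    penetrance = prior_disease * marker_freq_affected / marker_freq_population
    if penetrance > 1.0 + CONSISTENCY_TOL:
        raise InconsistentParametersError(
            f"implied penetrance {penetrance:.6g} > 1: population marker "
            "frequency is below P(D)*P(M|D)"
        )
    return min(penetrance, 1.0)


def _sample(interval: IntervalParam, n: int, rng: np.random.Generator) -> np.ndarray:
    """Logit-normal draws matching the interval's point and 95% bounds."""
    if interval.is_degenerate:
        return np.full(n, interval.point)
    if not (0.0 < interval.lower and interval.upper < 1.0 and 0.0 < interval.point < 1.0):
        raise ValueError(
            "non-degenerate intervals must lie strictly inside (0, 1) "
            "for logit-scale sampling"
        )
    mu = logit(interval.point)
    sigma = (logit(interval.upper) - logit(interval.lower)) / (2.0 * _Z975)
    return expit(rng.normal(mu, sigma, size=n))


def propagate_interval(
    scenario: ScreeningScenario,
    intervals: dict[str, IntervalParam],
    n_draws: int = 10_000,
    seed: int = 0,
) -> PropagationSummary:
    """Monte Carlo propagation of parameter intervals onto P(D|T).

    Parameters named in ``intervals`` (any of ``prior_disease``,
    ``marker_freq_affected``, ``penetrance``, ``sensitivity``,
    ``specificity``) are sampled per draw; the rest stay at the scenario's
    values.  Invalid draws (prior × marker frequency exceeding penetrance,
    or zero penetrance) are discarded and counted.  Deterministic for a
    fixed seed; with all intervals degenerate the summary collapses exactly
    to the point evaluation.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for stable percentiles")
    unknown = set(intervals) - set(UNCERTAIN_PARAMS)
    if unknown:
        raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")

    if all(iv.is_degenerate for iv in intervals.values()):
        point = evaluate_scenario(scenario).disease_given_positive
        return PropagationSummary(point, point, point, n_draws, 0, seed)

    rng = np.random.default_rng(seed)
    draws = {
        "prior_disease": np.full(n_draws, scenario.prior_disease),
        "marker_freq_affected": np.full(n_draws, scenario.marker_freq_affected),
        "penetrance": np.full(n_draws, scenario.penetrance),
        "sensitivity": np.full(n_draws, scenario.test.sensitivity),
        "specificity": np.full(n_draws, scenario.test.specificity),
    }
    # Sampling order is fixed by UNCERTAIN_PARAMS so the stream is stable
    # regardless of dict insertion order.
    for name in UNCERTAIN_PARAMS:
        if name in intervals:
            draws[name] = _sample(intervals[name], n_draws, rng)

    prior, mfa, pen = draws["prior_disease"], draws["marker_freq_affected"], draws["penetrance"]
    sens, spec = draws["sensitivity"], draws["specificity"]

    with np.errstate(divide="ignore", invalid="ignore"):
        p_m_all = prior * mfa / np.where(pen > 0, pen, 1.0)
        valid = (
            (pen > 0.0)
            & (p_m_all < 1.0)
            & (prior * (1.0 - mfa) <= (1.0 - p_m_all) + CONSISTENCY_TOL)
        )
    n_discarded = int(n_draws - valid.sum())
    if n_discarded > n_draws // 2:
        raise UnstablePropagationError(
            f"{n_discarded}/{n_draws} draws violated the consistency constraint"
        )
    prior, mfa, pen, sens, spec = (a[valid] for a in (prior, mfa, pen, sens, spec))

    # Vectorised Bayesian chain (same algebra as model.evaluate_scenario).
    p_m = np.minimum(prior * mfa / pen, 1.0)
    p_d_not_m = prior * (1.0 - mfa) / (1.0 - p_m)
    p_t = sens * p_m + (1.0 - spec) * (1.0 - p_m)
    p_m_pos = p_m * sens / p_t
    p_d_pos = pen * p_m_pos + p_d_not_m * (1.0 - p_m_pos)

    lo, med, hi = np.percentile(p_d_pos, [2.5, 50.0, 97.5])
    return PropagationSummary(
        lower=float(lo),
        median=float(med),
        upper=float(hi),
        n_valid=int(valid.sum()),
        n_discarded=n_discarded,
        seed=seed,
    )
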