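"""Packaged case-study scenarios, parameter sweeps, and report writers.

Ships the ten case-study scenarios — Huntington's disease (*HTT* repeat
expansion, screening and targeted), amyotrophic lateral sclerosis (*SOD1*,
*FUS* and *C9orf72* marker definitions, including PCR confirmation of a
positive *C9orf72* screen), and phenylketonuria (*PAH*, screening and
metabolic-screen confirmation) — together with the five variant-type
sensitivity/specificity profiles for short-read sequencing genotyping, a
grid sweeper over any one or two model parameters, a YAML scenario-config
loader, and CSV/JSON report writers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CONSISTENCY_TOL,
    PosteriorResult,
    ScreeningError,
    ScreeningScenario,
    TestPerformance,
    evaluate_scenario,
)
from .sequential import ChainResult, chain_confirmatory, chain_external_prior
from .uncertainty import IntervalParam

__all__ = [
    "VARIANT_PROFILES",
    "ScenarioSpec",
    "SweepGrid",
    "variant_test",
    "table1_scenarios",
    "evaluate_specs",
    "reproduce_table1",
    "load_scenarios",
    "sweep",
    "write_report",
    "round_sig",
]

logger = logging.getLogger(__name__)

#: Analytic validity of short-read sequencing genotyping by variant type
#: (SNV, small indel, short tandem repeat expansion, copy-number deletion /
#: duplication), as benchmarked for state-of-the-art callers.
VARIANT_PROFILES: dict[str, TestPerformance] = {
    "SNV": TestPerformance(0.9996, 0.9995, label="SNV calling"),
    "indel": TestPerformance(0.9962, 0.9971, label="indel calling"),
    "STRE": TestPerformance(0.99, 0.90, label="STRE calling (short-read)"),
    "CNV-del": TestPerformance(0.289, 0.959, label="CNV deletion calling"),
    "CNV-dup": TestPerformance(0.1020, 0.9233, label="CNV duplication calling"),
}


def variant_test(variant_type: str) -> TestPerformance:
    """The packaged sensitivity/specificity profile for a variant type."""
    try:
        return VARIANT_PROFILES[variant_type]
    except KeyError:
        raise KeyError(
            f"no packaged profile for {variant_type!r}; "
            f"known types: {sorted(VARIANT_PROFILES)}"
        ) from None


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario plus optional chaining and uncertainty annotations.

    ``confirmatory_tests`` chains further assays after a positive result;
    ``external_prior``/``external_negative_risk`` instead evaluate the
    scenario as genetic confirmation of a positive non-genetic first test.
    ``intervals`` carries 95% CIs for uncertain parameters.
    """

    scenario: ScreeningScenario
    confirmatory_tests: tuple[TestPerformance, ...] = ()
    external_prior: float | None = None
    external_negative_risk: float | None = None
    intervals: dict[str, IntervalParam] = field(default_factory=dict)

    def evaluate(self) -> PosteriorResult | ChainResult:
        if self.external_prior is not None:
            return chain_external_prior(
                self.external_prior, self.external_negative_risk or 0.0, self.scenario
            )
        if self.confirmatory_tests:
            return chain_confirmatory(self.scenario, *self.confirmatory_tests)
        return evaluate_scenario(self.scenario)


def table1_scenarios() -> list[ScenarioSpec]:
    """The ten packaged case-study scenarios, loaded from the bundled config."""
    with resources.files("screenrisk.data").joinpath("table1.yaml").open() as fh:
        return _parse_config(yaml.safe_load(fh), source="packaged table1.yaml")


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


def evaluate_specs(specs: Iterable[ScenarioSpec]) -> pd.DataFrame:
    """Evaluate scenario specs into one tidy row each.

    Columns: the five inputs, the post-test risks ``p_disease_pos`` /
    ``p_disease_neg``, ``relative_risk``, and for chained specs the
    cross-stage ``omega`` (NaN otherwise).  Values are full precision;
    :func:`write_report` adds 3-significant-figure display columns.
    """
    rows = []
    for spec in specs:
        outcome = spec.evaluate()
        if isinstance(outcome, ChainResult):
            final = outcome.final
            omega = outcome.omega_relative_risk
        else:
            final = outcome
            omega = math.nan
        sc = final.scenario
        rows.append(
            {
                "label": spec.scenario.label,
                "variant_type": sc.variant_type,
                "prior_disease": sc.prior_disease,
                "marker_freq_affected": sc.marker_freq_affected,
                "penetrance": sc.penetrance,
                "sensitivity": sc.test.sensitivity,
                "specificity": sc.test.specificity,
                "p_disease_pos": final.disease_given_positive,
                "p_disease_neg": final.disease_given_negative,
                "relative_risk": final.relative_risk,
                "omega": omega,
            }
        )
    return pd.DataFrame(rows)


def reproduce_table1() -> pd.DataFrame:
    """Evaluate all ten packaged case-study scenarios.

    Returns the tidy frame from :func:`evaluate_specs`: one row per
    scenario, inputs alongside the derived post-test risks and relative
    risks, everything computed at full precision from the packaged inputs.
    """
    return evaluate_specs(table1_scenarios())


# ---------------------------------------------------------------------------
# Scenario config files

_SCENARIO_KEYS = {
    "label",
    "variant_type",
    "prior_disease",
    "marker_freq_affected",
    "penetrance",
    "test",
    "confirmatory_tests",
    "external_prior",
    "external_negative_risk",
    "intervals",
}
_TEST_KEYS = {"sensitivity", "specificity", "label"}
_INTERVAL_KEYS = {"point", "lower", "upper"}


class ConfigError(ScreeningError):
    """Malformed scenario configuration file."""


def _require_mapping(obj, what: str) -> dict:
    if not isinstance(obj, dict):
        raise ConfigError(f"{what} must be a mapping, got {type(obj).__name__}")
    return obj


def _reject_unknown(entry: dict, allowed: set[str], what: str) -> None:
    unknown = set(entry) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {what}")


def _parse_test(entry, what: str) -> TestPerformance:
    entry = _require_mapping(entry, what)
    _reject_unknown(entry, _TEST_KEYS, what)
    try:
        return TestPerformance(**entry)
    except ScreeningError as err:
        raise ConfigError(f"{what}: {err}") from err


def _parse_config(doc, source: str) -> list[ScenarioSpec]:
    doc = _require_mapping(doc, f"config {source}")
    _reject_unknown(doc, {"scenarios"}, f"config {source}")
    entries = doc.get("scenarios") or []
    if not entries:
        logger.warning("config %s contains no scenarios", source)
        return []

    specs: list[ScenarioSpec] = []
    labels: set[str] = set()
    for i, entry in enumerate(entries):
        what = f"scenario #{i + 1} in {source}"
        entry = dict(_require_mapping(entry, what))
        _reject_unknown(entry, _SCENARIO_KEYS, what)
        label = entry.get("label", f"scenario-{i + 1}")
        if label in labels:
            raise ConfigError(f"duplicate scenario label {label!r} in {source}")
        labels.add(label)

        try:
            scenario = ScreeningScenario(
                prior_disease=entry["prior_disease"],
                marker_freq_affected=entry["marker_freq_affected"],
                penetrance=entry["penetrance"],
                test=_parse_test(entry["test"], f"test block of {what}"),
                label=label,
                variant_type=entry.get("variant_type", "other"),
            )
        except KeyError as err:
            raise ConfigError(f"{what} is missing required key {err}") from err
        except ScreeningError as err:
            raise ConfigError(f"{what}: {err}") from err

        confirms = tuple(
            _parse_test(t, f"confirmatory test of {what}")
            for t in entry.get("confirmatory_tests") or ()
        )
        intervals = {}
        for name, iv in (entry.get("intervals") or {}).items():
            iv = _require_mapping(iv, f"interval {name!r} of {what}")
            _reject_unknown(iv, _INTERVAL_KEYS, f"interval {name!r} of {what}")
            try:
                intervals[name] = IntervalParam(**iv)
            except ValueError as err:
                raise ConfigError(f"interval {name!r} of {what}: {err}") from err

        specs.append(
            ScenarioSpec(
                scenario=scenario,
                confirmatory_tests=confirms,
                external_prior=entry.get("external_prior"),
                external_negative_risk=entry.get("external_negative_risk"),
                intervals=intervals,
            )
        )
    return specs


def load_scenarios(path: str | Path) -> list[ScenarioSpec]:
    """Load and validate a YAML scenario config.

    The file holds a ``scenarios`` list; each entry carries the five model
    inputs (with a nested ``test`` block), an optional ``confirmatory_tests``
    list, optional ``external_prior``/``external_negative_risk`` for
    non-genetic first-stage tests, and optional ``intervals``.  Unknown keys,
    out-of-range probabilities and inconsistent parameter triples are each
    rejected with a distinct message.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"could not parse {path}: {err}") from err
    return _parse_config(doc, source=str(path))


# ---------------------------------------------------------------------------
# Parameter sweeps

_SWEEPABLE = ("prior_disease", "marker_freq_affected", "penetrance", "sensitivity", "specificity")


@dataclass(frozen=True)
class SweepGrid:
    """P(D|T) (and companions) over a 1- or 2-axis parameter grid.

    ``disease_given_positive``, ``disease_given_negative`` and
    ``relative_risk`` have shape ``(len(axes[0]),)`` or
    ``(len(axes[0]), len(axes[1]))``.  Grid points whose parameters violate
    the consistency constraint are NaN with ``valid`` False — a sweep never
    aborts on an invalid corner.
    """

    axes: tuple[tuple[str, np.ndarray], ...]
    base: ScreeningScenario
    disease_given_positive: np.ndarray
    disease_given_negative: np.ndarray
    relative_risk: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per grid point."""
        names = [name for name, _ in self.axes]
        grids = np.meshgrid(*[vals for _, vals in self.axes], indexing="ij")
        data = {name: g.reshape(-1) for name, g in zip(names, grids)}
        data["p_disease_pos"] = self.disease_given_positive.reshape(-1)
        data["p_disease_neg"] = self.disease_given_negative.reshape(-1)
        data["relative_risk"] = self.relative_risk.reshape(-1)
        data["valid"] = self.valid.reshape(-1)
        return pd.DataFrame(data)


def sweep(base: ScreeningScenario, axes: dict[str, Sequence[float]]) -> SweepGrid:
    """Evaluate the model over a grid along one or two named parameters.

    ``axes`` maps parameter names (any of ``prior_disease``,
    ``marker_freq_affected``, ``penetrance``, ``sensitivity``,
    ``specificity``) to value lists in [0, 1]; remaining parameters are held
    at ``base``'s values.  Evaluation is vectorised; a sweep restricted to a
    single valid grid point reproduces :func:`evaluate_scenario` exactly.
    """
    if not 1 <= len(axes) <= 2:
        raise ValueError("sweep supports one or two axes")
    for name in axes:
        if name not in _SWEEPABLE:
            raise ValueError(f"unknown sweep parameter {name!r}; choose from {_SWEEPABLE}")
    ax_items = tuple((name, np.asarray(vals, dtype=float)) for name, vals in axes.items())
    for name, vals in ax_items:
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError(f"axis {name!r} must be a non-empty 1-D value list")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"axis {name!r} has values outside [0, 1]")

    grids = dict(zip([n for n, _ in ax_items],
                     np.meshgrid(*[v for _, v in ax_items], indexing="ij")))
    shape = next(iter(grids.values())).shape

    def param(name: str, default: float) -> np.ndarray:
        return grids.get(name, np.full(shape, default))

    prior = param("prior_disease", base.prior_disease)
    mfa = param("marker_freq_affected", base.marker_freq_affected)
    pen = param("penetrance", base.penetrance)
    sens = param("sensitivity", base.test.sensitivity)
    spec = param("specificity", base.test.specificity)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_m_all = prior * mfa / np.where(pen > 0, pen, 1.0)
        valid = (
            (pen > 0.0)
            & (p_m_all < 1.0)
            & (prior * (1.0 - mfa) <= (1.0 - p_m_all) + CONSISTENCY_TOL)
        )
        p_m = np.where(valid, p_m_all, np.nan)
        p_d_not_m = prior * (1.0 - mfa) / (1.0 - p_m)
        p_t = sens * p_m + (1.0 - spec) * (1.0 - p_m)
        p_m_pos = np.where(p_t > 0, p_m * sens / p_t, np.nan)
        p_m_neg = np.where(p_t < 1, p_m * (1.0 - sens) / (1.0 - p_t), np.nan)
        p_d_pos = pen * p_m_pos + p_d_not_m * (1.0 - p_m_pos)
        p_d_neg = pen * p_m_neg + p_d_not_m * (1.0 - p_m_neg)
        rr = np.where(p_d_neg > 0, p_d_pos / p_d_neg, np.inf)

    valid = valid & np.isfinite(p_d_pos)
    return SweepGrid(
        axes=ax_items,
        base=base,
        disease_given_positive=np.where(valid, p_d_pos, np.nan),
        disease_given_negative=np.where(valid, p_d_neg, np.nan),
        relative_risk=np.where(valid, rr, np.nan),
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Reports

_DISPLAY_COLS = ("p_disease_pos", "p_disease_neg", "relative_risk", "omega")


def write_report(results: pd.DataFrame, destination: str | Path, format: str = "csv") -> Path:
    """Write an evaluation or sweep frame to CSV or JSON.

    Full-precision values are preserved losslessly (``repr`` round-trip);
    derived-risk columns additionally get a ``*_3sf`` display column at the
    3-significant-figure convention.  Column order is stable.
    """
    if results is None:
        raise ValueError("results must not be None")
    destination = Path(destination)
    out = results.copy()
    for col in _DISPLAY_COLS:
        if col in out.columns:
            out[f"{col}_3sf"] = out[col].map(
                lambda x: round_sig(float(x)) if pd.notna(x) else x
            )
    if format == "csv":
        out.to_csv(destination, index=False, float_format=lambda x: repr(float(x)))
    elif format == "json":
        # stdlib json uses repr for floats, so values round-trip bit-for-bit
        # (pandas' to_json caps precision at 15 digits)
        destination.write_text(
            json.dumps(out.to_dict(orient="records"), indent=2, allow_nan=True)
        )
    else:
        raise ValueError(f"format must be 'csv' or 'json', got {format!r}")
    return destination
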