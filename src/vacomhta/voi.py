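"""Value-of-information analysis: EVPI and per-parameter EVPPI.

EVPI at willingness-to-pay λ is the expected opportunity loss of deciding
under current uncertainty: ``E[max_s NMB_s] − max_s E[NMB_s]`` over the PSA
distribution, with per-strategy NMB ``λ·E_s − C_s`` on each draw.  EVPPI for
a parameter (or parameter subset) θ replaces the inner NMB with its
conditional expectation given θ.  Two estimators are provided: a nested
two-loop Monte-Carlo estimator (the validation path) and a single-loop
regression estimator that smooths the incremental NMB against θ (the fast
default, reusing one PSA).  Estimates that are negative due to Monte-Carlo
noise are clipped to 0 with the raw value retained.

EVSI/ENBS are deliberately not implemented, but nothing in the interfaces
precludes adding them later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cea import PsaSamples, evaluate_draws
from .parameters import (ParameterTable, ScenarioConfig, apply_scenario,
                         sample_psa_draws)

__all__ = [
    "evpi",
    "EvppiEstimate",
    "evppi_nested_mc",
    "evppi_regression",
    "scale_to_population",
    "VoiResult",
    "value_of_information",
]


def evpi(psa: PsaSamples, thresholds: Sequence[float]) -> pd.DataFrame:
    """Per-patient EVPI over a threshold grid.

    On a fixed draw set ``E[max] >= max[E]`` holds exactly, so no clipping
    is needed; degenerate (uncertainty-free) draws give EVPI 0.
    """
    if psa.n < 2:
        raise ValueError("evpi requires at least 2 PSA draws")
    grid = np.asarray(thresholds, dtype=float)
    out = []
    for lam in grid:
        per_strategy = [np.ascontiguousarray(psa.nmb(s, lam))
                        for s in psa.strategies]
        best = np.ascontiguousarray(np.max(per_strategy, axis=0))
        # identical contiguous summation paths keep E[max] - max[E] at an
        # exact 0 for degenerate (uncertainty-free) draws
        value = float(best.mean()) - max(float(a.mean())
                                         for a in per_strategy)
        out.append(max(value, 0.0))
    return pd.DataFrame({"threshold": grid, "evpi": out})


@dataclass(frozen=True)
class EvppiEstimate:
    """One EVPPI estimate with its provenance."""

    parameter: str  # comma-joined for parameter subsets
    value: float  # clipped at 0
    raw_value: float
    mc_error: float  # NaN for the regression estimator
    estimator: str  # "nested_mc" | "regression"
    metadata: dict = field(default_factory=dict)


def evppi_nested_mc(cohort, table: ParameterTable, scenario: ScenarioConfig,
                    target_parameter: "str | Sequence[str]",
                    n_outer: int = 200, n_inner: int = 500,
                    seed=0, threshold: "float | None" = None,
                    outer_values: "np.ndarray | None" = None
                    ) -> EvppiEstimate:
    """Two-loop Monte-Carlo EVPPI for one parameter (or a subset).

    The outer loop draws the target parameter(s); the inner loop draws all
    remaining parameters and averages each strategy's NMB.  ``outer_values``
    may supply explicit outer draws (e.g. a discrete two-point design), in
    which case the outer distribution is taken as given.  A fixed target
    parameter carries no decision uncertainty and returns 0 without
    simulation.
    """
    targets = ([target_parameter] if isinstance(target_parameter, str)
               else list(target_parameter))
    lam = scenario.threshold if threshold is None else threshold
    view = apply_scenario(table, scenario).for_cohort(cohort)
    specs = {s.name: s for s in view.specs}
    unknown = [t for t in targets if t not in specs]
    if unknown:
        raise KeyError(f"unknown target parameter(s) {unknown}")
    name = ",".join(targets)

    if outer_values is None and all(specs[t].is_fixed for t in targets):
        return EvppiEstimate(name, 0.0, 0.0, 0.0, "nested_mc",
                             {"reason": "fixed parameter"})
    if n_outer < 2 or n_inner < 2:
        raise ValueError("n_outer and n_inner must be >= 2")

    rng = np.random.default_rng(seed)
    if outer_values is None:
        outer = sample_psa_draws(view, n_outer, rng)[targets]
    else:
        outer = pd.DataFrame(np.atleast_2d(
            np.asarray(outer_values, dtype=float).reshape(
                len(outer_values), -1)), columns=targets)
        n_outer = len(outer)

    rr_map = view.strategy_rr_map() or None
    inner_means = np.empty((n_outer, 2))
    for i in range(n_outer):
        draws = sample_psa_draws(view, n_inner, rng)
        for t in targets:
            draws[t] = outer[t].iloc[i]
        psa = evaluate_draws(draws, scenario, rr_map)
        inner_means[i] = [psa.nmb(s, lam).mean() for s in psa.strategies]

    best_given_theta = inner_means.max(axis=1)
    raw = float(best_given_theta.mean() - inner_means.mean(axis=0).max())
    mc_error = float(best_given_theta.std(ddof=1) / math.sqrt(n_outer))
    return EvppiEstimate(name, max(raw, 0.0), raw, mc_error, "nested_mc",
                         {"n_outer": n_outer, "n_inner": n_inner,
                          "threshold": lam})


def evppi_regression(psa: PsaSamples, target_parameter: str,
                     threshold: float, frac: float = 0.4
                     ) -> EvppiEstimate:
    """Single-loop regression EVPPI from a stored PSA.

    Smooths the incremental NMB against the target parameter with a local
    linear (lowess) fit — any consistent one-dimensional conditional-mean
    estimator would do; the method and bandwidth are recorded in the
    metadata.  EVPPI = ``E[max(0, ĝ(θ))] − max(0, E[INB])``.
    """
    if psa.n < 2:
        raise ValueError("evppi_regression requires at least 2 PSA draws")
    if target_parameter not in psa.draws.columns:
        raise KeyError(f"parameter {target_parameter!r} not in the stored "
                       "draws")
    theta = psa.draws[target_parameter].to_numpy()
    meta = {"method": "lowess", "frac": frac, "threshold": threshold}
    inb = psa.incremental_nmb(threshold)
    if np.ptp(theta) == 0.0:
        return EvppiEstimate(target_parameter, 0.0, 0.0, math.nan,
                             "regression", {**meta,
                                            "reason": "constant parameter"})
    fitted = sm.nonparametric.lowess(inb, theta, frac=frac,
                                     return_sorted=False)
    raw = float(np.maximum(fitted, 0.0).mean() - max(inb.mean(), 0.0))
    return EvppiEstimate(target_parameter, max(raw, 0.0), raw, math.nan,
                         "regression", meta)


def scale_to_population(per_patient_voi: float,
                        effective_population: int) -> float:
    """Population-scaled VOI.  The effective population is an explicit user
    input — the analysis never assumes one silently."""
    if effective_population is None:
        raise ValueError("effective_population is required (no default)")
    if int(effective_population) < 1:
        raise ValueError("effective_population must be >= 1")
    return float(per_patient_voi) * int(effective_population)


@dataclass(frozen=True)
class VoiResult:
    """VOI summary at one threshold."""

    threshold: float
    evpi_per_patient: float
    evppi_per_patient: dict[str, float]
    estimator: str
    mc_error: float


def value_of_information(cohort, table: ParameterTable,
                         scenario: ScenarioConfig,
                         psa: "PsaSamples | None" = None,
                         parameters: "Sequence[str] | None" = None,
                         threshold: "float | None" = None) -> VoiResult:
    """EVPI plus regression EVPPI for the requested parameters (default:
    every non-fixed parameter) at a single threshold."""
    from .cea import run_psa

    lam = scenario.threshold if threshold is None else threshold
    if psa is None:
        psa = run_psa(cohort, table, scenario)
    evpi_val = float(evpi(psa, [lam])["evpi"].iloc[0])
    view = apply_scenario(table, scenario).for_cohort(cohort)
    if parameters is None:
        parameters = [s.name for s in view.specs if not s.is_fixed]
    evppi = {p: evppi_regression(psa, p, lam).value for p in parameters}
    return VoiResult(lam, evpi_val, evppi, "regression", math.nan)
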