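"""One-way deterministic sensitivity analysis and price-premium threshold
analysis.

The tornado metric is the percentage change of the incremental NMB (at the
scenario threshold) when one parameter at a time is set to its DSA low/high
bound, all others held at base case.  The threshold analysis exploits the
model's linearity in the premium: each S$1 of premium reduces the
incremental NMB by exactly S$1 per patient, so the maximum chargeable
premium has the closed form ``premium* = premium0 + NMB_inc(premium0)``; a
bisection root-finder verifies the closed form to S$0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .model import Strategy, build_and_evaluate
from .parameters import (ParameterTable, ScenarioConfig, apply_scenario,
                         ROLE_PROBABILITY, ROLE_UTILITY,
                         ROLE_WHOLE_PATHWAY_QALY, ROLE_COST,
                         ROLE_RELATIVE_RISK)
from .cea import incremental

__all__ = [
    "TornadoEntry",
    "one_way_dsa",
    "tornado_frame",
    "MaxPremiumResult",
    "max_premium",
    "threshold_curve",
]

#: bisection bracket for the premium root (far beyond any plausible device
#: premium)
_PREMIUM_BRACKET_HIGH = 1e6


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the NMB tornado."""

    parameter: str
    nmb_base: float
    nmb_at_low: float
    nmb_at_high: float
    pct_change_low: float
    pct_change_high: float
    span: float
    absolute_fallback: bool = False  # True when base NMB == 0 (absolute S$)


def _incremental_nmb_on_view(view: ParameterTable, scenario: ScenarioConfig,
                             premium: "float | None" = None) -> float:
    premium = scenario.price_premium if premium is None else premium
    # a resolved view is cohort-agnostic; any cohort label works for lookups
    vac = build_and_evaluate("ischemic", Strategy.vacom(premium), view,
                             scenario)
    ipc = build_and_evaluate("ischemic", Strategy.ipc_manual(), view,
                             scenario)
    return incremental(vac, ipc, scenario.threshold).nmb


def one_way_dsa(cohort, table: ParameterTable, scenario: ScenarioConfig,
                threshold: "float | None" = None) -> list[TornadoEntry]:
    """Tornado entries for every parameter, ranked by span (descending;
    ties broken alphabetically by parameter name).

    The percentage change is relative to the base-case incremental NMB; when
    the base NMB is exactly 0 the entries fall back to absolute S$ changes
    and are flagged.
    """
    if threshold is not None:
        scenario = ScenarioConfig(**{**_scenario_kwargs(scenario),
                                     "threshold": threshold})
    view = apply_scenario(table, scenario).for_cohort(cohort)
    nmb_base = _incremental_nmb_on_view(view, scenario)
    entries = []
    for spec in view.specs:
        nmb_lo = _incremental_nmb_on_view(
            view.with_base(spec.name, spec.dsa_low), scenario)
        nmb_hi = _incremental_nmb_on_view(
            view.with_base(spec.name, spec.dsa_high), scenario)
        if nmb_base != 0.0:
            lo = 100.0 * (nmb_lo - nmb_base) / abs(nmb_base)
            hi = 100.0 * (nmb_hi - nmb_base) / abs(nmb_base)
            fallback = False
        else:
            lo = nmb_lo - nmb_base
            hi = nmb_hi - nmb_base
            fallback = True
        entries.append(TornadoEntry(
            parameter=spec.name, nmb_base=nmb_base, nmb_at_low=nmb_lo,
            nmb_at_high=nmb_hi, pct_change_low=lo, pct_change_high=hi,
            span=max(abs(lo), abs(hi)), absolute_fallback=fallback))
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry],
                  top: "int | None" = None) -> pd.DataFrame:
    """Tabular tornado view; ``top=15`` reproduces the usual report cut."""
    rows = entries[:top] if top else entries
    return pd.DataFrame([{
        "parameter": e.parameter,
        "nmb_base": e.nmb_base,
        "nmb_at_low": e.nmb_at_low,
        "nmb_at_high": e.nmb_at_high,
        "pct_change_low": e.pct_change_low,
        "pct_change_high": e.pct_change_high,
        "span": e.span,
        "absolute_fallback": e.absolute_fallback,
    } for e in rows])


def _scenario_kwargs(s: ScenarioConfig) -> dict:
    return dict(name=s.name,
                rr_ankle_contracture_vacom=s.rr_ankle_contracture_vacom,
                price_premium=s.price_premium, cohort=s.cohort,
                threshold=s.threshold, timing=s.timing, seed=s.seed,
                n_psa=s.n_psa)


@dataclass(frozen=True)
class MaxPremiumResult:
    """Maximum price premium at which the intervention remains eligible for
    reimbursement (incremental NMB >= 0).  ``reimbursable`` is False when the
    NMB is negative even at zero premium (the premium is then reported as
    0)."""

    premium: float
    reimbursable: bool
    nmb_at_zero_premium: float

    def __float__(self) -> float:
        return self.premium


def _max_premium_on_view(view: ParameterTable, scenario: ScenarioConfig,
                         verify: bool = True, tol: float = 0.01
                         ) -> MaxPremiumResult:
    nmb0 = _incremental_nmb_on_view(view, scenario, premium=0.0)
    closed_form = nmb0  # NMB_inc(p) = NMB_inc(0) - p, root at p = NMB_inc(0)
    if closed_form < 0:
        return MaxPremiumResult(0.0, False, nmb0)
    if verify and closed_form > 0:
        hi = max(_PREMIUM_BRACKET_HIGH, 2.0 * closed_form)
        root = optimize.brentq(
            lambda p: _incremental_nmb_on_view(view, scenario, premium=p),
            0.0, hi, xtol=1e-6)
        if abs(root - closed_form) > tol:
            raise AssertionError(
                f"closed-form max premium {closed_form:.4f} and bisection "
                f"root {root:.4f} disagree by more than S${tol}")
    return MaxPremiumResult(float(closed_form), True, nmb0)


def max_premium(cohort, table: ParameterTable, scenario: ScenarioConfig,
                threshold: "float | None" = None, verify: bool = True
                ) -> MaxPremiumResult:
    """Maximum additional price chargeable for the intervention while its
    incremental NMB at the threshold remains non-negative."""
    if threshold is not None:
        scenario = ScenarioConfig(**{**_scenario_kwargs(scenario),
                                     "threshold": threshold})
    view = apply_scenario(table, scenario).for_cohort(cohort)
    return _max_premium_on_view(view, scenario, verify=verify)


_ROLE_BOUNDS = {
    ROLE_PROBABILITY: (0.0, 1.0),
    ROLE_UTILITY: (0.0, 1.0),
    ROLE_WHOLE_PATHWAY_QALY: (0.0, 1.0),
    ROLE_COST: (0.0, math.inf),
    ROLE_RELATIVE_RISK: (np.nextafter(0.0, 1.0), math.inf),
}


def threshold_curve(cohort, table: ParameterTable, scenario: ScenarioConfig,
                    sweep_parameter: str, grid: Sequence[float],
                    verify: bool = False) -> pd.DataFrame:
    """Maximum premium as a function of one swept parameter.

    All other parameters stay at base case; grid values must respect the
    swept parameter's role bounds.  Sweeping the RR of an event that raises
    cost and lowers QALY yields a non-increasing curve (a more effective
    device supports a higher premium).
    """
    view = apply_scenario(table, scenario).for_cohort(cohort)
    spec = view.get(sweep_parameter)
    lo, hi = _ROLE_BOUNDS[spec.role]
    grid = [float(v) for v in grid]
    bad = [v for v in grid if not (lo <= v <= hi)]
    if bad:
        raise ValueError(f"grid values {bad} violate bounds [{lo}, {hi}] "
                         f"for role {spec.role}")
    rows = []
    for v in grid:
        res = _max_premium_on_view(view.with_base(sweep_parameter, v),
                                   scenario, verify=verify)
        rows.append({sweep_parameter: v, "max_premium": res.premium,
                     "reimbursable": res.reimbursable})
    return pd.DataFrame(rows)
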