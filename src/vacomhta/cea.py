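"""Incremental cost-utility statistics: ICER, NMB, dominance, PSA and CEAC.

Conventions: ΔC and ΔE are intervention minus comparator; the net monetary
benefit at willingness-to-pay λ is ``NMB = λ·ΔE − ΔC``.  Dominance is
quadrant-aware: in the southwest quadrant (cheaper and less effective) the
classification uses the NMB sign, because the ICER is sign-ambiguous there.
Ties (NMB exactly 0) count against the intervention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (Strategy, build_and_evaluate, expected_outcomes,
                    StrategyResult, IPC_MANUAL, VACOM)
from .parameters import (ParameterTable, ScenarioConfig, apply_scenario,
                         sample_psa_draws)

__all__ = [
    "DOMINANCE_CLASSES",
    "IncrementalResult",
    "incremental",
    "evaluate_strategies",
    "base_case",
    "PsaSamples",
    "evaluate_draws",
    "run_psa",
    "ceac",
    "default_threshold_grid",
    "premium_icer_curve",
]

COST_SAVING_DOMINANT = "cost_saving_dominant"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"
DOMINATED = "dominated"
DOMINANCE_CLASSES = (COST_SAVING_DOMINANT, COST_EFFECTIVE,
                     NOT_COST_EFFECTIVE, DOMINATED)


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    icer: float  # NaN when delta_qaly == 0
    nmb: float
    dominance: str
    threshold: float

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)


def _classify(dc: float, de: float, nmb: float) -> str:
    if dc <= 0 and de >= 0 and (dc < 0 or de > 0):
        return COST_SAVING_DOMINANT
    if dc >= 0 and de <= 0 and (dc > 0 or de < 0):
        return DOMINATED
    if dc == 0 and de == 0:
        return NOT_COST_EFFECTIVE
    # NE quadrant (pay more, gain more) and SW quadrant (pay less, lose
    # some effect): decided by the NMB sign, ties against the intervention
    return COST_EFFECTIVE if nmb > 0 else NOT_COST_EFFECTIVE


def incremental(intervention: StrategyResult, comparator: StrategyResult,
                threshold: float) -> IncrementalResult:
    """ΔC, ΔE, ICER, NMB and dominance class at the given threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    dc = intervention.expected_cost - comparator.expected_cost
    de = intervention.expected_qaly - comparator.expected_qaly
    icer = dc / de if de != 0 else math.nan
    nmb = threshold * de - dc
    return IncrementalResult(dc, de, icer, nmb, _classify(dc, de, nmb),
                             threshold)


def evaluate_strategies(cohort, table: ParameterTable,
                        scenario: ScenarioConfig,
                        apply_rr_override: bool = True
                        ) -> tuple[StrategyResult, StrategyResult]:
    """Base-case evaluation of both arms under a scenario.

    Applies the scenario's ankle-contracture RR to the table (unless the
    caller already did), builds the VACOM strategy at the scenario premium,
    and enumerates both trees.  Returns ``(vacom, ipc_manual)``.
    """
    if apply_rr_override:
        table = apply_scenario(table, scenario)
    vac = build_and_evaluate(cohort, Strategy.vacom(scenario.price_premium),
                             table, scenario)
    ipc = build_and_evaluate(cohort, Strategy.ipc_manual(), table, scenario)
    return vac, ipc


def base_case(cohort, table: ParameterTable, scenario: ScenarioConfig
              ) -> IncrementalResult:
    vac, ipc = evaluate_strategies(cohort, table, scenario)
    return incremental(vac, ipc, scenario.threshold)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PsaSamples:
    """Parameter draws paired with per-strategy (cost, QALY) outputs.

    Both strategies are evaluated on the same draws (common random numbers),
    which reduces the Monte-Carlo variance of the CEAC and VOI estimates.
    """

    draws: pd.DataFrame
    cost: dict[str, np.ndarray]
    qaly: dict[str, np.ndarray]
    intervention: str = VACOM
    comparator: str = IPC_MANUAL

    def __post_init__(self) -> None:
        n = len(self.draws)
        for d in (self.cost, self.qaly):
            for k, v in d.items():
                d[k] = np.broadcast_to(np.asarray(v, dtype=float), (n,))

    @property
    def n(self) -> int:
        return len(self.draws)

    @property
    def strategies(self) -> list[str]:
        return [self.intervention, self.comparator]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost[self.intervention] - self.cost[self.comparator]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly[self.intervention] - self.qaly[self.comparator]

    def nmb(self, strategy: str, threshold: float) -> np.ndarray:
        """Absolute per-draw NMB of one strategy: λ·E − C."""
        return threshold * self.qaly[strategy] - self.cost[strategy]

    def incremental_nmb(self, threshold: float) -> np.ndarray:
        return threshold * self.delta_qaly - self.delta_cost


def evaluate_draws(draws: pd.DataFrame, scenario: ScenarioConfig,
                   rr_map: "Mapping[str, str] | None" = None) -> PsaSamples:
    """Evaluate both strategies, vectorised, on an explicit draw matrix."""
    values = {c: draws[c].to_numpy() for c in draws.columns}
    out_cost, out_qaly = {}, {}
    for strat in (Strategy.vacom(scenario.price_premium),
                  Strategy.ipc_manual()):
        c, q = expected_outcomes(values, strat, scenario.timing, rr_map)
        out_cost[strat.name] = c
        out_qaly[strat.name] = q
    return PsaSamples(draws, out_cost, out_qaly)


def run_psa(cohort, table: ParameterTable, scenario: ScenarioConfig,
            n: "int | None" = None, seed=None) -> PsaSamples:
    """Sample the joint parameter distribution and evaluate both arms.

    Uses the scenario's ``n_psa`` and ``seed`` unless overridden.
    """
    view = apply_scenario(table, scenario).for_cohort(cohort)
    draws = sample_psa_draws(view, n if n is not None else scenario.n_psa,
                             scenario.seed if seed is None else seed)
    rr_map = view.strategy_rr_map() or None
    return evaluate_draws(draws, scenario, rr_map)


def default_threshold_grid() -> np.ndarray:
    """S$0 to S$150,000 per QALY in steps of S$5,000."""
    return np.arange(0.0, 150_000.0 + 1, 5_000.0)


def ceac(psa: PsaSamples, thresholds: "Sequence[float] | None" = None
         ) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each threshold λ, the fraction of PSA draws in which the
    intervention's incremental NMB is strictly positive (ties count as not
    cost-effective).
    """
    if psa.n < 2:
        raise ValueError("ceac requires at least 2 PSA draws")
    grid = np.asarray(default_threshold_grid() if thresholds is None
                      else thresholds, dtype=float)
    dc, de = psa.delta_cost, psa.delta_qaly
    probs = [float(np.mean(lam * de - dc > 0)) for lam in grid]
    return pd.DataFrame({"threshold": grid, "p_cost_effective": probs})


def premium_icer_curve(cohort, table: ParameterTable,
                       scenario: ScenarioConfig,
                       premium_grid: Sequence[float]) -> pd.DataFrame:
    """ICER as a function of the price premium (all else at base case).

    Each S$1 of premium adds exactly S$1 to ΔC per patient and leaves ΔE
    unchanged, so the curve is affine with slope 1/ΔE; this is asserted
    against the pointwise evaluations.  When ΔE = 0 the curve is undefined
    and every ICER is NaN.
    """
    applied = apply_scenario(table, scenario)
    grid = [float(p) for p in premium_grid]
    rows = []
    de0 = None
    dc0 = None
    for premium in grid:
        vac = build_and_evaluate(cohort, Strategy.vacom(premium), applied,
                                 scenario)
        ipc = build_and_evaluate(cohort, Strategy.ipc_manual(), applied,
                                 scenario)
        inc = incremental(vac, ipc, scenario.threshold)
        if de0 is None:
            de0, dc0 = inc.delta_qaly, inc.delta_cost - premium
        else:
            # affine structure: ΔE constant, ΔC = ΔC(0) + premium
            if not (math.isclose(inc.delta_qaly, de0, rel_tol=1e-9,
                                 abs_tol=1e-12)
                    and math.isclose(inc.delta_cost - premium, dc0,
                                     rel_tol=1e-9, abs_tol=1e-6)):
                raise AssertionError(
                    "premium-ICER curve is not affine; model invariant "
                    "violated")
        rows.append({"premium": premium, "delta_cost": inc.delta_cost,
                     "delta_qaly": inc.delta_qaly, "icer": inc.icer,
                     "nmb": inc.nmb})
    return pd.DataFrame(rows)
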