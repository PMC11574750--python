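"""Synthetic parameter tables and the built-in analysis scenarios.

The generator emits a complete, validated parameter table with the
statistical structure the model expects: inpatient DVT/PE/death
probabilities, post-discharge recurrence/contracture/mortality
probabilities, intervention relative risks and compliance, per-state costs,
and whole-pathway QALY parameters under the ``qaly_<inpatient>_1_12m_<outcome>``
naming convention (the table layout the analysis was designed around).

The packaged base values are synthetic placeholders drawn once from
literature-plausible ranges for the Singapore post-stroke setting — they are
NOT transcribed study values.  An analyst holding the original parameter
sources can transcribe them into the same CSV layout (see
``templates/parameters_template.csv``) and run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (InpatientState, PostdischargeState, TimingConstants,
                    pathway_qaly)
from .parameters import (ParameterSpec, ParameterTable, ScenarioConfig,
                         ROLE_PROBABILITY, ROLE_RELATIVE_RISK, ROLE_COST,
                         ROLE_UTILITY, ROLE_WHOLE_PATHWAY_QALY)

__all__ = [
    "GeneratorProfile",
    "generate_parameter_table",
    "default_parameter_table",
    "builtin_scenarios",
]


def _default_ranges() -> dict[str, tuple[float, float]]:
    """Plausibility ranges (uniform draw bounds) per parameter.

    Probabilities refer to the model's own time windows (1-month inpatient
    stay; months 2–12 post-discharge); costs are 2019 S$ per patient or per
    event; utilities are comorbidity multipliers except the post-stroke base.
    """
    return {
        # inpatient period
        "prob_dvt": (0.05, 0.12),          # symptomatic DVT under IPC + manual movement
        "prob_pe_dvt": (0.15, 0.30),       # PE among DVT patients
        "prob_death_inpatient": (0.08, 0.15),   # ischemic; hemorrhagic scaled up
        # post-discharge period (months 2-12)
        "prob_recur_stroke": (0.04, 0.10),
        "prob_recur_dvt": (0.02, 0.05),
        "prob_recur_pe": (0.005, 0.02),
        "prob_ankcon": (0.20, 0.40),       # ankle-specific contracture
        "prob_death_postdis": (0.05, 0.10),     # ischemic; hemorrhagic scaled up
        # intervention profile
        "prob_compliance_vac": (0.70, 0.90),
        "rr_dvt_vac_ipc": (0.50, 0.90),
        "rr_ankcon_vac": (0.30, 0.90),     # overridden by the scenario presets
        # costs, 2019 S$
        "cost_device": (300.0, 800.0),
        "cost_inpatient_stay": (15_000.0, 25_000.0),
        "cost_dvt": (2_000.0, 5_000.0),
        "cost_pe": (6_000.0, 12_000.0),
        "cost_recstroke": (10_000.0, 20_000.0),
        "cost_recdvt": (2_000.0, 5_000.0),
        "cost_recpe": (6_000.0, 12_000.0),
        "cost_ankcon": (3_000.0, 8_000.0),
        "cost_death_postdis": (500.0, 2_000.0),
        "cost_monthly_postdis": (200.0, 600.0),
        # utilities (post-stroke base; the rest multiply it)
        "util_poststroke": (0.60, 0.80),
        "util_dvt": (0.85, 0.95),
        "util_pe": (0.75, 0.90),
        "util_recstroke": (0.60, 0.80),
        "util_recdvt": (0.85, 0.95),
        "util_recpe": (0.75, 0.90),
        "util_ankcon": (0.70, 0.85),
    }


_COHORT_SPECIFIC = ("prob_death_inpatient", "prob_death_postdis")
_ROLE_BY_PREFIX = {
    "prob": ROLE_PROBABILITY,
    "rr": ROLE_RELATIVE_RISK,
    "cost": ROLE_COST,
    "util": ROLE_UTILITY,
    "qaly": ROLE_WHOLE_PATHWAY_QALY,
}
_STRATEGY_RR = {"prob_dvt": "rr_dvt_vac_ipc", "prob_ankcon": "rr_ankcon_vac"}


@dataclass(frozen=True)
class GeneratorProfile:
    """Everything the generator needs to emit one parameter table.

    ``ranges`` bounds the uniform draw of each base value;
    ``hemorrhagic_mortality_multiplier`` bounds the ratio of hemorrhagic to
    ischemic mortality (hemorrhagic-cohort mortality is always >= the
    ischemic value); ``se_fraction`` is the relative standard error attached
    to every non-fixed row (PSA distributions and DSA ranges are fitted from
    it by the method of moments); ``qaly_mode`` selects whole-pathway QALY
    parameters (the default table layout) or decomposed state utilities.
    """

    seed: int = 0
    se_fraction: float = 0.2
    qaly_mode: str = "whole_pathway"  # or "decomposed"
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_ranges)
    hemorrhagic_mortality_multiplier: tuple[float, float] = (1.8, 3.0)
    timing: TimingConstants = field(default_factory=TimingConstants)

    def __post_init__(self) -> None:
        if self.qaly_mode not in ("whole_pathway", "decomposed"):
            raise ValueError("qaly_mode must be whole_pathway or decomposed")
        if not 0 < self.se_fraction < 1:
            raise ValueError("se_fraction must lie in (0, 1)")
        missing = set(_default_ranges()) - set(self.ranges)
        if missing:
            raise ValueError(f"profile ranges missing {sorted(missing)}")
        for name, (lo, hi) in self.ranges.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")


def _role_of(name: str) -> str:
    return _ROLE_BY_PREFIX[name.split("_", 1)[0]]


def generate_parameter_table(profile: "GeneratorProfile | None" = None
                             ) -> ParameterTable:
    """Draw a complete parameter table; deterministic under the profile seed.

    Base values are drawn uniformly within the profile's plausibility
    ranges.  Hemorrhagic-cohort mortality rows are the ischemic draw scaled
    by the mortality multiplier (capped at 0.95), encoding the higher
    baseline mortality of hemorrhagic stroke.  Whole-pathway QALY base
    values are computed from the drawn state utilities with the decomposed
    time-weighting rule, so the two QALY modes agree at base case.
    """
    profile = profile or GeneratorProfile()
    rng = np.random.default_rng(profile.seed)
    draw = {name: float(rng.uniform(lo, hi))
            for name, (lo, hi) in sorted(profile.ranges.items())}

    specs: list[ParameterSpec] = []

    def add(name: str, cohort: str, value: float, role: "str | None" = None,
            strategy_rr: str = "") -> None:
        se = profile.se_fraction * abs(value)
        specs.append(ParameterSpec(
            name=name, cohort=cohort, role=role or _role_of(name),
            base_value=value, se=se if se > 0 else float("nan"),
            strategy_rr=strategy_rr))

    for name, value in draw.items():
        if name.startswith("util_"):
            continue  # emitted below depending on the QALY mode
        if name in _COHORT_SPECIFIC:
            mult = float(rng.uniform(*profile.hemorrhagic_mortality_multiplier))
            add(name, "ischemic", value,
                strategy_rr=_STRATEGY_RR.get(name, ""))
            add(name, "hemorrhagic", min(0.95, value * mult),
                strategy_rr=_STRATEGY_RR.get(name, ""))
        else:
            add(name, "both", value, strategy_rr=_STRATEGY_RR.get(name, ""))

    utilities = {k: v for k, v in draw.items() if k.startswith("util_")}
    if profile.qaly_mode == "decomposed":
        for name, value in utilities.items():
            add(name, "both", value)
    else:
        for inp_code, (dvt, pe) in (("ndnp", (False, False)),
                                    ("dnp", (True, False)),
                                    ("dp", (True, True))):
            dead = InpatientState(dvt, pe, True)
            q = pathway_qaly(dead, None, utilities, profile.timing)
            add(f"qaly_{inp_code}_1m_death", "both", float(q))
            alive = InpatientState(dvt, pe, False)
            for state in PostdischargeState:
                q = pathway_qaly(alive, state, utilities, profile.timing)
                add(f"qaly_{inp_code}_1_12m_{state.code}", "both", float(q))

    return ParameterTable(specs)


def default_parameter_table() -> ParameterTable:
    """The packaged default table (default profile, seed 0)."""
    return generate_parameter_table(GeneratorProfile())


def builtin_scenarios() -> list[ScenarioConfig]:
    """The analysis scenario presets.

    Optimistic (RR of ankle contracture 0.3) and conservative (0.9)
    effectiveness assumptions, each at the revised S$150 and the original
    S$300 price premium, plus the S$1,000-premium optimistic scenario used
    for the value-of-information analysis.  All use the S$75,000/QALY
    ceiling threshold, a 12-month horizon with a 1-month inpatient stay,
    inpatient death on day 15, and post-discharge events at the start of
    month 7.
    """
    presets = []
    for name in ("optimistic", "conservative"):
        for premium in (150.0, 300.0):
            presets.append(ScenarioConfig(
                name=name, rr_ankle_contracture_vacom={"optimistic": 0.3,
                                                       "conservative": 0.9}[name],
                price_premium=premium))
    presets.append(ScenarioConfig(name="optimistic",
                                  rr_ankle_contracture_vacom=0.3,
                                  price_premium=1000.0))
    return presets


def get_scenario(label: str) -> ScenarioConfig:
    """Look up a built-in scenario by its label (e.g. ``conservative_premium150``)."""
    for s in builtin_scenarios():
        if s.label == label:
            return s
    labels = [s.label for s in builtin_scenarios()]
    raise KeyError(f"unknown scenario {label!r}; built-ins: {labels}")
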