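"""Two-period decision-tree model for VACOM versus IPC plus manual ankle movement.

The model follows a hypothetical cohort of post-stroke inpatients with lower
limb weakness over a 1-year horizon from a healthcare-system perspective.
Period 1 is a 1-month inpatient stay during which deep vein thrombosis (DVT),
pulmonary embolism (PE, modelled as a DVT sequela) and inpatient death may
occur; inpatient deaths happen on day 15 of the stay.  Period 2 runs from
month 2 to month 12; one of {recurrent stroke, recurrent DVT, recurrent PE,
ankle contracture, death} may occur at the start of month 7, with a residual
"well" branch.  The intervention acts by multiplying the baseline DVT and
ankle-contracture probabilities by relative risks, diluted by the device
compliance rate (a cohort-level mixture equivalent in expectation to
patient-level binary compliance).

Expected cost and QALY per strategy are obtained by exact enumeration of all
pathway probabilities; :func:`microsimulate` provides an independent
Monte-Carlo oracle over the same tree.  All arithmetic is elementwise, so
parameter values may be scalars or NumPy arrays (one entry per PSA draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .parameters import ParameterTable, ScenarioConfig

__all__ = [
    "ModelError",
    "ConfigurationError",
    "InvalidParameterSetError",
    "Cohort",
    "TimingConstants",
    "Strategy",
    "InpatientState",
    "PostdischargeState",
    "PathwayOutcome",
    "StrategyResult",
    "effective_relative_risk",
    "arm_probability",
    "combined_utility",
    "pathway_qaly",
    "pathway_cost",
    "enumerate_pathways",
    "expected_outcomes",
    "build_and_evaluate",
    "microsimulate",
    "DEFAULT_STRATEGY_RR",
]


class ModelError(Exception):
    """Base class for model errors."""


class ConfigurationError(ModelError):
    """A required parameter (cost, utility, probability) is missing."""


class InvalidParameterSetError(ModelError):
    """Chance-node probabilities are inconsistent (residual branch negative)."""


class Cohort(str, Enum):
    """Stroke type; cohorts are analysed separately because their baseline
    mortality differs."""

    ISCHEMIC = "ischemic"
    HEMORRHAGIC = "hemorrhagic"

    @classmethod
    def parse(cls, value: "str | Cohort") -> "Cohort":
        if isinstance(value, Cohort):
            return value
        aliases = {"is": cls.ISCHEMIC, "ha": cls.HEMORRHAGIC,
                   "ischemic": cls.ISCHEMIC, "hemorrhagic": cls.HEMORRHAGIC}
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ValueError(f"unknown cohort {value!r}; use 'is'/'ischemic' "
                             f"or 'ha'/'hemorrhagic'") from None


@dataclass(frozen=True)
class TimingConstants:
    """Timing of the two periods and of adverse events.

    Defaults encode the base model: 12-month horizon, 1-month inpatient stay,
    inpatient deaths on day 15 of the stay, and post-discharge complications
    at the start of month 7.  Months are 1/12 of a year for QALY weighting;
    the day-of-stay rule uses calendar days over 365.
    """

    horizon_months: int = 12
    inpatient_months: int = 1
    inpatient_death_day: int = 15
    postdischarge_event_month: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.inpatient_months < self.horizon_months:
            raise ValueError("require 0 < inpatient_months < horizon_months")
        if not 1 <= self.inpatient_death_day <= 30 * self.inpatient_months:
            raise ValueError("inpatient_death_day must fall within the stay")
        if not (self.inpatient_months < self.postdischarge_event_month
                <= self.horizon_months):
            raise ValueError("postdischarge_event_month must lie after "
                             "discharge and within the horizon")

    @property
    def horizon_years(self) -> float:
        return self.horizon_months / 12.0

    @property
    def inpatient_years(self) -> float:
        """Year fraction of the inpatient stay for survivors."""
        return self.inpatient_months / 12.0

    @property
    def inpatient_death_years(self) -> float:
        """Year fraction lived by patients who die on the death day."""
        return self.inpatient_death_day / 365.0

    @property
    def inpatient_stay_fraction_at_death(self) -> float:
        """Fraction of the inpatient stay completed at the death day."""
        return self.inpatient_death_day / (30.0 * self.inpatient_months)

    @property
    def pre_event_months(self) -> int:
        """Post-discharge months lived before the complication month."""
        return self.postdischarge_event_month - 1 - self.inpatient_months

    @property
    def post_event_months(self) -> int:
        """Months from the complication month to the end of the horizon."""
        return self.horizon_months - self.postdischarge_event_month + 1


VACOM = "VACOM"
IPC_MANUAL = "IPC_manual"


@dataclass(frozen=True)
class Strategy:
    """A comparator arm.  ``price_premium`` is the extra per-patient price of
    VACOM over IPC plus manual ankle movement, in 2019 S$ (0 for the
    comparator by definition)."""

    name: str
    price_premium: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in (VACOM, IPC_MANUAL):
            raise ValueError(f"unknown strategy {self.name!r}")
        if self.price_premium < 0:
            raise ValueError("price_premium must be >= 0")
        if self.name == IPC_MANUAL and self.price_premium != 0:
            raise ValueError("comparator price premium must be exactly 0")

    @property
    def is_intervention(self) -> bool:
        return self.name == VACOM

    @classmethod
    def vacom(cls, price_premium: float) -> "Strategy":
        return cls(VACOM, price_premium)

    @classmethod
    def ipc_manual(cls) -> "Strategy":
        return cls(IPC_MANUAL, 0.0)


@dataclass(frozen=True)
class InpatientState:
    """Inpatient-period events.  PE occurs only among DVT patients."""

    dvt: bool
    pe: bool
    died_inpatient: bool

    def __post_init__(self) -> None:
        if self.pe and not self.dvt:
            raise ValueError("PE is modelled as a DVT sequela: pe implies dvt")

    @property
    def code(self) -> str:
        """Mnemonic code: ndnp (no DVT, no PE), dnp (DVT only), dp (DVT+PE)."""
        if not self.dvt:
            return "ndnp"
        return "dp" if self.pe else "dnp"


class PostdischargeState(str, Enum):
    """Mutually exclusive post-discharge outcome (one chance node)."""

    WELL = "well"
    RECURRENT_STROKE = "recurrent_stroke"
    RECURRENT_DVT = "recurrent_dvt"
    RECURRENT_PE = "recurrent_pe"
    ANKLE_CONTRACTURE = "ankle_contracture"
    DEATH = "death"

    @property
    def code(self) -> str:
        return _POST_CODE[self]


_POST_CODE = {
    PostdischargeState.WELL: "well",
    PostdischargeState.RECURRENT_STROKE: "recstroke",
    PostdischargeState.RECURRENT_DVT: "recdvt",
    PostdischargeState.RECURRENT_PE: "recpe",
    PostdischargeState.ANKLE_CONTRACTURE: "ankcon",
    PostdischargeState.DEATH: "death",
}

#: baseline-probability parameter for each non-well post-discharge branch
POST_EVENT_PARAM = {
    PostdischargeState.RECURRENT_STROKE: "prob_recur_stroke",
    PostdischargeState.RECURRENT_DVT: "prob_recur_dvt",
    PostdischargeState.RECURRENT_PE: "prob_recur_pe",
    PostdischargeState.ANKLE_CONTRACTURE: "prob_ankcon",
    PostdischargeState.DEATH: "prob_death_postdis",
}

#: default mapping baseline probability -> relative-risk parameter applied in
#: the intervention arm (the parameter table may flag others)
DEFAULT_STRATEGY_RR = {
    "prob_dvt": "rr_dvt_vac_ipc",
    "prob_ankcon": "rr_ankcon_vac",
}

COMPLIANCE_PARAM = "prob_compliance_vac"


@dataclass
class PathwayOutcome:
    """One leaf of the decision tree."""

    label: str
    inpatient: InpatientState
    postdischarge: "PostdischargeState | None"
    probability: float
    cost: float
    qaly: float


@dataclass
class StrategyResult:
    """Expected cost and QALY per patient for one strategy, with the full
    pathway enumeration (or the empirical pathway table for a microsimulation,
    in which case Monte-Carlo standard errors are attached)."""

    strategy: Strategy
    expected_cost: float
    expected_qaly: float
    pathways: list[PathwayOutcome] = field(default_factory=list)
    cost_se: "float | None" = None
    qaly_se: "float | None" = None

    def to_frame(self) -> pd.DataFrame:
        """Flat pathway table: label, probability, cost, qaly."""
        return pd.DataFrame(
            {
                "pathway": [p.label for p in self.pathways],
                "probability": [p.probability for p in self.pathways],
                "cost": [p.cost for p in self.pathways],
                "qaly": [p.qaly for p in self.pathways],
            }
        )


# ---------------------------------------------------------------------------
# elementary operations


def _check_finite(name: str, value) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"{name} must be finite")


def effective_relative_risk(rr, compliance):
    """Compliance-diluted relative risk: ``compliance*rr + (1-compliance)``.

    A fraction ``compliance`` of patients use the device and experience the
    full relative risk ``rr``; the rest experience the comparator risk.  The
    mixture equals ``rr`` at full compliance and 1 at zero compliance.
    """
    _check_finite("rr", rr)
    _check_finite("compliance", compliance)
    if np.any(np.asarray(rr) <= 0):
        raise ValueError("rr must be > 0")
    if np.any((np.asarray(compliance) < 0) | (np.asarray(compliance) > 1)):
        raise ValueError("compliance must lie in [0, 1]")
    # rr == 1 mixes 1 with 1: short-circuit so a null effect stays exactly 1
    # (float round-off in c*rr + (1-c) would otherwise leak into ΔE)
    if np.ndim(rr) == 0 and np.ndim(compliance) == 0:
        return float(rr) if rr == 1.0 else compliance * rr + (1.0 - compliance)
    return np.where(np.asarray(rr) == 1.0, 1.0,
                    compliance * rr + (1.0 - compliance))


def arm_probability(baseline_prob, rr_effective):
    """Arm-specific event probability ``min(1, baseline * rr_effective)``."""
    if np.any((np.asarray(baseline_prob) < 0) | (np.asarray(baseline_prob) > 1)):
        raise ValueError("baseline_prob must lie in [0, 1]")
    if np.any(np.asarray(rr_effective) <= 0):
        raise ValueError("rr_effective must be > 0")
    return np.minimum(1.0, baseline_prob * rr_effective)


def combined_utility(base_utility, comorbidity_utilities: Iterable) -> float:
    """Multiplicative comorbidity adjustment of a state utility.

    The utility of living with several conditions is the product of the base
    utility and each comorbidity's utility weight; the result never exceeds
    any input.
    """
    out = base_utility
    for u in [base_utility, *comorbidity_utilities]:
        if np.any((np.asarray(u) < 0) | (np.asarray(u) > 1)):
            raise ValueError("utilities must lie in [0, 1]")
    for u in comorbidity_utilities:
        out = out * u
    return out


def _get(values: Mapping[str, object], key: str, context: str):
    try:
        return values[key]
    except KeyError:
        raise ConfigurationError(
            f"missing parameter {key!r} required for {context}"
        ) from None


def _whole_pathway_key(inpatient: InpatientState,
                       postdischarge: "PostdischargeState | None") -> str:
    if inpatient.died_inpatient:
        return f"qaly_{inpatient.code}_1m_death"
    assert postdischarge is not None
    return f"qaly_{inpatient.code}_1_12m_{postdischarge.code}"


def _inpatient_utility(inpatient: InpatientState, utilities: Mapping):
    base = _get(utilities, "util_poststroke", "inpatient utility")
    mults = []
    if inpatient.dvt:
        mults.append(_get(utilities, "util_dvt", "inpatient DVT utility"))
    if inpatient.pe:
        mults.append(_get(utilities, "util_pe", "inpatient PE utility"))
    return combined_utility(base, mults)


_POST_UTILITY_PARAM = {
    PostdischargeState.RECURRENT_STROKE: "util_recstroke",
    PostdischargeState.RECURRENT_DVT: "util_recdvt",
    PostdischargeState.RECURRENT_PE: "util_recpe",
    PostdischargeState.ANKLE_CONTRACTURE: "util_ankcon",
}


def pathway_qaly(inpatient: InpatientState,
                 postdischarge: "PostdischargeState | None",
                 utilities: Mapping,
                 timing: TimingConstants = TimingConstants()):
    """Time-weighted utility (in years) accrued along one pathway.

    If the lookup supplies a whole-pathway QALY value under the
    ``qaly_<inpatient>_1_12m_<outcome>`` / ``qaly_<inpatient>_1m_death``
    convention, it is returned directly.  Otherwise the QALY is decomposed:
    inpatient deaths accrue ``(death_day/365) * u_inpatient``; survivors
    accrue the inpatient month at ``u_inpatient``, months 2..6 at the well
    utility, and months 7..12 at the outcome utility (zero for post-discharge
    death).
    """
    if inpatient.died_inpatient and postdischarge is not None:
        raise ValueError("inpatient deaths have no post-discharge state")
    if not inpatient.died_inpatient and postdischarge is None:
        raise ValueError("survivors require a post-discharge state")

    key = _whole_pathway_key(inpatient, postdischarge)
    if key in utilities:
        return utilities[key]

    u_inp = _inpatient_utility(inpatient, utilities)
    if inpatient.died_inpatient:
        return timing.inpatient_death_years * u_inp

    base = _get(utilities, "util_poststroke", "post-discharge well utility")
    qaly = (timing.inpatient_years * u_inp
            + (timing.pre_event_months / 12.0) * base)
    if postdischarge is PostdischargeState.DEATH:
        return qaly
    if postdischarge is PostdischargeState.WELL:
        u_post = base
    else:
        mult = _get(utilities, _POST_UTILITY_PARAM[postdischarge],
                    f"utility of state {postdischarge.value}")
        u_post = combined_utility(base, [mult])
    return qaly + (timing.post_event_months / 12.0) * u_post


_POST_COST_PARAM = {
    PostdischargeState.RECURRENT_STROKE: "cost_recstroke",
    PostdischargeState.RECURRENT_DVT: "cost_recdvt",
    PostdischargeState.RECURRENT_PE: "cost_recpe",
    PostdischargeState.ANKLE_CONTRACTURE: "cost_ankcon",
    PostdischargeState.DEATH: "cost_death_postdis",
}


def pathway_cost(inpatient: InpatientState,
                 postdischarge: "PostdischargeState | None",
                 costs: Mapping,
                 strategy: Strategy,
                 timing: TimingConstants = TimingConstants()):
    """Healthcare-system cost (2019 S$) accrued along one pathway.

    Components: device cost (comparator device cost plus the VACOM price
    premium — charged to every intervention patient, compliant or not),
    inpatient stay cost (pro-rated to the death day for inpatient deaths),
    one-off event costs for each adverse event on the pathway, and monthly
    post-discharge care cost for months lived after discharge.
    """
    if inpatient.died_inpatient and postdischarge is not None:
        raise ValueError("inpatient deaths have no post-discharge state")
    if not inpatient.died_inpatient and postdischarge is None:
        raise ValueError("survivors require a post-discharge state")

    cost = _get(costs, "cost_device", "device cost")
    if strategy.is_intervention:
        cost = cost + strategy.price_premium

    stay = _get(costs, "cost_inpatient_stay", "inpatient stay cost")
    if inpatient.died_inpatient:
        cost = cost + stay * timing.inpatient_stay_fraction_at_death
    else:
        cost = cost + stay

    if inpatient.dvt:
        cost = cost + _get(costs, "cost_dvt", "inpatient DVT event cost")
    if inpatient.pe:
        cost = cost + _get(costs, "cost_pe", "inpatient PE event cost")

    if inpatient.died_inpatient:
        months_lived = 0
    elif postdischarge is PostdischargeState.DEATH:
        months_lived = timing.pre_event_months
    else:
        months_lived = timing.horizon_months - timing.inpatient_months
    cost = cost + months_lived * _get(costs, "cost_monthly_postdis",
                                      "monthly post-discharge care cost")

    if postdischarge is not None and postdischarge is not PostdischargeState.WELL:
        cost = cost + _get(costs, _POST_COST_PARAM[postdischarge],
                           f"cost of event {postdischarge.value}")
    return cost


# ---------------------------------------------------------------------------
# tree enumeration


def _event_probability(values: Mapping, name: str, strategy: Strategy,
                       rr_map: Mapping[str, str]):
    p = _get(values, name, f"probability {name}")
    if strategy.is_intervention and name in rr_map:
        rr = _get(values, rr_map[name], f"relative risk for {name}")
        compliance = _get(values, COMPLIANCE_PARAM, "device compliance rate")
        return arm_probability(p, effective_relative_risk(rr, compliance))
    return p


def _node_probabilities(values: Mapping, strategy: Strategy,
                        rr_map: Mapping[str, str]):
    """Chance-node probabilities shared by enumeration and microsimulation."""
    p_dvt = _event_probability(values, "prob_dvt", strategy, rr_map)
    p_pe = _event_probability(values, "prob_pe_dvt", strategy, rr_map)
    p_die_default = _get(values, "prob_death_inpatient",
                         "inpatient mortality")
    # per-inpatient-state mortality overrides are honoured when present
    p_die = {
        code: values.get(f"prob_death_inpatient_{code}", p_die_default)
        for code in ("ndnp", "dnp", "dp")
    }
    baseline = {state: _get(values, name, f"probability {name}")
                for state, name in POST_EVENT_PARAM.items()}
    base_total = sum(baseline.values())
    if np.any(np.asarray(base_total) > 1.0 + 1e-12):
        bad = int(np.sum(np.asarray(base_total) > 1.0 + 1e-12))
        raise InvalidParameterSetError(
            "baseline post-discharge branch probabilities sum to more than "
            f"1 ({bad} parameter set(s)); the residual 'well' branch would "
            "be negative")
    post = {
        state: _event_probability(values, name, strategy, rr_map)
        for state, name in POST_EVENT_PARAM.items()
    }
    # a strategy-modified branch (e.g. a harmful RR draw in the PSA tail)
    # may overflow the node: saturate the modified branches at the mass the
    # unmodified ones leave free -- the multi-branch analogue of the
    # min(1, p*rr) clip
    modified = [s for s, name in POST_EVENT_PARAM.items()
                if strategy.is_intervention and name in rr_map]
    if modified:
        unmod_total = sum(post[s] for s in post if s not in modified)
        mod_total = sum(post[s] for s in modified)
        available = 1.0 - unmod_total
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(np.asarray(mod_total) > np.asarray(available),
                             available / np.where(mod_total > 0, mod_total,
                                                  1.0),
                             1.0)
        for s in modified:
            post[s] = post[s] * scale
    residual = 1.0 - sum(post.values())
    post[PostdischargeState.WELL] = np.maximum(residual, 0.0)
    return p_dvt, p_pe, p_die, post


_INPATIENT_STATES = {
    "ndnp": (False, False),
    "dnp": (True, False),
    "dp": (True, True),
}


def enumerate_pathways(values: Mapping, strategy: Strategy,
                       timing: TimingConstants = TimingConstants(),
                       rr_map: "Mapping[str, str] | None" = None
                       ) -> list[PathwayOutcome]:
    """Exhaustively enumerate the 21 pathways of the two-period tree.

    ``values`` maps parameter names to scalars or NumPy arrays; with arrays
    the enumeration is vectorised across parameter sets.
    """
    if rr_map is None:
        rr_map = DEFAULT_STRATEGY_RR
    p_dvt, p_pe, p_die, post = _node_probabilities(values, strategy, rr_map)

    inpatient_prob = {
        "ndnp": 1.0 - p_dvt,
        "dnp": p_dvt * (1.0 - p_pe),
        "dp": p_dvt * p_pe,
    }

    leaves: list[PathwayOutcome] = []
    for code, (dvt, pe) in _INPATIENT_STATES.items():
        died = InpatientState(dvt, pe, True)
        leaves.append(PathwayOutcome(
            label=f"{code}_inpdeath",
            inpatient=died,
            postdischarge=None,
            probability=inpatient_prob[code] * p_die[code],
            cost=pathway_cost(died, None, values, strategy, timing),
            qaly=pathway_qaly(died, None, values, timing),
        ))
        alive = InpatientState(dvt, pe, False)
        p_survive = inpatient_prob[code] * (1.0 - p_die[code])
        for state in PostdischargeState:
            leaves.append(PathwayOutcome(
                label=f"{code}_{state.code}",
                inpatient=alive,
                postdischarge=state,
                probability=p_survive * post[state],
                cost=pathway_cost(alive, state, values, strategy, timing),
                qaly=pathway_qaly(alive, state, values, timing),
            ))
    return leaves


def expected_outcomes(values: Mapping, strategy: Strategy,
                      timing: TimingConstants = TimingConstants(),
                      rr_map: "Mapping[str, str] | None" = None):
    """Probability-weighted expected (cost, qaly); vectorised over arrays."""
    leaves = enumerate_pathways(values, strategy, timing, rr_map)
    cost = sum(leaf.probability * leaf.cost for leaf in leaves)
    qaly = sum(leaf.probability * leaf.qaly for leaf in leaves)
    return cost, qaly


def _resolve_inputs(cohort, params, scenario):
    """Extract (values, rr_map, timing) from a ParameterTable or a Mapping."""
    cohort = Cohort.parse(cohort)
    timing = scenario.timing if scenario is not None else TimingConstants()
    if hasattr(params, "cohort_values"):
        values = params.cohort_values(cohort)
        rr_map = params.strategy_rr_map(cohort)
        if not rr_map:
            rr_map = DEFAULT_STRATEGY_RR
    else:
        values = dict(params)
        rr_map = DEFAULT_STRATEGY_RR
    return values, rr_map, timing


def build_and_evaluate(cohort, strategy: Strategy, params,
                       scenario: "ScenarioConfig | None" = None
                       ) -> StrategyResult:
    """Evaluate the tree at base-case parameter values by exact enumeration.

    ``params`` is a :class:`~vacomhta.parameters.ParameterTable` (resolved for
    the cohort internally) or a plain name->value mapping.  Scenario RR
    overrides and the price premium are applied to the table and strategy by
    :func:`vacomhta.parameters.apply_scenario` / :meth:`Strategy.vacom`;
    ``scenario`` here supplies the timing constants.
    """
    values, rr_map, timing = _resolve_inputs(cohort, params, scenario)
    leaves = enumerate_pathways(values, strategy, timing, rr_map)
    total = sum(leaf.probability for leaf in leaves)
    if abs(total - 1.0) > 1e-12:
        raise InvalidParameterSetError(
            f"pathway probabilities sum to {total!r}, not 1")
    cost = sum(leaf.probability * leaf.cost for leaf in leaves)
    qaly = sum(leaf.probability * leaf.qaly for leaf in leaves)
    return StrategyResult(strategy, float(cost), float(qaly), leaves)


def microsimulate(cohort, strategy: Strategy, params,
                  scenario: "ScenarioConfig | None" = None,
                  n_patients: int = 10_000,
                  seed: "int | Sequence[int]" = 0) -> StrategyResult:
    """Monte-Carlo oracle: individual patients drawn through the same tree.

    Each patient's pathway is sampled by staged Bernoulli/categorical draws
    at the chance nodes; the patient accrues the pathway's cost and QALY.
    Means converge to :func:`build_and_evaluate` as ``n_patients`` grows;
    Monte-Carlo standard errors of the means are attached to the result.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    values, rr_map, timing = _resolve_inputs(cohort, params, scenario)
    p_dvt, p_pe, p_die, post = _node_probabilities(values, strategy, rr_map)

    rng = np.random.default_rng(seed)
    n = int(n_patients)
    dvt = rng.random(n) < p_dvt
    pe = dvt & (rng.random(n) < p_pe)
    codes = np.where(~dvt, 0, np.where(~pe, 1, 2))  # ndnp, dnp, dp
    die_p = np.array([p_die["ndnp"], p_die["dnp"], p_die["dp"]], dtype=float)
    died = rng.random(n) < die_p[codes]

    post_states = list(PostdischargeState)
    post_probs = np.array([post[s] for s in post_states], dtype=float)
    edges = np.cumsum(post_probs)
    outcome_idx = np.searchsorted(edges, rng.random(n) * edges[-1],
                                  side="right")
    outcome_idx = np.minimum(outcome_idx, len(post_states) - 1)

    # per-leaf cost/qaly are deterministic given the parameter set: tabulate
    # the 21 leaves once, then index per patient
    cost_lut = np.zeros((3, len(post_states) + 1))
    qaly_lut = np.zeros_like(cost_lut)
    for c, (code, (d, p)) in enumerate(_INPATIENT_STATES.items()):
        dead = InpatientState(d, p, True)
        cost_lut[c, -1] = pathway_cost(dead, None, values, strategy, timing)
        qaly_lut[c, -1] = pathway_qaly(dead, None, values, timing)
        alive = InpatientState(d, p, False)
        for k, state in enumerate(post_states):
            cost_lut[c, k] = pathway_cost(alive, state, values, strategy,
                                          timing)
            qaly_lut[c, k] = pathway_qaly(alive, state, values, timing)

    col = np.where(died, len(post_states), outcome_idx)
    costs = cost_lut[codes, col]
    qalys = qaly_lut[codes, col]

    pathways: list[PathwayOutcome] = []
    for c, (code, (d, p)) in enumerate(_INPATIENT_STATES.items()):
        mask_dead = (codes == c) & died
        pathways.append(PathwayOutcome(
            label=f"{code}_inpdeath",
            inpatient=InpatientState(d, p, True), postdischarge=None,
            probability=float(mask_dead.mean()),
            cost=float(cost_lut[c, -1]), qaly=float(qaly_lut[c, -1])))
        for k, state in enumerate(post_states):
            mask = (codes == c) & ~died & (outcome_idx == k)
            pathways.append(PathwayOutcome(
                label=f"{code}_{state.code}",
                inpatient=InpatientState(d, p, False), postdischarge=state,
                probability=float(mask.mean()),
                cost=float(cost_lut[c, k]), qaly=float(qaly_lut[c, k])))

    return StrategyResult(
        strategy,
        expected_cost=float(costs.mean()),
        expected_qaly=float(qalys.mean()),
        pathways=pathways,
        cost_se=float(costs.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        qaly_se=float(qalys.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
    )
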