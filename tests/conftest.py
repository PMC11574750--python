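"""Shared fixtures: the packaged synthetic table, scenario presets, and a
deterministic all-fixed toy table for hand-checkable oracles."""

from __future__ import annotations

import math

import pytest
from hypothesis import settings

from vacomhta.parameters import ParameterSpec, ParameterTable, ScenarioConfig
from vacomhta.synthetic import default_parameter_table, get_scenario

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


#: deterministic base values for toy models (decomposed-utility mode)
FIXED_BASE = {
    "prob_dvt": 0.08,
    "prob_pe_dvt": 0.20,
    "prob_death_inpatient": 0.10,
    "prob_recur_stroke": 0.07,
    "prob_recur_dvt": 0.03,
    "prob_recur_pe": 0.01,
    "prob_ankcon": 0.30,
    "prob_death_postdis": 0.07,
    "prob_compliance_vac": 0.80,
    "rr_dvt_vac_ipc": 0.70,
    "rr_ankcon_vac": 0.90,
    "cost_device": 500.0,
    "cost_inpatient_stay": 20_000.0,
    "cost_dvt": 3_500.0,
    "cost_pe": 9_000.0,
    "cost_recstroke": 15_000.0,
    "cost_recdvt": 3_500.0,
    "cost_recpe": 9_000.0,
    "cost_ankcon": 5_000.0,
    "cost_death_postdis": 1_000.0,
    "cost_monthly_postdis": 400.0,
    "util_poststroke": 0.70,
    "util_dvt": 0.90,
    "util_pe": 0.82,
    "util_recstroke": 0.70,
    "util_recdvt": 0.90,
    "util_recpe": 0.82,
    "util_ankcon": 0.78,
}

_ROLE = {"prob": "probability", "rr": "relative_risk", "cost": "cost",
         "util": "utility", "qaly": "whole_pathway_qaly"}
_STRATEGY_RR = {"prob_dvt": "rr_dvt_vac_ipc", "prob_ankcon": "rr_ankcon_vac"}


def make_fixed_table(overrides: "dict | None" = None,
                     variable: "tuple[str, ...]" = (),
                     se_fraction: float = 0.2) -> ParameterTable:
    """All-parameters-fixed toy table, with optional overrides and a subset
    of parameters carrying fitted PSA distributions (``variable``)."""
    base = {**FIXED_BASE, **(overrides or {})}
    specs = []
    for name, value in base.items():
        role = _ROLE[name.split("_", 1)[0]]
        if name in variable:
            spec = ParameterSpec(name=name, cohort="both", role=role,
                                 base_value=value,
                                 se=se_fraction * abs(value),
                                 strategy_rr=_STRATEGY_RR.get(name, ""))
        else:
            spec = ParameterSpec(name=name, cohort="both", role=role,
                                 base_value=value, dist_family="fixed",
                                 strategy_rr=_STRATEGY_RR.get(name, ""))
        specs.append(spec)
    return ParameterTable(specs)


@pytest.fixture(scope="session")
def default_table():
    return default_parameter_table()


@pytest.fixture(scope="session")
def conservative_150():
    return get_scenario("conservative_premium150")


@pytest.fixture(scope="session")
def conservative_300():
    return get_scenario("conservative_premium300")


@pytest.fixture(scope="session")
def optimistic_150():
    return get_scenario("optimistic_premium150")


@pytest.fixture()
def fixed_table():
    return make_fixed_table()


@pytest.fixture()
def custom_scenario():
    def _make(rr: float = 0.9, premium: float = 150.0,
              threshold: float = 75_000.0, **kw) -> ScenarioConfig:
        return ScenarioConfig(name="custom",
                              rr_ankle_contracture_vacom=rr,
                              price_premium=premium, threshold=threshold,
                              **kw)
    return _make
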