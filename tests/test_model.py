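"""Decision-tree core: elementary operations, pathway accounting, exact
enumeration versus independent oracles, and structural invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vacomhta.model import (ConfigurationError, InpatientState,
                            InvalidParameterSetError, PostdischargeState,
                            Strategy, TimingConstants, arm_probability,
                            build_and_evaluate, combined_utility,
                            effective_relative_risk, enumerate_pathways,
                            microsimulate, pathway_cost, pathway_qaly)
from vacomhta.synthetic import GeneratorProfile, generate_parameter_table

from conftest import FIXED_BASE

TIMING = TimingConstants()


# ---------------------------------------------------------------------------
# elementary operations


@pytest.mark.parametrize("rr, compliance, expected", [
    (0.3, 1.0, 0.3),   # full compliance: the raw relative risk
    (0.3, 0.0, 1.0),   # zero compliance: comparator effect
    (0.5, 0.8, 0.6),   # mixture 0.8*0.5 + 0.2*1
])
def test_effective_relative_risk_examples(rr, compliance, expected):
    assert effective_relative_risk(rr, compliance) == pytest.approx(expected)


@given(rr=st.floats(0.01, 5.0), c1=st.floats(0, 1), c2=st.floats(0, 1))
def test_effective_relative_risk_is_a_mixture(rr, c1, c2):
    """The diluted RR lies between rr and 1 and moves monotonically with
    compliance when the device is protective."""
    lo, hi = min(rr, 1.0), max(rr, 1.0)
    eff = effective_relative_risk(rr, c1)
    assert lo - 1e-12 <= eff <= hi + 1e-12
    if rr < 1 and c1 < c2:
        assert effective_relative_risk(rr, c2) <= eff + 1e-12


@pytest.mark.parametrize("bad", [math.nan, math.inf])
def test_effective_relative_risk_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        effective_relative_risk(bad, 0.5)
    with pytest.raises(ValueError):
        effective_relative_risk(0.5, bad)


@pytest.mark.parametrize("p, rr, expected", [
    (0.10, 1.0, 0.10),  # comparator identity
    (0.10, 0.3, 0.03),
    (0.60, 2.0, 1.0),   # clipped at 1
])
def test_arm_probability(p, rr, expected):
    assert arm_probability(p, rr) == pytest.approx(expected)


@pytest.mark.parametrize("base, mults, expected", [
    (0.8, [0.9], 0.72),
    (0.7, [], 0.7),
    (0.8, [0.9, 0.5], 0.36),
])
def test_combined_utility_examples(base, mults, expected):
    assert combined_utility(base, mults) == pytest.approx(expected)


@given(base=st.floats(0, 1),
       mults=st.lists(st.floats(0, 1), max_size=4))
def test_combined_utility_never_exceeds_any_input(base, mults):
    out = combined_utility(base, mults)
    assert out <= min([base, *mults]) + 1e-12


def test_combined_utility_rejects_out_of_range():
    with pytest.raises(ValueError):
        combined_utility(1.2, [0.9])
    with pytest.raises(ValueError):
        combined_utility(0.8, [-0.1])


# ---------------------------------------------------------------------------
# pathway accounting


def test_pathway_qaly_inpatient_death():
    """A day-15 inpatient death accrues 15/365 of a year at the inpatient
    utility: 0.5 * 15/365."""
    state = InpatientState(False, False, True)
    q = pathway_qaly(state, None, {"util_poststroke": 0.5}, TIMING)
    assert q == pytest.approx(0.5 * 15 / 365, rel=1e-12)


def test_pathway_qaly_full_health_year_is_exactly_one():
    utilities = {k: 1.0 for k in FIXED_BASE if k.startswith("util_")}
    q = pathway_qaly(InpatientState(False, False, False),
                     PostdischargeState.WELL, utilities, TIMING)
    assert q == pytest.approx(1.0, abs=1e-15)


def test_pathway_qaly_whole_pathway_passthrough():
    q = pathway_qaly(InpatientState(False, False, False),
                     PostdischargeState.WELL,
                     {"qaly_ndnp_1_12m_well": 0.62}, TIMING)
    assert q == 0.62


def test_pathway_qaly_death_truncates_at_event_month():
    """A post-discharge death accrues the inpatient month plus months 2-6
    at the well utility and nothing afterwards."""
    u = {"util_poststroke": 0.7}
    q = pathway_qaly(InpatientState(False, False, False),
                     PostdischargeState.DEATH, u, TIMING)
    assert q == pytest.approx(0.7 / 12 + 5 * 0.7 / 12, rel=1e-12)


def test_pathway_qaly_missing_utility_names_the_state():
    with pytest.raises(ConfigurationError, match="ankle_contracture"):
        pathway_qaly(InpatientState(False, False, False),
                     PostdischargeState.ANKLE_CONTRACTURE,
                     {"util_poststroke": 0.7}, TIMING)


def test_pathway_cost_additive_sum():
    costs = {"cost_device": 500.0, "cost_inpatient_stay": 8_000.0,
             "cost_monthly_postdis": 0.0}
    well = PostdischargeState.WELL
    alive = InpatientState(False, False, False)
    assert pathway_cost(alive, well, costs, Strategy.vacom(150.0),
                        TIMING) == pytest.approx(8_650.0)
    assert pathway_cost(alive, well, costs, Strategy.ipc_manual(),
                        TIMING) == pytest.approx(8_500.0)


def test_pathway_cost_day15_death_matches_daily_accrual():
    """The half-stay rule for day-15 deaths equals an independent
    day-by-day accrual of the monthly stay cost."""
    costs = {"cost_device": 500.0, "cost_inpatient_stay": 8_000.0,
             "cost_monthly_postdis": 0.0}
    dead = InpatientState(False, False, True)
    got = pathway_cost(dead, None, costs, Strategy.ipc_manual(), TIMING)
    daily = 8_000.0 / 30.0
    accrued = sum(daily for _ in range(15))  # days 1..15 of the stay
    assert got == pytest.approx(500.0 + accrued)
    assert got == pytest.approx(4_500.0)


def test_pathway_cost_missing_entry_names_it():
    with pytest.raises(ConfigurationError, match="cost_inpatient_stay"):
        pathway_cost(InpatientState(False, False, False),
                     PostdischargeState.WELL, {"cost_device": 1.0},
                     Strategy.ipc_manual(), TIMING)


def test_pe_requires_dvt():
    with pytest.raises(ValueError):
        InpatientState(dvt=False, pe=True, died_inpatient=False)


def test_timing_invariants():
    with pytest.raises(ValueError):
        TimingConstants(inpatient_months=12)
    with pytest.raises(ValueError):
        TimingConstants(inpatient_death_day=31)
    with pytest.raises(ValueError):
        TimingConstants(postdischarge_event_month=1)


# ---------------------------------------------------------------------------
# tree enumeration vs independent oracle


def brute_force_expected(values: dict, strategy: Strategy,
                         timing: TimingConstants = TIMING):
    """Independent exhaustive enumeration, written directly from the model
    description (nested loops and explicit arithmetic; no tree builder)."""
    def eff(rr_name):
        if not strategy.is_intervention:
            return 1.0
        rr = values[rr_name]
        c = values["prob_compliance_vac"]
        return c * rr + (1 - c)

    p_dvt = min(1.0, values["prob_dvt"] * eff("rr_dvt_vac_ipc"))
    p_pe = values["prob_pe_dvt"]
    p_die = values["prob_death_inpatient"]
    p_ank = min(1.0, values["prob_ankcon"] * eff("rr_ankcon_vac"))
    post = {
        "recstroke": values["prob_recur_stroke"],
        "recdvt": values["prob_recur_dvt"],
        "recpe": values["prob_recur_pe"],
        "ankcon": p_ank,
        "death": values["prob_death_postdis"],
    }
    post["well"] = 1.0 - sum(post.values())

    u = values
    device = values["cost_device"] + (strategy.price_premium
                                      if strategy.is_intervention else 0.0)
    exp_cost = exp_qaly = total_p = 0.0
    for dvt in (False, True):
        for pe in ((False, True) if dvt else (False,)):
            p_inp = ((p_dvt * (p_pe if pe else 1 - p_pe)) if dvt
                     else (1 - p_dvt))
            u_inp = u["util_poststroke"] * (u["util_dvt"] if dvt else 1.0) \
                * (u["util_pe"] if pe else 1.0)
            event_cost = (u["cost_dvt"] if dvt else 0.0) \
                + (u["cost_pe"] if pe else 0.0)
            # inpatient death on day 15
            p_leaf = p_inp * p_die
            cost = device + values["cost_inpatient_stay"] / 2 + event_cost
            qaly = (15 / 365) * u_inp
            exp_cost += p_leaf * cost
            exp_qaly += p_leaf * qaly
            total_p += p_leaf
            # survivors: one post-discharge outcome at the start of month 7
            for out, p_out in post.items():
                p_leaf = p_inp * (1 - p_die) * p_out
                months = 5 if out == "death" else 11
                cost = (device + values["cost_inpatient_stay"] + event_cost
                        + months * values["cost_monthly_postdis"])
                if out != "well":
                    cost += values[f"cost_{out}"] if out != "death" \
                        else values["cost_death_postdis"]
                qaly = u_inp / 12 + 5 * u["util_poststroke"] / 12
                if out == "well":
                    qaly += 6 * u["util_poststroke"] / 12
                elif out != "death":
                    qaly += 6 * u["util_poststroke"] * u[f"util_{out}"] / 12
                exp_cost += p_leaf * cost
                exp_qaly += p_leaf * qaly
                total_p += p_leaf
    assert abs(total_p - 1.0) < 1e-12
    return exp_cost, exp_qaly


@pytest.mark.parametrize("strategy", [Strategy.vacom(150.0),
                                      Strategy.ipc_manual()])
def test_enumeration_matches_brute_force_oracle(strategy):
    values = dict(FIXED_BASE)
    res = build_and_evaluate("is", strategy, values)
    cost, qaly = brute_force_expected(values, strategy)
    assert res.expected_cost == pytest.approx(cost, rel=1e-12)
    assert res.expected_qaly == pytest.approx(qaly, rel=1e-12)
    assert sum(p.probability for p in res.pathways) == pytest.approx(
        1.0, abs=1e-12)


def test_toy_tree_hand_enumeration():
    """3-parameter toy tree (p_dvt=0.2, inpatient death 0.1, rest well)."""
    values = {**{k: 0.0 for k in FIXED_BASE if k.startswith("prob_")},
              **{k: v for k, v in FIXED_BASE.items()
                 if not k.startswith("prob_")},
              "prob_dvt": 0.2, "prob_death_inpatient": 0.1,
              "prob_compliance_vac": 1.0}
    res = build_and_evaluate("is", Strategy.ipc_manual(), values)
    cost, qaly = brute_force_expected(values, Strategy.ipc_manual())
    assert res.expected_cost == pytest.approx(cost, rel=1e-12)
    assert res.expected_qaly == pytest.approx(qaly, rel=1e-12)


def test_degenerate_tree_single_pathway():
    """All adverse-event probabilities 0: one pathway with probability 1
    whose QALY is the well-year value."""
    values = {**FIXED_BASE,
              **{k: 0.0 for k in FIXED_BASE if k.startswith("prob_")},
              "prob_compliance_vac": 0.8}
    for strategy in (Strategy.vacom(150.0), Strategy.ipc_manual()):
        res = build_and_evaluate("is", strategy, values)
        live = [p for p in res.pathways if p.probability > 0]
        assert len(live) == 1 and live[0].label == "ndnp_well"
        well = (values["util_poststroke"] / 12
                + 11 * values["util_poststroke"] / 12)
        assert res.expected_qaly == pytest.approx(well, rel=1e-12)


def test_identity_when_rrs_one_and_premium_zero():
    """RRs of 1 and a zero premium make the two arms exactly identical."""
    values = {**FIXED_BASE, "rr_dvt_vac_ipc": 1.0, "rr_ankcon_vac": 1.0}
    vac = build_and_evaluate("is", Strategy.vacom(0.0), values)
    ipc = build_and_evaluate("is", Strategy.ipc_manual(), values)
    assert vac.expected_cost == ipc.expected_cost
    assert vac.expected_qaly == ipc.expected_qaly


def test_invalid_postdischarge_probabilities_rejected():
    values = {**FIXED_BASE, "prob_ankcon": 0.7, "prob_recur_stroke": 0.4}
    with pytest.raises(InvalidParameterSetError):
        build_and_evaluate("is", Strategy.ipc_manual(), values)


@pytest.mark.parametrize("cohort", ["is", "ha"])
@pytest.mark.parametrize("seed", [0, 7, 42])
def test_generated_tables_pathway_probabilities_sum_to_one(cohort, seed):
    table = generate_parameter_table(GeneratorProfile(seed=seed))
    for strategy in (Strategy.vacom(300.0), Strategy.ipc_manual()):
        res = build_and_evaluate(cohort, strategy, table)
        assert sum(p.probability for p in res.pathways) == pytest.approx(
            1.0, abs=1e-12)


def test_per_state_inpatient_mortality_overrides():
    values = {**FIXED_BASE, "prob_death_inpatient_dp": 0.5}
    res = build_and_evaluate("is", Strategy.ipc_manual(), values)
    by_label = {p.label: p for p in res.pathways}
    p_dp = FIXED_BASE["prob_dvt"] * FIXED_BASE["prob_pe_dvt"]
    assert by_label["dp_inpdeath"].probability == pytest.approx(p_dp * 0.5)
    assert by_label["ndnp_inpdeath"].probability == pytest.approx(
        (1 - FIXED_BASE["prob_dvt"]) * 0.1)


# ---------------------------------------------------------------------------
# microsimulation oracle


def test_microsim_degenerate_equals_enumeration():
    values = {**FIXED_BASE,
              **{k: 0.0 for k in FIXED_BASE if k.startswith("prob_")},
              "prob_compliance_vac": 0.8}
    enum = build_and_evaluate("is", Strategy.ipc_manual(), values)
    ms = microsimulate("is", Strategy.ipc_manual(), values, n_patients=50,
                       seed=0)
    assert ms.expected_cost == pytest.approx(enum.expected_cost, rel=1e-12)
    assert ms.expected_qaly == pytest.approx(enum.expected_qaly, rel=1e-12)


def test_microsim_single_patient_is_one_pathway():
    res = microsimulate("is", Strategy.ipc_manual(), dict(FIXED_BASE),
                        n_patients=1, seed=5)
    labels = {p.label: p.probability for p in res.pathways}
    hits = [lbl for lbl, pr in labels.items() if pr == 1.0]
    assert len(hits) == 1
    enum = build_and_evaluate("is", Strategy.ipc_manual(), dict(FIXED_BASE))
    exact = {p.label: (p.cost, p.qaly) for p in enum.pathways}
    assert (res.expected_cost, res.expected_qaly) == pytest.approx(
        exact[hits[0]])


@pytest.mark.parametrize("strategy", [Strategy.vacom(150.0),
                                      Strategy.ipc_manual()])
def test_microsim_converges_to_enumeration(strategy):
    values = dict(FIXED_BASE)
    enum = build_and_evaluate("is", strategy, values)
    ms = microsimulate("is", strategy, values, n_patients=200_000, seed=11)
    assert abs(ms.expected_cost - enum.expected_cost) < 3 * ms.cost_se
    assert abs(ms.expected_qaly - enum.expected_qaly) < 3 * ms.qaly_se


@given(seed=st.integers(0, 10_000))
def test_microsim_agrees_over_random_tables(seed):
    """Property: enumeration and microsimulation agree within Monte-Carlo
    error on seeded synthetic parameter tables."""
    table = generate_parameter_table(GeneratorProfile(seed=seed % 1000))
    enum = build_and_evaluate("is", Strategy.vacom(150.0), table)
    ms = microsimulate("is", Strategy.vacom(150.0), table,
                       n_patients=20_000, seed=seed)
    assert abs(ms.expected_cost - enum.expected_cost) < 4 * ms.cost_se
    assert abs(ms.expected_qaly - enum.expected_qaly) < 4 * ms.qaly_se


# ---------------------------------------------------------------------------
# monotonicity and round trips


MORBIDITY_PROBS = ["prob_dvt", "prob_pe_dvt", "prob_recur_stroke",
                   "prob_recur_dvt", "prob_recur_pe", "prob_ankcon"]


@pytest.mark.parametrize("param", MORBIDITY_PROBS)
def test_lowering_morbidity_probability_helps(param):
    """Lowering a morbidity probability never lowers expected QALY and
    never raises expected cost (event costs >= 0 and complication utilities
    <= the well utility)."""
    for strategy in (Strategy.vacom(150.0), Strategy.ipc_manual()):
        base = build_and_evaluate("is", strategy, dict(FIXED_BASE))
        lowered = build_and_evaluate(
            "is", strategy, {**FIXED_BASE, param: 0.5 * FIXED_BASE[param]})
        assert lowered.expected_qaly >= base.expected_qaly - 1e-12
        assert lowered.expected_cost <= base.expected_cost + 1e-9


@pytest.mark.parametrize("cohort", ["is", "ha"])
def test_whole_pathway_and_decomposed_modes_agree(cohort):
    """Whole-pathway QALY parameters computed from the decomposed rule give
    the same expected outcomes as the decomposed utilities themselves."""
    whole = generate_parameter_table(
        GeneratorProfile(seed=3, qaly_mode="whole_pathway"))
    decomp = generate_parameter_table(
        GeneratorProfile(seed=3, qaly_mode="decomposed"))
    for strategy in (Strategy.vacom(150.0), Strategy.ipc_manual()):
        a = build_and_evaluate(cohort, strategy, whole)
        b = build_and_evaluate(cohort, strategy, decomp)
        assert a.expected_qaly == pytest.approx(b.expected_qaly, rel=1e-12)
        assert a.expected_cost == pytest.approx(b.expected_cost, rel=1e-12)


def test_strategy_result_frame_and_expectation_consistency(fixed_table):
    res = build_and_evaluate("is", Strategy.vacom(150.0), fixed_table)
    df = res.to_frame()
    assert res.expected_cost == pytest.approx(
        float((df.probability * df.cost).sum()), rel=1e-9)
    assert res.expected_qaly == pytest.approx(
        float((df.probability * df.qaly).sum()), rel=1e-9)
    assert (df.cost >= 0).all()
    assert df.qaly.between(0, 1).all()
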