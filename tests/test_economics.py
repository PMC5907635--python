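"""Economics: discounting, per-cycle costs/QALYs, accumulation, comparison."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from oabcea import ArmResult, compare, discount_factor, net_monetary_benefit, \
    run_cohort
from oabcea.economics import (CLASS_CE, CLASS_DOMINANT, CLASS_DOMINATED,
                              CLASS_EQUIVALENT, CLASS_NOT_CE, accumulate,
                              cycle_cost, cycle_qaly)
from oabcea.engine import (N_PATHWAY, PHASE_FIRST, PHASE_OFF,
                           CohortDistribution, CycleTally, state_index)
from oabcea.transitions import identity_model


# -- discounting -------------------------------------------------------------

@pytest.mark.parametrize("cycle, rate, expected", [
    (1, 0.035, 1.0),
    (7, 0.0, 1.0),
    (13, 0.035, 0.96618),   # one year out
    (61, 0.035, 1.035 ** -5),
])
def test_discount_factor(cycle, rate, expected):
    assert discount_factor(cycle, rate) == pytest.approx(expected, abs=5e-6)


def test_discount_factor_rejects_cycle_zero():
    with pytest.raises(ValueError):
        discount_factor(0, 0.035)


# -- per-cycle costs and QALYs ----------------------------------------------

def _point_mass(params, phase_kwargs, mict, incont):
    L = params.n_levels
    mass = np.zeros((N_PATHWAY, L * L))
    mass[state_index(**phase_kwargs), (mict - 1) * L + (incont - 1)] = 1.0
    return CohortDistribution(mass, L)


def test_cycle_cost_off_treatment_pads_only(default_params):
    dist = _point_mass(default_params, dict(phase=PHASE_OFF, fails=0), 5, 5)
    costs = cycle_cost(dist, CycleTally(), default_params, "solifenacin_5mg")
    assert costs["pads"] == pytest.approx(121.30 * 0.17)
    for k, v in costs.items():
        if k != "pads":
            assert v == 0.0


def test_cycle_cost_on_first_line(default_params):
    dist = _point_mass(default_params,
                       dict(phase=PHASE_FIRST, month=1, fails=0, ae=0), 3, 1)
    costs = cycle_cost(dist, CycleTally(), default_params, "solifenacin_5mg")
    assert costs["drug_acquisition"] == pytest.approx(28.00)
    assert costs["pads"] == pytest.approx(6.97 * 0.17)
    assert costs["other_oab_drugs"] == 0.0


def test_entry_and_later_initiations_cost_different_gp_rates(default_params):
    dist = _point_mass(default_params,
                       dict(phase=PHASE_FIRST, month=1, fails=0, ae=0), 5, 5)
    entry = cycle_cost(dist, CycleTally(entries=1.0), default_params, "solifenacin_5mg")
    later = cycle_cost(dist, CycleTally(switches=0.5, restarts=0.5),
                       default_params, "solifenacin_5mg")
    assert entry["gp_visits"] == pytest.approx(65.00)
    assert entry["specialist_visits"] == pytest.approx(94.00)
    assert later["gp_visits"] == pytest.approx(27.00)
    assert later["specialist_visits"] == pytest.approx(94.00)


def test_btxa_injections_costed(default_params):
    dist = _point_mass(default_params, dict(phase=PHASE_OFF, fails=2), 5, 5)
    costs = cycle_cost(dist, CycleTally(btxa_injections=0.001, btxa_reinjections=0.002),
                       default_params, "solifenacin_5mg")
    assert costs["btxa"] == pytest.approx(0.003 * 1151.98)


def _qaly_params(default_params):
    p = default_params.copy()
    p.utility.base_utility = 0.80
    return p


@pytest.mark.parametrize("mict, incont, ae, expected", [
    (5, 5, 0, 0.80 / 12),
    (5, 5, 1, (0.80 - 0.0357) / 12),
    (1, 1, 0, (0.80 + 0.0632 + 0.0586) / 12),
])
def test_cycle_qaly_point_masses(default_params, mict, incont, ae, expected):
    p = _qaly_params(default_params)
    dist = _point_mass(p, dict(phase=PHASE_FIRST, month=2, fails=0, ae=ae),
                       mict, incont)
    assert cycle_qaly(dist, p) == pytest.approx(expected, abs=1e-12)


def test_ae_decrement_not_applied_off_treatment(default_params):
    p = _qaly_params(default_params)
    dist = _point_mass(p, dict(phase=PHASE_OFF, fails=1), 5, 5)
    assert cycle_qaly(dist, p) == pytest.approx(0.80 / 12)


# -- accumulation ------------------------------------------------------------

def _constant_stream_params(toy_params, rate):
    p = toy_params.copy()
    p.settings.horizon = 60
    p.settings.annual_discount_rate = rate
    for d in p.drugs:
        d.ae_prob_3m = {"dry_mouth": 0.0, "constipation": 0.0}
    p.pathway.p_discontinue_no_ae = 0.0
    p.transition_models = {name: identity_model(name, 2) for name in p.drug_names()}
    return p


def test_accumulate_geometric_series_closed_form(toy_params):
    p = _constant_stream_params(toy_params, 0.035)
    trace = run_cohort(p, "solifenacin_5mg")
    arm = accumulate(trace, p)
    per_cycle = cycle_cost(trace.cycles[5].start, CycleTally(), p, "solifenacin_5mg")
    c = sum(per_cycle.values())
    series = sum(1.035 ** (-(t - 1) / 12) for t in range(1, 61))
    expected = c * series + 65.00 + 94.00  # entry visits hit cycle 1 only
    assert arm.total_cost == pytest.approx(expected, abs=1e-9)


def test_accumulate_without_discounting_is_sixty_fold(toy_params):
    p = _constant_stream_params(toy_params, 0.0)
    trace = run_cohort(p, "solifenacin_5mg")
    arm = accumulate(trace, p)
    per_cycle = cycle_cost(trace.cycles[5].start, CycleTally(), p, "solifenacin_5mg")
    assert arm.total_cost == pytest.approx(60 * sum(per_cycle.values()) + 65.0 + 94.0,
                                           abs=1e-9)
    q = cycle_qaly(trace.cycles[0].start, p)
    assert arm.total_qalys == pytest.approx(60 * q, abs=1e-9)


def test_discounted_total_below_undiscounted(toy_params):
    t0 = run_cohort(_constant_stream_params(toy_params, 0.0), "solifenacin_5mg")
    t35 = run_cohort(_constant_stream_params(toy_params, 0.035), "solifenacin_5mg")
    a0 = accumulate(t0, _constant_stream_params(toy_params, 0.0))
    a35 = accumulate(t35, _constant_stream_params(toy_params, 0.035))
    assert a35.total_cost < a0.total_cost
    assert a35.total_qalys < a0.total_qalys


def test_categories_reconcile_to_total(default_params):
    from oabcea.estimation import prepare_transition_models
    models, _ = prepare_transition_models(
        default_params, ["solifenacin_5mg", "tolterodine_er_4mg"])
    trace = run_cohort(default_params, "solifenacin_5mg", models)
    arm = accumulate(trace, default_params)
    assert arm.total_cost == pytest.approx(sum(arm.cost_by_category.values()), abs=1e-9)
    assert arm.reconciles()
    assert 0.0 <= arm.total_qalys <= 5.0


# -- comparison and NMB ------------------------------------------------------

def _arm(name, cost, qalys):
    return ArmResult(arm=name, total_cost=cost, total_qalys=qalys)


def test_identical_arms_are_equivalent():
    cea = compare(_arm("a", 1000.0, 3.0), _arm("b", 1000.0, 3.0))
    assert cea.classification == CLASS_EQUIVALENT
    assert cea.icer is None
    assert net_monetary_benefit(cea) == 0.0


def test_cheaper_more_effective_is_dominant():
    cea = compare(_arm("a", 1733.0, 3.732), _arm("b", 1756.0, 3.725))
    assert cea.incremental_cost == pytest.approx(-23.0)
    assert cea.incremental_qalys == pytest.approx(0.007)
    assert cea.classification == CLASS_DOMINANT


def test_threshold_rule():
    cea = compare(_arm("a", 1100.0, 3.01), _arm("b", 1000.0, 3.0), wtp=30000)
    assert cea.icer == pytest.approx(10000.0)
    assert cea.classification == CLASS_CE
    cea2 = compare(_arm("a", 1400.0, 3.01), _arm("b", 1000.0, 3.0), wtp=30000)
    assert cea2.icer == pytest.approx(40000.0)
    assert cea2.classification == CLASS_NOT_CE


def test_costlier_less_effective_is_dominated():
    cea = compare(_arm("a", 1100.0, 2.9), _arm("b", 1000.0, 3.0))
    assert cea.classification == CLASS_DOMINATED


def test_nmb_worked_example():
    cea = compare(_arm("a", 1733.0, 3.7316), _arm("b", 1756.0, 3.7250), wtp=30000)
    assert net_monetary_benefit(cea) == pytest.approx(30000 * 0.0066 + 23, abs=1e-9)
    assert net_monetary_benefit(cea, wtp=0.0) == pytest.approx(23.0)


@given(st.floats(-500, 500), st.floats(0.0001, 0.05), st.floats(0, 50000))
def test_nmb_sign_matches_classification_for_positive_qaly_gain(dc, dq, wtp):
    cea = compare(_arm("a", 1000 + dc, 3 + dq), _arm("b", 1000.0, 3.0), wtp=wtp)
    nmb = net_monetary_benefit(cea)
    in_ce_set = cea.classification in (CLASS_DOMINANT, CLASS_CE)
    assert (nmb >= 0) == in_ce_set
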