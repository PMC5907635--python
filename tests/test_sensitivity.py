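"""Sensitivity analyses: one-way, probabilistic, CEAC, scenario."""
import numpy as np
import pytest

from oabcea import ceac, run_cohort, run_psa, run_scenario_discontinuation
from oabcea.engine import PHASE_FIRST
from oabcea.sensitivity import (PSASample, default_dsa_ranges,
                                evaluate_comparison, get_param, run_one_way,
                                set_param)

COMP = "tolterodine_er_4mg"


def test_parameter_paths_read_and_write(toy_params):
    assert get_param(toy_params, "pathway.p_discontinue_ae") == 0.90
    assert get_param(toy_params,
                     "drugs.solifenacin_5mg.ae_prob_3m.dry_mouth") == pytest.approx(0.143)
    assert get_param(toy_params, "utility.mict_coefs.1") == 0.05
    set_param(toy_params, "cost.pads_per_month.2", 90.0)
    assert toy_params.cost.pads_per_month[2] == 90.0
    with pytest.raises(KeyError):
        get_param(toy_params, "pathway.nonexistent")
    with pytest.raises(KeyError):
        get_param(toy_params, "elephants.count")


def test_empty_ranges_give_empty_tornado(toy_params):
    base, results = run_one_way(toy_params, {}, COMP)
    assert results == []
    assert base.classification


def test_degenerate_range_reproduces_base_case(toy_params):
    path = "pathway.p_discontinue_ae"
    base_value = get_param(toy_params, path)
    base, results = run_one_way(toy_params, {path: (base_value, base_value)}, COMP)
    r = results[0]
    assert r.cost_low == pytest.approx(base.incremental_cost, abs=1e-9)
    assert r.cost_high == pytest.approx(base.incremental_cost, abs=1e-9)
    assert r.qalys_low == pytest.approx(base.incremental_qalys, abs=1e-9)
    assert r.cost_range == 0.0


def test_non_bracketing_range_rejected(toy_params):
    with pytest.raises(ValueError, match="bracket"):
        run_one_way(toy_params, {"pathway.p_discontinue_ae": (0.95, 1.0)}, COMP)


def test_parameter_without_outcome_pathway_has_zero_range(toy_params):
    p = toy_params.copy()
    p.pathway.p_btxa_monthly = 0.0  # BTX-A never given -> its price is inert
    _, results = run_one_way(p, {"cost.btxa_injection_cost": (500.0, 2000.0)}, COMP)
    assert results[0].cost_range == pytest.approx(0.0, abs=1e-9)
    assert results[0].qalys_range == pytest.approx(0.0, abs=1e-9)


def test_psa_zero_variance_reproduces_base_case(toy_params):
    base = evaluate_comparison(toy_params, "solifenacin_5mg", COMP).cea
    ranges = {"pathway.p_discontinue_ae": (0.90, 0.90),
              "utility.mict_coefs.1": (0.05, 0.05)}
    samples = run_psa(toy_params, n_iter=1, seed=3, comparator=COMP, ranges=ranges)
    assert samples[0].delta_cost == pytest.approx(base.incremental_cost, abs=1e-9)
    assert samples[0].delta_qalys == pytest.approx(base.incremental_qalys, abs=1e-9)


def test_psa_is_seed_reproducible(toy_params):
    a = run_psa(toy_params, n_iter=10, seed=42, comparator=COMP)
    b = run_psa(toy_params, n_iter=10, seed=42, comparator=COMP)
    assert [(s.delta_cost, s.delta_qalys, s.values) for s in a] == \
           [(s.delta_cost, s.delta_qalys, s.values) for s in b]
    c = run_psa(toy_params, n_iter=10, seed=43, comparator=COMP)
    assert [s.delta_cost for s in a] != [s.delta_cost for s in c]


def test_psa_draws_respect_probability_support(toy_params):
    samples = run_psa(toy_params, n_iter=30, seed=5, comparator=COMP)
    for s in samples:
        for path, val in s.values.items():
            if "ae_prob_3m" in path or path.startswith("pathway.p_"):
                assert 0.0 <= val <= 1.0, (path, val)
            if "pads_per_month" in path:
                assert val >= 0.0


def test_ceac_enumeration_oracle():
    # 4 hand-built samples; NMB at w=30000: +70, -10, +230, -50
    samples = [PSASample(0, {}, delta_cost=-10.0, delta_qalys=0.002),
               PSASample(1, {}, delta_cost=40.0, delta_qalys=0.001),
               PSASample(2, {}, delta_cost=-200.0, delta_qalys=0.001),
               PSASample(3, {}, delta_cost=80.0, delta_qalys=0.001)]
    curve = ceac(samples, [0.0, 30000.0])
    assert curve[30000.0] == pytest.approx(2 / 4)
    assert curve[0.0] == pytest.approx(2 / 4)  # fraction with cost saving


def test_ceac_monotone_and_bounded_for_nonnegative_qaly_gains():
    rng = np.random.default_rng(0)
    samples = [PSASample(i, {}, delta_cost=float(rng.normal(0, 50)),
                         delta_qalys=float(abs(rng.normal(0.002, 0.001))))
               for i in range(200)]
    grid = [0.0, 5000.0, 15000.0, 30000.0, 50000.0]
    curve = ceac(samples, grid)
    vals = [curve[w] for w in grid]
    assert all(0.0 <= v <= 1.0 for v in vals)
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_ceac_requires_samples():
    with pytest.raises(ValueError):
        ceac([], [30000.0])


def test_all_dominant_samples_give_probability_one():
    samples = [PSASample(i, {}, delta_cost=-5.0 - i, delta_qalys=0.001)
               for i in range(10)]
    curve = ceac(samples, [0.0, 10000.0, 30000.0])
    assert all(v == 1.0 for v in curve.values())


def test_scenario_zero_rates_freeze_first_line(toy_params):
    rates = {name: 0.0 for name in toy_params.drug_names()}
    results = run_scenario_discontinuation(toy_params, rates, comparators=[COMP])
    assert set(results) == {COMP}
    # with zero discontinuation nobody ever leaves first-line treatment
    p = toy_params.copy()
    for d in p.drugs:
        d.discontinuation_monthly_no_ae = 0.0
        d.discontinuation_monthly_ae = 0.0
    from oabcea.estimation import prepare_transition_models
    models, _ = prepare_transition_models(p, ["solifenacin_5mg", COMP])
    trace = run_cohort(p, "solifenacin_5mg", models)
    assert trace.final.phase_mass()[PHASE_FIRST] == pytest.approx(1.0)
    assert sum(r.tally.switches for r in trace.cycles) == 0.0


def test_scenario_requires_rate_for_every_drug(toy_params):
    with pytest.raises(KeyError, match="oxybutynin_ir_10mg"):
        run_scenario_discontinuation(
            toy_params, {"solifenacin_5mg": 0.03, COMP: 0.05})


def test_scenario_equalized_rates_remove_ae_discontinuation_channel(toy_params):
    """Setting both rates to the base no-AE value isolates the AE channel."""
    base = evaluate_comparison(toy_params, "solifenacin_5mg", COMP).cea
    rates = {name: toy_params.pathway.p_discontinue_no_ae
             for name in toy_params.drug_names()}
    scen = run_scenario_discontinuation(toy_params, rates, comparators=[COMP])[COMP]
    # outcomes move because AE-driven discontinuation (0.90/cycle) is gone
    assert scen.incremental_cost != pytest.approx(base.incremental_cost, abs=1e-9)


def test_default_ranges_bracket_bases(default_params):
    ranges = default_dsa_ranges(default_params)
    assert len(ranges) > 30
    for path, (lo, hi) in ranges.items():
        base = get_param(default_params, path)
        assert lo <= base <= hi, path
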