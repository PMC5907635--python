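"""Estimation stages: conversions, regressions, calibration."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oabcea import adjust_probability_by_odds_ratio, \
    calibrate_comparator_transitions, fit_transition_regression, \
    fit_utility_regression, generate_trial_data, predicted_mean_change, \
    three_month_to_monthly_prob
from oabcea.estimation import (EstimationError, fit_transition_model,
                               resolve_ae_prob_3m, severity_to_daily_count,
                               shift_row, shift_transition_model)
from oabcea.parameters import DrugSpec
from oabcea.synthetic import DEFAULT_MIDPOINTS, default_truth
from oabcea.transitions import TransitionModel, identity_model


# -- probability conversions -------------------------------------------------

@pytest.mark.parametrize("p3m, expected", [
    (0.0, 0.0),
    (1.0, 1.0),
    (0.143, 0.0501),   # dry mouth on the reference drug
    (0.072, 0.0246),
])
def test_three_month_to_monthly(p3m, expected):
    assert three_month_to_monthly_prob(p3m) == pytest.approx(expected, abs=5e-5)


@given(st.floats(0.0, 1.0))
def test_monthly_prob_composes_back_to_three_month(p3m):
    pm = three_month_to_monthly_prob(p3m)
    assert 1 - (1 - pm) ** 3 == pytest.approx(p3m, abs=1e-12)


@pytest.mark.parametrize("bad", [-0.1, 1.1])
def test_three_month_out_of_range(bad):
    with pytest.raises(ValueError):
        three_month_to_monthly_prob(bad)


@pytest.mark.parametrize("p_ref, orv, expected", [
    (0.143, 1.0, 0.143),
    (0.143, 1.5, 0.2002),
    (0.5, 2.0, 2 / 3),
])
def test_odds_ratio_adjustment(p_ref, orv, expected):
    assert adjust_probability_by_odds_ratio(p_ref, orv) == pytest.approx(expected, abs=5e-5)


def test_vanishing_odds_ratio_gives_vanishing_probability():
    assert adjust_probability_by_odds_ratio(0.3, 1e-12) == pytest.approx(0.0, abs=1e-9)


def test_certain_reference_probability_rejected():
    with pytest.raises(ValueError):
        adjust_probability_by_odds_ratio(1.0, 2.0)
    with pytest.raises(ValueError):
        adjust_probability_by_odds_ratio(0.2, 0.0)


@given(st.floats(0.01, 0.95), st.floats(0.1, 8.0), st.floats(1.05, 1.5))
def test_adjustment_strictly_increasing_in_or_and_p(p, orv, factor):
    base = adjust_probability_by_odds_ratio(p, orv)
    assert adjust_probability_by_odds_ratio(p, orv * factor) > base
    if p * factor < 1.0:
        assert adjust_probability_by_odds_ratio(p * factor, orv) > base


def test_severity_midpoint_lookup():
    assert severity_to_daily_count(1, "micturition", DEFAULT_MIDPOINTS) == 6.0
    assert severity_to_daily_count(1, "incontinence", DEFAULT_MIDPOINTS) == 0.0
    custom = {"micturition": [5, 8, 10, 12, 20], "incontinence": [0, 1, 2, 4, 8]}
    assert severity_to_daily_count(5, "micturition", custom) == 20
    with pytest.raises(ValueError):
        severity_to_daily_count(6, "micturition", DEFAULT_MIDPOINTS)


def test_resolve_ae_prob_via_odds_ratio():
    ref = DrugSpec(name="ref", monthly_cost=1.0,
                   ae_prob_3m={"dry_mouth": 0.143, "constipation": 0.072},
                   is_reference=True)
    other = DrugSpec(name="x", monthly_cost=1.0,
                     ae_odds_ratio={"dry_mouth": 1.5, "constipation": 1.0})
    assert resolve_ae_prob_3m(other, ref, "dry_mouth") == pytest.approx(0.2002, abs=5e-5)
    assert resolve_ae_prob_3m(other, ref, "constipation") == pytest.approx(0.072)
    with pytest.raises(EstimationError):
        resolve_ae_prob_3m(DrugSpec(name="y", monthly_cost=0.0), ref, "dry_mouth")


# -- transition regression ---------------------------------------------------

def test_constant_levels_fit_identity_matrices():
    n = 30
    rows = []
    for pid in range(n):
        lvl = pid % 5 + 1
        for month in range(4):
            rows.append((pid, month, lvl, lvl))
    df = pd.DataFrame(rows, columns=["patient_id", "month", "mict_level", "incont_level"])
    mats, flagged = fit_transition_regression(df, "micturition")
    for m in (1, 2, 3):
        assert np.allclose(mats[m], np.eye(5))
    assert flagged == []


def test_saturated_fit_equals_observed_frequencies():
    # hand-built cohort: 4 patients from level 2, destinations 1,1,2,3 at month 1
    rows = []
    dest = {0: 1, 1: 1, 2: 2, 3: 3}
    for pid in range(4):
        for month in range(4):
            lvl = 2 if month == 0 else dest[pid]
            rows.append((pid, month, lvl, 1))
    df = pd.DataFrame(rows, columns=["patient_id", "month", "mict_level", "incont_level"])
    mats, flagged = fit_transition_regression(df, "micturition")
    assert np.allclose(mats[1][1], [0.5, 0.25, 0.25])     # origin level 2
    assert (1, 1) in flagged  # no month-1 observations start at level 1
    assert np.allclose(mats[1][0], np.eye(3)[0])


def test_multinomial_logit_matches_frequency_mle():
    # two-level truth keeps every origin-destination cell populated, so the
    # saturated logit MLE sits in the interior and must equal the frequencies
    from oabcea.synthetic import SyntheticTruth
    m = {1: np.array([[0.8, 0.2], [0.4, 0.6]]),
         2: np.array([[0.75, 0.25], [0.35, 0.65]]),
         3: np.array([[0.7, 0.3], [0.3, 0.7]])}
    t = SyntheticTruth(transition_matrices={"micturition": m, "incontinence": m},
                       utility=default_truth(1).utility, nma_effects={})
    df = generate_trial_data(t, 400, seed=9)
    sat, _ = fit_transition_regression(df, "incontinence", method="saturated")
    mnl, _ = fit_transition_regression(df, "incontinence", method="mnlogit")
    for month in (1, 2, 3):
        assert np.allclose(sat[month], mnl[month], atol=1e-6)


def test_fitted_matrices_are_row_stochastic(truth):
    df = generate_trial_data(truth, 500, seed=11)
    tm = fit_transition_model(df, "solifenacin_5mg")
    assert tm.validate() == []


def test_empty_records_rejected():
    df = pd.DataFrame(columns=["patient_id", "month", "mict_level", "incont_level"])
    with pytest.raises(ValueError):
        fit_transition_regression(df, "micturition")


# -- utility regression ------------------------------------------------------

def test_noiseless_utility_regression_is_exact(truth):
    t = default_truth(1)
    t.utility["noise_sd"] = 0.0
    df = generate_trial_data(t, 300, seed=2)
    fit = fit_utility_regression(df)
    for lvl, coef in t.utility["mict_coefs"].items():
        assert fit.mict_coefs[lvl] == pytest.approx(coef, abs=1e-8)
    for lvl, coef in t.utility["incont_coefs"].items():
        assert fit.incont_coefs[lvl] == pytest.approx(coef, abs=1e-8)


def test_rank_deficient_design_is_an_error():
    df = pd.DataFrame({
        "patient_id": range(20), "month": 0,
        "mict_level": 5, "incont_level": 5,
        "sex": 0, "age": 60.0, "country": "UK",
        "eq5d_index": 0.7,
    })
    with pytest.raises(EstimationError, match="mict_level"):
        fit_utility_regression(df)


# -- predicted change and calibration ---------------------------------------

def test_identity_model_predicts_zero_change():
    tm = identity_model("x", 5)
    base = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
    assert predicted_mean_change(tm, base, "micturition", DEFAULT_MIDPOINTS) == 0.0


def test_full_shift_to_level_one_changes_by_midpoint_difference():
    mats = {m: np.tile(np.eye(5)[0], (5, 1)) for m in (1, 2, 3)}
    tm = TransitionModel("x", {"micturition": mats,
                               "incontinence": {m: np.eye(5) for m in (1, 2, 3)}})
    base = np.eye(5)[1]  # everyone at level 2 (9 voids/day)
    change = predicted_mean_change(tm, base, "micturition", DEFAULT_MIDPOINTS)
    assert change == pytest.approx(6.0 - 9.0)


def test_predicted_change_is_linear_in_baseline(truth):
    tm = TransitionModel("ref", truth.transition_matrices)
    b1, b2 = np.eye(5)[1], np.eye(5)[3]
    mix = 0.3 * b1 + 0.7 * b2
    c1 = predicted_mean_change(tm, b1, "micturition", DEFAULT_MIDPOINTS)
    c2 = predicted_mean_change(tm, b2, "micturition", DEFAULT_MIDPOINTS)
    cm = predicted_mean_change(tm, mix, "micturition", DEFAULT_MIDPOINTS)
    assert cm == pytest.approx(0.3 * c1 + 0.7 * c2, abs=1e-12)


@given(st.integers(0, 2 ** 31 - 1), st.floats(-3, 3))
def test_shifted_rows_remain_probability_vectors(seed, delta):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(5))
    q = shift_row(p, delta)
    assert q.min() >= 0
    assert q.sum() == pytest.approx(1.0, abs=1e-12)
    # positive delta moves mass toward lower levels (stochastic dominance)
    if delta > 0:
        assert np.all(np.cumsum(q)[:-1] >= np.cumsum(p)[:-1] - 1e-12)


def test_zero_shift_is_identity(truth):
    tm = TransitionModel("ref", truth.transition_matrices)
    shifted = shift_transition_model(tm, 0.0, "micturition")
    for m in (1, 2, 3):
        assert np.allclose(shifted.matrices["micturition"][m],
                           tm.matrices["micturition"][m], atol=1e-12)


def _ref_tm(truth):
    return TransitionModel("solifenacin_5mg", truth.transition_matrices)


def test_zero_target_calibrates_to_zero_shift(truth):
    base = truth.baseline_marginal("micturition")
    res, _ = calibrate_comparator_transitions(
        _ref_tm(truth), 0.0, base, "micturition", DEFAULT_MIDPOINTS)
    assert abs(res.delta) < 1e-6
    assert res.objective_value < 1e-10


def test_calibration_recovers_known_shift(truth):
    """Round trip: perturb by a known delta*, calibrate back, recover it."""
    ref = _ref_tm(truth)
    base = truth.baseline_marginal("micturition")
    for delta_star in (-0.8, 0.35, 1.2):
        perturbed = shift_transition_model(ref, delta_star, "micturition")
        diff = (predicted_mean_change(perturbed, base, "micturition", DEFAULT_MIDPOINTS)
                - predicted_mean_change(ref, base, "micturition", DEFAULT_MIDPOINTS))
        res, _ = calibrate_comparator_transitions(
            ref, diff, base, "micturition", DEFAULT_MIDPOINTS)
        assert res.delta == pytest.approx(delta_star, abs=1e-3)


def test_achieved_change_monotone_in_target(truth):
    ref = _ref_tm(truth)
    base = truth.baseline_marginal("micturition")
    achieved = []
    for target in np.linspace(-1.0, 1.0, 9):
        res, _ = calibrate_comparator_transitions(
            ref, target, base, "micturition", DEFAULT_MIDPOINTS)
        achieved.append(res.achieved_change)
    assert all(b >= a - 1e-9 for a, b in zip(achieved, achieved[1:]))


def test_unreachable_target_warns_and_returns_bound(truth):
    ref = _ref_tm(truth)
    base = truth.baseline_marginal("micturition")
    from oabcea.estimation import CalibrationWarning
    with pytest.warns(CalibrationWarning):
        res, tm = calibrate_comparator_transitions(
            ref, 50.0, base, "micturition", DEFAULT_MIDPOINTS)
    assert res.objective_value > 0
    assert tm.validate() == []


def test_calibrated_matrices_are_row_stochastic(truth):
    ref = _ref_tm(truth)
    base = truth.baseline_marginal("incontinence")
    _, tm = calibrate_comparator_transitions(
        ref, 0.05, base, "incontinence", DEFAULT_MIDPOINTS)
    assert tm.validate() == []
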