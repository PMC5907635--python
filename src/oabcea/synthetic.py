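"""Synthetic trial-like data and default model parameterization.

The published base-case inputs (adverse-event probabilities, pathway
probabilities, utility coefficients, resource use, unit costs) are carried
verbatim in :func:`make_default_paramset`.  The patient-level trial data,
the baseline severity distribution, the reference drug's monthly transition
matrices and the network-meta-analysis effect estimates are not deposited
anywhere, so this module provides documented synthetic stand-ins with the
statistical structure the downstream stages assume:

* baseline severity strata: independent truncated-geometric marginals over
  levels 1..5 in each dimension (monotonically decreasing occupancy with
  worsening severity);
* monthly symptom transitions for the reference drug: discretized-normal
  rows centred on the origin level minus a month-specific improvement
  drift (strongest in month 1, tapering by month 3);
* EQ-5D index observations: linear in severity-level indicators plus sex,
  age and country effects, Gaussian noise truncated to the UK tariff range
  [-0.594, 1];
* NMA outputs: mean differences in daily micturitions/incontinence
  episodes versus the reference drug, and adverse-event odds ratios
  derived from the 3-month probability table, each with configurable
  interval half-widths.

Every generator is deterministic given (truth, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import three_month_to_monthly_prob
from .parameters import (AE_TYPES, CostSpec, DrugSpec, ParamSet, PathwaySpec,
                         Settings, UtilitySpec)
from .transitions import DIMENSIONS, MONTHS, TransitionModel

EQ5D_RANGE = (-0.594, 1.0)

#: severity-level midpoints, episodes/day (level <-> daily-count bridge;
#: the model needs one and none is published)
DEFAULT_MIDPOINTS = {
    "micturition": [6.0, 9.0, 11.0, 13.0, 16.0],
    "incontinence": [0.0, 0.5, 1.5, 3.0, 6.0],
}

COUNTRIES = ("UK", "FR", "DE")


@dataclass
class SyntheticTruth:
    """Generating parameters retained alongside output for recovery tests."""

    transition_matrices: dict[str, dict[int, np.ndarray]]
    utility: dict
    nma_effects: dict[str, dict]
    baseline_ratios: tuple[float, float] = (0.7, 0.7)
    seed: int = 1

    def baseline_marginal(self, dimension: str, n_levels: int = 5) -> np.ndarray:
        ratio = self.baseline_ratios[0 if dimension == "micturition" else 1]
        w = ratio ** np.arange(n_levels)
        return w / w.sum()

    def baseline_joint(self, n_levels: int = 5) -> np.ndarray:
        m = self.baseline_marginal("micturition", n_levels)
        i = self.baseline_marginal("incontinence", n_levels)
        return np.outer(m, i)

    def validate(self) -> None:
        for dim, months in self.transition_matrices.items():
            for m, mat in months.items():
                mat = np.asarray(mat, float)
                if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1) > 1e-9):
                    raise ValueError(f"truth matrix {dim}/month{m} is not row-stochastic")


def _drift_matrix(n_levels: int, drift: float, sd: float = 0.85) -> np.ndarray:
    """Row-stochastic matrix: destination ~ discretized N(origin - drift, sd^2)."""
    j = np.arange(1, n_levels + 1)
    rows = []
    for i in j:
        w = np.exp(-0.5 * ((j - (i - drift)) / sd) ** 2)
        rows.append(w / w.sum())
    return np.vstack(rows)


def default_truth(seed: int = 1) -> SyntheticTruth:
    """Synthetic generating truth for the 5-level model."""
    matrices = {
        "micturition": {m: _drift_matrix(5, d) for m, d in ((1, 0.9), (2, 0.45), (3, 0.2))},
        "incontinence": {m: _drift_matrix(5, d) for m, d in ((1, 0.8), (2, 0.40), (3, 0.15))},
    }
    utility = {
        "base": 0.70,
        "mict_coefs": {1: 0.0632, 2: 0.0422, 3: 0.0204, 4: 0.0210},
        "incont_coefs": {1: 0.0586, 2: 0.0437, 3: 0.0314, 4: 0.02485},
        "sex_effect": -0.015,
        "age_effect": -0.0008,   # per year, centred at 58
        "age_center": 58.0,
        "country_effects": {"UK": 0.0, "FR": 0.01, "DE": -0.005},
        "noise_sd": 0.1,
    }
    # mean differences in daily-count change vs the reference drug
    # (positive = less improvement); interval half-widths are stand-ins for
    # the NMA's credible intervals
    nma = {
        "tolterodine_er_4mg": {"micturitions_per_day": 0.10, "incontinence_per_day": 0.030},
        "fesoterodine_4mg": {"micturitions_per_day": 0.07, "incontinence_per_day": 0.020},
        "fesoterodine_8mg": {"micturitions_per_day": -0.05, "incontinence_per_day": -0.020},
        "oxybutynin_er_10mg": {"micturitions_per_day": 0.12, "incontinence_per_day": 0.040},
        "oxybutynin_ir_10mg": {"micturitions_per_day": 0.15, "incontinence_per_day": 0.050},
        "solifenacin_10mg": {"micturitions_per_day": -0.08, "incontinence_per_day": -0.030},
        "tolterodine_ir_4mg": {"micturitions_per_day": 0.18, "incontinence_per_day": 0.060},
        "trospium_60mg": {"micturitions_per_day": 0.08, "incontinence_per_day": 0.040},
    }
    halfwidth = {"micturitions_per_day": 0.30, "incontinence_per_day": 0.12}
    nma_effects = {
        name: {"mean_diff": eff, "ci_halfwidth": dict(halfwidth)}
        for name, eff in nma.items()
    }
    return SyntheticTruth(transition_matrices=matrices, utility=utility,
                          nma_effects=nma_effects, seed=seed)


# ---------------------------------------------------------------------------
# patient-level trial data
# ---------------------------------------------------------------------------

def generate_trial_data(truth: SyntheticTruth, n_patients: int,
                        seed: int) -> pd.DataFrame:
    """Simulate one trial arm: baseline + 3 monthly visits per patient.

    Baseline severity levels are drawn from the stand-in baseline
    distribution; months 1-3 evolve by the truth transition matrices
    (independently per dimension); the EQ-5D index is the truth linear
    predictor plus truncated Gaussian noise.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    truth.validate()
    rng = np.random.default_rng(seed)
    L = next(iter(truth.transition_matrices["micturition"].values())).shape[0]

    sex = rng.binomial(1, 0.75, n_patients)          # predominantly female
    age = np.clip(rng.normal(58, 12, n_patients), 18, 90)
    country = rng.choice(COUNTRIES, n_patients, p=(0.5, 0.25, 0.25))

    levels = {}
    for dim in DIMENSIONS:
        marg = truth.baseline_marginal(dim, L)
        cur = rng.choice(np.arange(1, L + 1), size=n_patients, p=marg)
        traj = [cur]
        for m in MONTHS:
            mat = np.asarray(truth.transition_matrices[dim][m], float)
            cum = np.cumsum(mat, axis=1)
            u = rng.random(n_patients)
            cur = 1 + (u[:, None] > cum[cur - 1]).sum(axis=1)
            traj.append(cur)
        levels[dim] = np.vstack(traj)   # (4, n_patients)

    ut = truth.utility
    mict_c = np.array([ut["mict_coefs"].get(k, 0.0) for k in range(1, L + 1)])
    incont_c = np.array([ut["incont_coefs"].get(k, 0.0) for k in range(1, L + 1)])
    country_eff = np.array([ut["country_effects"][c] for c in country])

    rows = []
    for month in range(4):
        ml = levels["micturition"][month]
        il = levels["incontinence"][month]
        linpred = (ut["base"] + mict_c[ml - 1] + incont_c[il - 1]
                   + ut["sex_effect"] * sex
                   + ut["age_effect"] * (age - ut["age_center"])
                   + country_eff)
        eq5d = linpred + rng.normal(0.0, ut["noise_sd"], n_patients)
        eq5d = np.clip(eq5d, *EQ5D_RANGE)
        rows.append(pd.DataFrame({
            "patient_id": np.arange(n_patients),
            "sex": sex, "age": age, "country": country,
            "month": month, "mict_level": ml, "incont_level": il,
            "eq5d_index": eq5d,
        }))
    return (pd.concat(rows, ignore_index=True)
            .sort_values(["patient_id", "month"], kind="stable")
            .reset_index(drop=True))


def generate_nma_inputs(truth: SyntheticTruth, seed: int,
                        ae_prob_3m: dict[str, dict[str, float]] | None = None,
                        or_log_halfwidth: float = 0.3) -> pd.DataFrame:
    """Emit NMA-like outputs: mean differences and AE odds ratios with CIs.

    Point estimates equal the truth effects exactly (the reference drug gets
    mean difference 0 and odds ratio 1); only the interval half-widths are
    synthetic.  ``ae_prob_3m`` (drug -> AE -> 3-month probability) is used
    to derive odds ratios; when omitted, odds ratios are reported as 1.
    """
    del seed  # points are deterministic; kept for interface symmetry
    if ae_prob_3m is None:
        ae_prob_3m = {}
    ref_name = "solifenacin_5mg"
    ref_p = ae_prob_3m.get(ref_name, {})

    def odds(p: float) -> float:
        return p / (1.0 - p)

    rows = []
    for name in [ref_name, *truth.nma_effects]:
        rec: dict[str, float | str] = {"drug": name}
        eff = (truth.nma_effects.get(name) or
               {"mean_diff": {k: 0.0 for k in ("micturitions_per_day", "incontinence_per_day")},
                "ci_halfwidth": {"micturitions_per_day": 0.0, "incontinence_per_day": 0.0}})
        for outcome in ("micturitions_per_day", "incontinence_per_day"):
            md = eff["mean_diff"][outcome]
            hw = eff["ci_halfwidth"][outcome]
            rec[f"mean_diff_{outcome}"] = md
            rec[f"mean_diff_{outcome}_lo"] = md - hw
            rec[f"mean_diff_{outcome}_hi"] = md + hw
        for ae in AE_TYPES:
            if name == ref_name or not ref_p or name not in ae_prob_3m:
                orv = 1.0
            else:
                orv = odds(ae_prob_3m[name][ae]) / odds(ref_p[ae])
            rec[f"or_{ae}"] = orv
            rec[f"or_{ae}_lo"] = orv * np.exp(-or_log_halfwidth)
            rec[f"or_{ae}_hi"] = orv * np.exp(or_log_halfwidth)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default parameter sets
# ---------------------------------------------------------------------------

# (name, monthly cost GBP, dry-mouth % at 3m, range, constipation % at 3m, range)
_DRUG_TABLE = [
    ("solifenacin_5mg", 28.00, 14.3, (10.2, 18.4), 7.2, (4.2, 10.2)),
    ("tolterodine_er_4mg", 28.01, 14.9, (12.8, 17.8), 4.3, (3.0, 6.2)),
    ("fesoterodine_4mg", 28.01, 15.1, (12.2, 19.3), 3.7, (2.4, 5.8)),
    ("fesoterodine_8mg", 28.01, 28.9, (24.8, 33.7), 6.9, (4.8, 10.0)),
    ("oxybutynin_er_10mg", 27.92, 21.0, (16.3, 27.2), 3.7, (1.7, 7.5)),
    ("oxybutynin_ir_10mg", 2.40, 37.1, (26.4, 51.0), 3.7, (2.1, 6.4)),
    ("solifenacin_10mg", 36.41, 27.5, (24.3, 30.9), 12.2, (9.9, 15.0)),
    ("tolterodine_ir_4mg", 2.88, 22.3, (18.1, 25.7), 3.7, (1.7, 7.5)),
    ("trospium_60mg", 25.04, 12.7, (7.7, 18.5), 15.1, (8.1, 27.7)),
]

_PAD_TABLE = {
    1: (6.97, (5.83, 8.10)),
    2: (23.48, (20.80, 26.16)),
    3: (44.47, (39.76, 49.18)),
    4: (58.13, (52.10, 64.15)),
    5: (121.30, (111.88, 130.72)),
}

# level-4 base coefficients are not published; the midpoint of the published
# sensitivity range stands in (flagged in the docs, user-overridable)
_UTILITY_TABLE = {
    "mict": {1: (0.0632, (0.0453, 0.0811)), 2: (0.0422, (0.0258, 0.0587)),
             3: (0.0204, (0.0045, 0.0363)), 4: (0.0210, (0.0104, 0.0316))},
    "incont": {1: (0.0586, (0.0422, 0.0749)), 2: (0.0437, (0.0271, 0.0602)),
               3: (0.0314, (0.0142, 0.0486)), 4: (0.02485, (0.0128, 0.0369))},
}


def make_default_paramset(seed: int = 1) -> tuple[ParamSet, SyntheticTruth]:
    """The full 9-drug, 5-level parameterization.

    Published base-case values are verbatim; the baseline severity
    distribution, severity midpoints, reference transition matrices, NMA
    mean differences and the base utility are synthetic stand-ins drawn
    from :func:`default_truth`.  Deterministic per seed.
    """
    truth = default_truth(seed)

    drugs = []
    for name, cost, dm, dm_rng, cons, cons_rng in _DRUG_TABLE:
        eff = truth.nma_effects.get(name)
        dsa = {
            "ae_prob_3m.dry_mouth": (dm_rng[0] / 100, dm_rng[1] / 100),
            "ae_prob_3m.constipation": (cons_rng[0] / 100, cons_rng[1] / 100),
            "discontinuation_monthly_no_ae": (0.034, 0.102),
        }
        nma = None
        if eff is not None:
            nma = dict(eff["mean_diff"])
            for k, hw in eff["ci_halfwidth"].items():
                dsa[f"nma_mean_diff.{k}"] = (nma[k] - hw, nma[k] + hw)
        drugs.append(DrugSpec(
            name=name, monthly_cost=cost,
            ae_prob_3m={"dry_mouth": dm / 100, "constipation": cons / 100},
            nma_mean_diff=nma,
            is_reference=(name == "solifenacin_5mg"),
            dsa_ranges=dsa,
        ))

    pathway = PathwaySpec(dsa_ranges={
        "p_discontinue_ae": (0.50, 1.00),
        "p_discontinue_no_ae": (0.034, 0.102),
        "p_switch_after_discontinuation": (0.067, 0.391),
        "p_restart_monthly": (0.0, 0.0842),
        "p_btxa_monthly": (0.0, 0.005),
        "p_btxa_reinjection_6m": (0.50, 1.00),
    })

    ut = truth.utility
    udsa = {"ae_decrement": (-0.1, 0.0), "base_utility": (0.65, 0.75)}
    for key, prefix in (("mict", "mict_coefs"), ("incont", "incont_coefs")):
        for lvl, (_, rng_) in _UTILITY_TABLE[key].items():
            udsa[f"{prefix}.{lvl}"] = rng_
    utility = UtilitySpec(
        base_utility=ut["base"],
        mict_coefs={k: v for k, (v, _) in _UTILITY_TABLE["mict"].items()},
        incont_coefs={k: v for k, (v, _) in _UTILITY_TABLE["incont"].items()},
        ae_decrement=-0.0357,
        dsa_ranges=udsa,
    )

    cost = CostSpec(
        pads_per_month={k: v for k, (v, _) in _PAD_TABLE.items()},
        dsa_ranges={f"pads_per_month.{k}": rng_ for k, (_, rng_) in _PAD_TABLE.items()},
    )

    settings = Settings(
        baseline_distribution=truth.baseline_joint(5),
        severity_midpoints={k: list(v) for k, v in DEFAULT_MIDPOINTS.items()},
        seed=seed,
    )

    ref_tm = TransitionModel(
        drug="solifenacin_5mg",
        matrices={dim: {m: np.asarray(mat, float).copy()
                        for m, mat in months.items()}
                  for dim, months in truth.transition_matrices.items()})

    params = ParamSet(drugs=drugs, pathway=pathway, utility=utility,
                      cost=cost, settings=settings,
                      transition_models={"solifenacin_5mg": ref_tm})
    return params, truth


def make_toy_paramset(seed: int = 1, horizon: int = 12) -> ParamSet:
    """A reduced 2-level, 3-drug parameterization for fast verification.

    Two severity levels per dimension keep the state space small enough for
    walker-level cross-checks while exercising every pathway rule (AEs,
    discontinuation, switching, restart, BTX-A) with the default pathway
    probabilities.
    """
    m1 = np.array([[0.90, 0.10], [0.45, 0.55]])
    m2 = np.array([[0.88, 0.12], [0.30, 0.70]])
    m3 = np.array([[0.87, 0.13], [0.25, 0.75]])
    ref_tm = TransitionModel(
        drug="solifenacin_5mg",
        matrices={dim: {1: m1.copy(), 2: m2.copy(), 3: m3.copy()}
                  for dim in DIMENSIONS})

    table = [r for r in _DRUG_TABLE
             if r[0] in ("solifenacin_5mg", "tolterodine_er_4mg", "oxybutynin_ir_10mg")]
    drugs = []
    for name, cost, dm, dm_rng, cons, cons_rng in table:
        nma = None
        if name != "solifenacin_5mg":
            nma = {"micturitions_per_day": 0.10 if "tolterodine" in name else 0.15,
                   "incontinence_per_day": 0.05 if "tolterodine" in name else 0.08}
        drugs.append(DrugSpec(
            name=name, monthly_cost=cost,
            ae_prob_3m={"dry_mouth": dm / 100, "constipation": cons / 100},
            nma_mean_diff=nma,
            is_reference=(name == "solifenacin_5mg"),
            dsa_ranges={
                "ae_prob_3m.dry_mouth": (dm_rng[0] / 100, dm_rng[1] / 100),
                "ae_prob_3m.constipation": (cons_rng[0] / 100, cons_rng[1] / 100),
            },
        ))

    baseline = np.outer([0.35, 0.65], [0.45, 0.55])
    settings = Settings(
        horizon=horizon,
        baseline_distribution=baseline,
        severity_midpoints={"micturition": [7.0, 13.0], "incontinence": [0.5, 4.0]},
        seed=seed,
    )
    return ParamSet(
        drugs=drugs,
        pathway=PathwaySpec(dsa_ranges={
            "p_discontinue_ae": (0.50, 1.00),
            "p_discontinue_no_ae": (0.034, 0.102),
            "p_switch_after_discontinuation": (0.067, 0.391),
        }),
        utility=UtilitySpec(base_utility=0.80,
                            mict_coefs={1: 0.05}, incont_coefs={1: 0.045},
                            dsa_ranges={"mict_coefs.1": (0.03, 0.07),
                                        "incont_coefs.1": (0.025, 0.065)}),
        cost=CostSpec(pads_per_month={1: 10.0, 2: 80.0},
                      dsa_ranges={"pads_per_month.2": (60.0, 100.0)}),
        settings=settings,
        transition_models={"solifenacin_5mg": ref_tm},
    )
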