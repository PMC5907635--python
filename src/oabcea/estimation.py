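"""Statistical estimation stages.

Four things happen here:

1. **Transition regression** — monthly symptom-level transition matrices
   P(level_m = j | level_{m-1} = i) for months 1-3, estimated from
   patient-level trial records.  The default specification is saturated in
   the origin level, whose maximum-likelihood estimate is the observed
   destination frequencies per origin row; a multinomial-logit fit is
   available as an option and coincides with the frequencies when saturated.
2. **Utility regression** — ordinary least squares of the EQ-5D index on
   severity-level indicators (worst level as reference) plus sex, age and
   country, giving the utility coefficients the economic model consumes.
3. **Probability conversions** — 3-month AE probabilities to constant-hazard
   monthly probabilities, and odds-ratio adjustment of a reference
   probability.
4. **Calibration** — comparator transition matrices are not observed;
   they are derived from the reference drug's matrices by shifting each
   row on a latent ordered-destination scale (a cumulative-logit shift
   delta, one scalar per drug and symptom dimension) until the model's
   predicted month-3 change in daily symptom count matches the reference
   change plus the network-meta-analysis mean difference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .parameters import DIMENSION_TO_NMA, DrugSpec, ParamSet
from .transitions import MONTHS, TransitionModel


class EstimationError(RuntimeError):
    pass


class CalibrationWarning(UserWarning):
    pass


_LEVEL_COL = {"micturition": "mict_level", "incontinence": "incont_level"}


# ---------------------------------------------------------------------------
# probability conversions
# ---------------------------------------------------------------------------

def three_month_to_monthly_prob(p3m: float) -> float:
    """Constant-hazard monthly probability equivalent to a 3-month one.

    Returns ``1 - (1 - p3m)**(1/3)``: three independent monthly risks of the
    returned size compound to exactly ``p3m``.
    """
    if not 0.0 <= p3m <= 1.0:
        raise ValueError(f"3-month probability out of [0,1]: {p3m}")
    return 1.0 - (1.0 - p3m) ** (1.0 / 3.0)


def adjust_probability_by_odds_ratio(p_ref: float, or_value: float) -> float:
    """Apply an odds ratio to a reference probability on the odds scale."""
    if not 0.0 <= p_ref < 1.0:
        raise ValueError(f"reference probability must be in [0,1): {p_ref}")
    if not or_value > 0:
        raise ValueError(f"odds ratio must be > 0: {or_value}")
    odds = or_value * p_ref / (1.0 - p_ref)
    return odds / (1.0 + odds)


def severity_to_daily_count(level: int, dimension: str,
                            midpoints: dict[str, list[float]]) -> float:
    """Episodes/day midpoint for a severity level (1-based)."""
    mids = midpoints[dimension]
    if not (isinstance(level, (int, np.integer)) and 1 <= level <= len(mids)):
        raise ValueError(f"level must be an integer in 1..{len(mids)}, got {level}")
    return float(mids[level - 1])


# ---------------------------------------------------------------------------
# transition regression
# ---------------------------------------------------------------------------

def fit_transition_regression(records: pd.DataFrame, dimension: str,
                              method: str = "saturated",
                              ) -> tuple[dict[int, np.ndarray], list[tuple[int, int]]]:
    """Estimate month-indexed transition matrices from patient records.

    Parameters
    ----------
    records : DataFrame
        One row per (patient, month) with columns ``patient_id``, ``month``
        (0-3) and the level column for ``dimension``.
    dimension : str
        ``"micturition"`` or ``"incontinence"``.
    method : str
        ``"saturated"`` (default; closed-form frequency MLE) or
        ``"mnlogit"`` (multinomial logit with one indicator per origin
        level, numerically identical at the optimum).

    Returns
    -------
    matrices : dict month -> (L, L) row-stochastic array
    flagged : list of (month, origin_level) rows with no observations,
        which received an identity row.
    """
    if len(records) == 0:
        raise ValueError("no records supplied")
    col = _LEVEL_COL[dimension]
    levels = records[col].to_numpy()
    if not np.all((levels == np.round(levels)) & (levels >= 1)):
        raise ValueError(f"{col} must contain integer levels >= 1")
    L = int(records[col].max())
    wide = records.pivot(index="patient_id", columns="month", values=col)

    matrices: dict[int, np.ndarray] = {}
    flagged: list[tuple[int, int]] = []
    for m in MONTHS:
        if m - 1 not in wide.columns or m not in wide.columns:
            raise ValueError(f"records missing month {m - 1} or {m}")
        pair = wide[[m - 1, m]].dropna().astype(int).to_numpy()
        counts = np.zeros((L, L))
        np.add.at(counts, (pair[:, 0] - 1, pair[:, 1] - 1), 1.0)
        mat = np.empty((L, L))
        for i in range(L):
            total = counts[i].sum()
            if total == 0:
                mat[i] = np.eye(L)[i]
                flagged.append((m, i + 1))
            else:
                mat[i] = counts[i] / total
        if method == "mnlogit":
            mat = _mnlogit_matrix(pair, L, fallback=mat)
        elif method != "saturated":
            raise ValueError(f"unknown method '{method}'")
        matrices[m] = mat
    return matrices, flagged


def _mnlogit_matrix(pair: np.ndarray, L: int, fallback: np.ndarray) -> np.ndarray:
    """Saturated multinomial-logit fit of destination on origin indicators."""
    import statsmodels.api as sm

    origins = np.unique(pair[:, 0])
    dests = np.unique(pair[:, 1])
    if len(dests) < 2:
        return fallback  # degenerate outcome; frequency MLE already exact
    exog = (pair[:, 0:1] == origins[None, :]).astype(float)
    # destinations recoded to 0..K-1 over observed categories
    dest_codes = np.searchsorted(dests, pair[:, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MNLogit(dest_codes, exog).fit(disp=0, method="newton", maxiter=200)
        except Exception as exc:  # pragma: no cover - convergence pathology
            raise EstimationError(f"multinomial logit failed: {exc}") from None
    probs = fit.predict(np.eye(len(origins)))
    mat = fallback.copy()
    for r, origin in enumerate(origins):
        row = np.zeros(L)
        row[dests - 1] = probs[r]
        mat[origin - 1] = row / row.sum()
    return mat


def fit_transition_model(records: pd.DataFrame, drug: str,
                         method: str = "saturated") -> TransitionModel:
    """Convenience wrapper fitting both symptom dimensions into a model."""
    matrices = {}
    for dim in _LEVEL_COL:
        matrices[dim], _ = fit_transition_regression(records, dim, method=method)
    return TransitionModel(drug=drug, matrices=matrices)


# ---------------------------------------------------------------------------
# utility regression
# ---------------------------------------------------------------------------

@dataclass
class UtilityFit:
    """OLS estimates of the utility model."""

    base_utility: float          # predicted utility at worst levels, covariates at sample means
    mict_coefs: dict[int, float]
    incont_coefs: dict[int, float]
    se: dict[str, float]         # standard errors keyed like "mict_1", "incont_3"
    results: object              # the underlying statsmodels results


def fit_utility_regression(records: pd.DataFrame) -> UtilityFit:
    """OLS of the EQ-5D index on severity indicators, sex, age and country.

    The worst observed level in each dimension is the reference category, so
    level coefficients are utility increments over the worst state.  Raises
    :class:`EstimationError` naming the offending terms when the design
    matrix is rank deficient (e.g. a level or covariate with no variation).
    """
    import statsmodels.formula.api as smf

    df = records.copy()
    L_m = int(df["mict_level"].max())
    L_i = int(df["incont_level"].max())

    deficient = []
    for col, L in (("mict_level", L_m), ("incont_level", L_i)):
        if df[col].nunique() < 2:
            deficient.append(col)
    if deficient:
        raise EstimationError(
            "design matrix rank deficient; no variation in: " + ", ".join(deficient))

    formula = (f"eq5d_index ~ C(mict_level, Treatment(reference={L_m}))"
               f" + C(incont_level, Treatment(reference={L_i}))")
    for cov in ("sex", "age"):
        if cov in df.columns and df[cov].nunique() > 1:
            formula += f" + {cov}"
    if "country" in df.columns and df["country"].nunique() > 1:
        formula += " + C(country)"

    model = smf.ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise EstimationError(
            "design matrix rank deficient; collinear terms among: "
            + ", ".join(model.exog_names))
    fit = model.fit()

    mict, incont, se = {}, {}, {}
    for name, coef, s in zip(fit.params.index, fit.params.values, fit.bse.values):
        if name.startswith("C(mict_level"):
            lvl = int(name.split("[T.")[1].rstrip("]"))
            mict[lvl] = float(coef)
            se[f"mict_{lvl}"] = float(s)
        elif name.startswith("C(incont_level"):
            lvl = int(name.split("[T.")[1].rstrip("]"))
            incont[lvl] = float(coef)
            se[f"incont_{lvl}"] = float(s)

    # base utility: predicted value at the worst state with covariates at means
    ref = df.iloc[[0]].copy()
    ref["mict_level"], ref["incont_level"] = L_m, L_i
    if "age" in df.columns:
        ref["age"] = df["age"].mean()
    if "sex" in df.columns:
        ref["sex"] = df["sex"].mean()
    base = float(fit.predict(ref).iloc[0])
    if "country" in df.columns and df["country"].nunique() > 1:
        # average the country intercepts over their sample shares
        preds = []
        for c, w in df["country"].value_counts(normalize=True).items():
            ref["country"] = c
            preds.append(w * float(fit.predict(ref).iloc[0]))
        base = float(sum(preds))
    return UtilityFit(base_utility=base, mict_coefs=mict, incont_coefs=incont,
                      se=se, results=fit)


# ---------------------------------------------------------------------------
# calibration of comparator transition matrices
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    drug: str
    dimension: str
    delta: float
    achieved_change: float
    target_change: float
    objective_value: float


def shift_row(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift one transition row on the cumulative-logit scale.

    Positive ``delta`` moves probability mass toward lower (better) severity
    levels; the row remains a probability vector and the shift is monotone
    in ``delta``.  Degenerate cumulative probabilities (0 or 1) are fixed
    points, so structurally impossible destinations stay impossible.
    """
    p = np.asarray(p, float)
    F = np.cumsum(p)[:-1]
    interior = (F > 0.0) & (F < 1.0)
    F_new = F.copy()
    F_new[interior] = expit(logit(F[interior]) + delta)
    full = np.concatenate(([0.0], F_new, [1.0]))
    out = np.diff(full)
    return np.clip(out, 0.0, 1.0)


def shift_transition_model(tm: TransitionModel, delta: float,
                           dimension: str) -> TransitionModel:
    """Apply the same latent shift to all three monthly matrices of one dimension."""
    out = tm.copy()
    for m in MONTHS:
        mat = out.matrices[dimension][m]
        out.matrices[dimension][m] = np.vstack([shift_row(row, delta) for row in mat])
    return out


def predicted_mean_change(tm: TransitionModel, baseline: np.ndarray,
                          dimension: str,
                          midpoints: dict[str, list[float]]) -> float:
    """Expected change in daily symptom count from baseline to month 3.

    ``baseline`` is the marginal level distribution for ``dimension``.
    The cohort is pushed through the month 1, 2 and 3 matrices and the
    expected daily count (via the configured level midpoints) is compared
    with baseline.
    """
    b = np.asarray(baseline, float)
    counts = np.array([severity_to_daily_count(k, dimension, midpoints)
                       for k in range(1, len(b) + 1)])
    d = b.copy()
    for m in MONTHS:
        d = d @ tm.matrices[dimension][m]
    return float(d @ counts - b @ counts)


def calibrate_comparator_transitions(
    ref_tm: TransitionModel,
    target_diff: float,
    baseline: np.ndarray,
    dimension: str,
    midpoints: dict[str, list[float]],
    drug: str | None = None,
    delta_bounds: tuple[float, float] = (-8.0, 8.0),
) -> tuple[CalibrationResult, TransitionModel]:
    """Find the latent shift reproducing an NMA mean difference.

    Solves for the scalar ``delta`` such that the calibrated model's
    predicted month-3 change equals the reference model's change plus
    ``target_diff`` (episodes/day; positive = less improvement than the
    reference).  The achieved change is monotone in ``delta`` so a bracketed
    root search is used; if the target is unreachable within
    ``delta_bounds``, the closer bound is returned with a
    :class:`CalibrationWarning`.
    """
    if not np.isfinite(target_diff):
        raise ValueError("target_diff must be finite")
    drug = drug or ref_tm.drug
    ref_change = predicted_mean_change(ref_tm, baseline, dimension, midpoints)
    target = ref_change + target_diff

    def achieved(delta: float) -> float:
        return predicted_mean_change(
            shift_transition_model(ref_tm, delta, dimension),
            baseline, dimension, midpoints)

    lo, hi = delta_bounds
    # achieved() is decreasing in delta (positive delta -> lower counts)
    f_lo, f_hi = achieved(lo) - target, achieved(hi) - target
    if f_lo == 0.0:
        delta = lo
    elif f_hi == 0.0:
        delta = hi
    elif f_lo * f_hi > 0:
        delta = lo if abs(f_lo) < abs(f_hi) else hi
        warnings.warn(
            f"{drug}/{dimension}: target change {target:.4f} unreachable within "
            f"delta bounds {delta_bounds}; achieved {achieved(delta):.4f}",
            CalibrationWarning)
    else:
        try:
            delta = brentq(lambda d: achieved(d) - target, lo, hi,
                           xtol=1e-12, rtol=8.9e-16, maxiter=200)
        except RuntimeError as exc:  # pragma: no cover
            raise EstimationError(f"calibration root search failed: {exc}") from None
    cal_tm = shift_transition_model(ref_tm, delta, dimension)
    cal_tm.drug = drug
    ach = predicted_mean_change(cal_tm, baseline, dimension, midpoints)
    result = CalibrationResult(
        drug=drug, dimension=dimension, delta=float(delta),
        achieved_change=ach, target_change=target,
        objective_value=(ach - target) ** 2)
    return result, cal_tm


def calibrate_drug(ref_tm: TransitionModel, drug: DrugSpec,
                   baseline_joint: np.ndarray,
                   midpoints: dict[str, list[float]],
                   ) -> tuple[dict[str, CalibrationResult], TransitionModel]:
    """Calibrate both symptom dimensions of one comparator drug.

    NMA mean differences are applied independently per dimension; the
    baseline marginals are taken from the joint baseline distribution.
    """
    if drug.nma_mean_diff is None:
        raise EstimationError(
            f"drug '{drug.name}' has no transition matrices and no NMA mean "
            "differences to calibrate from")
    tm = ref_tm.copy()
    tm.drug = drug.name
    results = {}
    for axis, dim in ((1, "micturition"), (0, "incontinence")):
        marginal = baseline_joint.sum(axis=axis)
        target_diff = drug.nma_mean_diff[DIMENSION_TO_NMA[dim]]
        res, shifted = calibrate_comparator_transitions(
            ref_tm, target_diff, marginal, dim, midpoints, drug=drug.name)
        tm.matrices[dim] = shifted.matrices[dim]
        results[dim] = res
    return results, tm


def prepare_transition_models(params: ParamSet, drugs: list[str],
                              ) -> tuple[dict[str, TransitionModel],
                                         dict[str, dict[str, CalibrationResult]]]:
    """Resolve a transition model for each requested drug.

    Drugs with a model in ``params.transition_models`` use it verbatim
    (the reference drug must); the rest are calibrated from the reference
    model and their NMA mean differences.
    """
    ref_name = params.reference.name
    if ref_name not in params.transition_models:
        raise EstimationError(
            f"reference drug '{ref_name}' must carry fitted transition matrices")
    ref_tm = params.transition_models[ref_name]
    models: dict[str, TransitionModel] = {}
    calibrations: dict[str, dict[str, CalibrationResult]] = {}
    for name in dict.fromkeys(drugs):
        if name in params.transition_models:
            models[name] = params.transition_models[name]
        else:
            results, tm = calibrate_drug(
                ref_tm, params.drug(name),
                params.settings.baseline_distribution,
                params.settings.severity_midpoints)
            models[name] = tm
            calibrations[name] = results
    return models, calibrations


# ---------------------------------------------------------------------------
# adverse-event probability resolution
# ---------------------------------------------------------------------------

def resolve_ae_prob_3m(drug: DrugSpec, reference: DrugSpec, ae: str) -> float:
    """3-month AE probability for a drug, via odds ratio when not direct."""
    if ae in drug.ae_prob_3m:
        return drug.ae_prob_3m[ae]
    if drug.ae_odds_ratio is not None and ae in drug.ae_odds_ratio:
        return adjust_probability_by_odds_ratio(
            reference.ae_prob_3m[ae], drug.ae_odds_ratio[ae])
    raise EstimationError(
        f"drug '{drug.name}' has neither a 3-month probability nor an odds "
        f"ratio for adverse event '{ae}'")
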