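"""Deterministic, probabilistic and scenario sensitivity analyses.

All three analyses perturb a :class:`~oabcea.parameters.ParamSet`, rebuild
every derived quantity (monthly probability conversions happen inside the
engine; comparator transition matrices are recalibrated from the perturbed
NMA mean differences), rerun both arms and record the incremental cost and
QALYs.  Parameters are addressed by dotted path, e.g.
``pathway.p_discontinue_ae``, ``drugs.tolterodine_er_4mg.ae_prob_3m.dry_mouth``,
``utility.mict_coefs.1`` or ``cost.pads_per_month.5``.

Probabilistic draws use standard health-economics distribution families by
parameter class: beta for probabilities (method-of-moments from the point
estimate and its interval, falling back to uniform on the interval when the
implied variance is infeasible), normal for utility coefficients and NMA
mean differences, lognormal for odds ratios, gamma for resource counts.
Interval half-widths are read as 95% confidence intervals (SE = width/3.92).
Draws are independent across parameters and bit-reproducible per seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .economics import ArmResult, CEAResult, accumulate, compare
from .engine import run_cohort
from .estimation import CalibrationResult, prepare_transition_models
from .parameters import ParamSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter addressing
# ---------------------------------------------------------------------------

def _resolve(params: ParamSet, path: str):
    """Returns (container, key) such that container[key] or attr is the value."""
    parts = path.split(".")
    root = parts[0]
    if root == "drugs":
        obj = params.drug(parts[1])
        rest = parts[2:]
    elif root in ("pathway", "utility", "cost", "settings"):
        obj = getattr(params, root)
        rest = parts[1:]
    else:
        raise KeyError(f"unknown parameter root '{root}' in '{path}'")
    for i, part in enumerate(rest):
        last = i == len(rest) - 1
        if isinstance(obj, dict):
            key = int(part) if part.lstrip("-").isdigit() else part
            if key not in obj:
                raise KeyError(f"'{path}': no key '{part}'")
            if last:
                return obj, key
            obj = obj[key]
        else:
            if not hasattr(obj, part):
                raise KeyError(f"'{path}': no field '{part}'")
            if last:
                return obj, part
            obj = getattr(obj, part)
    raise KeyError(f"'{path}' does not address a value")


def get_param(params: ParamSet, path: str) -> float:
    obj, key = _resolve(params, path)
    return obj[key] if isinstance(obj, dict) else getattr(obj, key)


def set_param(params: ParamSet, path: str, value: float) -> None:
    obj, key = _resolve(params, path)
    if isinstance(obj, dict):
        obj[key] = value
    else:
        setattr(obj, key, value)


def default_dsa_ranges(params: ParamSet) -> dict[str, tuple[float, float]]:
    """Collect every configured deterministic-sensitivity interval by path."""
    ranges: dict[str, tuple[float, float]] = {}
    for d in params.drugs:
        for sub, rng in d.dsa_ranges.items():
            if sub == "discontinuation_monthly_no_ae" and d.discontinuation_monthly_no_ae is None:
                continue  # governed by the pathway-level knob
            ranges[f"drugs.{d.name}.{sub}"] = rng
    for section in ("pathway", "utility", "cost"):
        spec = getattr(params, section)
        for sub, rng in spec.dsa_ranges.items():
            ranges[f"{section}.{sub}"] = rng
    return ranges


# ---------------------------------------------------------------------------
# core evaluation
# ---------------------------------------------------------------------------

@dataclass
class Evaluation:
    intervention: ArmResult
    comparator: ArmResult
    cea: CEAResult
    calibrations: dict[str, dict[str, CalibrationResult]]
    traces: dict[str, object] = field(default_factory=dict)


def evaluate_comparison(params: ParamSet, intervention: str, comparator: str,
                        wtp: float = 30000.0, keep_traces: bool = False,
                        ) -> Evaluation:
    """Calibrate, run both arms over the horizon and compare them."""
    needed = [intervention, comparator, params.pathway.next_line_transition_source]
    models, calibrations = prepare_transition_models(params, needed)
    arms = {}
    traces = {}
    for drug in (intervention, comparator):
        trace = run_cohort(params, drug, models)
        arms[drug] = accumulate(trace, params)
        if keep_traces:
            traces[drug] = trace
    cea = compare(arms[intervention], arms[comparator], wtp=wtp)
    return Evaluation(intervention=arms[intervention], comparator=arms[comparator],
                      cea=cea, calibrations=calibrations, traces=traces)


# ---------------------------------------------------------------------------
# one-way (tornado) analysis
# ---------------------------------------------------------------------------

@dataclass
class OneWayResult:
    parameter: str
    low_value: float
    high_value: float
    cost_low: float
    cost_high: float
    qalys_low: float
    qalys_high: float

    @property
    def cost_range(self) -> float:
        return abs(self.cost_high - self.cost_low)

    @property
    def qalys_range(self) -> float:
        return abs(self.qalys_high - self.qalys_low)


def run_one_way(params: ParamSet, ranges: dict[str, tuple[float, float]],
                comparator: str, intervention: str | None = None,
                wtp: float = 30000.0) -> tuple[CEAResult, list[OneWayResult]]:
    """Vary each parameter to its bounds, rerunning the full comparison.

    Each range must bracket the base-case value.  Returns the base-case
    result and one :class:`OneWayResult` per parameter with the incremental
    cost and QALYs at each bound (sortable by range for tornado plots).
    """
    intervention = intervention or params.reference.name
    for path, (lo, hi) in ranges.items():
        base = get_param(params, path)
        if not lo <= base <= hi:
            raise ValueError(
                f"range ({lo}, {hi}) for '{path}' does not bracket base value {base}")
    base_eval = evaluate_comparison(params, intervention, comparator, wtp)
    out = []
    for path, (lo, hi) in ranges.items():
        bounds = {}
        for label, value in (("low", lo), ("high", hi)):
            trial = params.copy()
            set_param(trial, path, value)
            ev = evaluate_comparison(trial, intervention, comparator, wtp)
            bounds[label] = ev.cea
        out.append(OneWayResult(
            parameter=path, low_value=lo, high_value=hi,
            cost_low=bounds["low"].incremental_cost,
            cost_high=bounds["high"].incremental_cost,
            qalys_low=bounds["low"].incremental_qalys,
            qalys_high=bounds["high"].incremental_qalys))
    return base_eval.cea, out


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASample:
    draw_id: int
    values: dict[str, float]
    delta_cost: float
    delta_qalys: float


def _classify_path(path: str) -> str:
    if "nma_mean_diff" in path:
        return "normal"
    if "odds_ratio" in path or path.endswith(("or_dry_mouth", "or_constipation")):
        return "lognormal"
    if path.startswith("utility."):
        return "normal"
    if "pads_per_month" in path:
        return "gamma"
    if path.startswith("cost."):
        return "gamma"
    return "beta"  # probabilities (AE, pathway, discontinuation)


def _draw(rng: np.random.Generator, family: str, base: float,
          lo: float, hi: float, path: str) -> float:
    sd = (hi - lo) / 3.92
    if sd <= 0.0:
        return base
    if family == "beta":
        if base <= 0.0 or base >= 1.0:
            return base
        var = sd * sd
        max_var = base * (1.0 - base)
        if var >= max_var:
            logger.info("PSA: '%s' beta moments infeasible, using uniform(%g, %g)",
                        path, lo, hi)
            return float(rng.uniform(lo, hi))
        nu = max_var / var - 1.0
        return float(rng.beta(base * nu, (1.0 - base) * nu))
    if family == "normal":
        return float(rng.normal(base, sd))
    if family == "lognormal":
        if base <= 0 or lo <= 0:
            return base
        sigma = (np.log(hi) - np.log(lo)) / 3.92
        return float(base * np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    if family == "gamma":
        if base <= 0.0:
            return base
        var = sd * sd
        return float(rng.gamma(base * base / var, var / base))
    raise ValueError(family)


def run_psa(params: ParamSet, n_iter: int, seed: int, comparator: str,
            intervention: str | None = None, wtp: float = 30000.0,
            ranges: dict[str, tuple[float, float]] | None = None,
            ) -> list[PSASample]:
    """Monte-Carlo propagation of parameter uncertainty.

    Per iteration, every parameter with a configured interval is drawn from
    its class's distribution, the comparison is rebuilt and rerun, and
    (dCost, dQALY) recorded.  A fixed seed reproduces the sample set
    bit-identically.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    intervention = intervention or params.reference.name
    ranges = ranges if ranges is not None else default_dsa_ranges(params)
    specs = sorted(ranges.items())  # fixed order for reproducibility
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_iter):
        trial = params.copy()
        values = {}
        for path, (lo, hi) in specs:
            base = get_param(params, path)
            val = _draw(rng, _classify_path(path), base, lo, hi, path)
            values[path] = val
            set_param(trial, path, val)
        ev = evaluate_comparison(trial, intervention, comparator, wtp)
        samples.append(PSASample(draw_id=i, values=values,
                                 delta_cost=ev.cea.incremental_cost,
                                 delta_qalys=ev.cea.incremental_qalys))
    return samples


def ceac(samples: list[PSASample], wtp_grid: list[float]) -> dict[float, float]:
    """Cost-effectiveness acceptability curve from PSA samples.

    For each willingness-to-pay value, the fraction of samples whose net
    monetary benefit ``wtp * dQALY - dCost`` is nonnegative.
    """
    if not samples:
        raise ValueError("no PSA samples")
    dq = np.array([s.delta_qalys for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    return {float(w): float(np.mean(w * dq - dc >= 0.0)) for w in wtp_grid}


# ---------------------------------------------------------------------------
# scenario analysis: observational discontinuation rates
# ---------------------------------------------------------------------------

def run_scenario_discontinuation(params: ParamSet,
                                 per_drug_rates: dict[str, float],
                                 comparators: list[str] | None = None,
                                 wtp: float = 30000.0) -> dict[str, CEAResult]:
    """Replace all discontinuation probabilities with observed per-drug rates.

    The per-drug monthly rate applies both with and without adverse events
    (observational sources cannot separate the two).  Every drug in the
    parameter set must have a rate.
    """
    for name, rate in per_drug_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for '{name}' out of [0,1]: {rate}")
    trial = params.copy()
    for d in trial.drugs:
        if d.name not in per_drug_rates:
            raise KeyError(f"no discontinuation rate supplied for drug '{d.name}'")
        d.discontinuation_monthly_no_ae = per_drug_rates[d.name]
        d.discontinuation_monthly_ae = per_drug_rates[d.name]
    intervention = trial.reference.name
    comparators = comparators if comparators is not None else trial.comparators()
    return {c: evaluate_comparison(trial, intervention, c, wtp).cea
            for c in comparators}
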