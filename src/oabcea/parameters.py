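"""Parameter schema for the overactive-bladder cost-utility model.

The model is parameterized by:

* a list of :class:`DrugSpec` (monthly acquisition cost, 3-month adverse
  event probabilities for dry mouth and constipation, network-meta-analysis
  mean differences in daily symptom counts versus the reference drug,
  monthly discontinuation probability without adverse events);
* a :class:`PathwaySpec` describing the treatment pathway (discontinuation
  with adverse events, switching, restart, botulinum toxin type A);
* a :class:`UtilitySpec` with EQ-5D utility coefficients by symptom
  severity level (level L is the reference, worst, level) and the adverse
  event utility decrement;
* a :class:`CostSpec` with resource use (incontinence pads per month by
  severity level) and unit costs (GBP, UK NHS perspective);
* :class:`Settings` (cycle length, horizon, discount rate, baseline
  severity distribution, severity-level midpoints, willingness-to-pay grid).

Parameter files are a single structured YAML document (schema below);
drug tables can also be imported from CSV.  Unknown keys are errors, not
warnings: silent typos in health-economic inputs are a known failure mode.
Validation is data, not exceptions: :func:`validate_parameter_set` returns
a list of :class:`Violation` records, empty iff the set is usable.
"""
from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import yaml

from .transitions import DIMENSIONS, TransitionModel

SCHEMA_VERSION = "1.0"

AE_TYPES = ("dry_mouth", "constipation")
NMA_OUTCOMES = ("micturitions_per_day", "incontinence_per_day")

#: maps symptom dimension -> key used for NMA mean differences
DIMENSION_TO_NMA = {
    "micturition": "micturitions_per_day",
    "incontinence": "incontinence_per_day",
}


class SchemaError(ValueError):
    """A config file does not match the documented schema."""


class ValidationError(ValueError):
    """A ParamSet violates one or more invariants."""


@dataclass(frozen=True)
class Violation:
    type_name: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.type_name}.{self.field}: {self.rule}"


# ---------------------------------------------------------------------------
# component specs
# ---------------------------------------------------------------------------

@dataclass
class DrugSpec:
    """One oral antimuscarinic agent.

    ``ae_prob_3m`` are probabilities of dry mouth / constipation over the
    first 3 months on the drug; the engine converts them to constant-hazard
    monthly probabilities.  ``ae_odds_ratio`` (versus the reference drug) is
    used to derive a missing ``ae_prob_3m`` entry from the reference drug's.
    ``nma_mean_diff`` is the change in daily symptom count for this drug
    minus the change for the reference drug (episodes/day; positive means
    less improvement than the reference), used to calibrate transition
    matrices.  ``dsa_ranges`` holds deterministic-sensitivity intervals
    keyed by dotted field path (e.g. ``"ae_prob_3m.dry_mouth"``).
    """

    name: str
    monthly_cost: float
    ae_prob_3m: dict[str, float] = field(default_factory=dict)
    ae_odds_ratio: dict[str, float] | None = None
    nma_mean_diff: dict[str, float] | None = None
    #: per-drug overrides; ``None`` falls back to the PathwaySpec values
    discontinuation_monthly_no_ae: float | None = None
    discontinuation_monthly_ae: float | None = None
    is_reference: bool = False
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class PathwaySpec:
    """Treatment-pathway probabilities (per 1-month cycle unless noted)."""

    p_discontinue_ae: float = 0.90
    p_discontinue_no_ae: float = 0.068
    p_switch_after_discontinuation: float = 0.261
    p_restart_monthly: float = 0.056
    restart_split: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    p_btxa_monthly: float = 0.001
    p_btxa_reinjection_6m: float = 0.70
    next_line_a: str = "tolterodine_er_4mg"
    next_line_b: str = "oxybutynin_ir_10mg"
    #: drug whose transition matrices next-line therapies use
    next_line_transition_source: str = "tolterodine_er_4mg"
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class UtilitySpec:
    """EQ-5D utility model: state utility = base + level coefficients.

    ``base_utility`` is the utility of the reference state (worst level in
    both dimensions); ``mict_coefs[k]`` / ``incont_coefs[k]`` are increments
    for being at level k instead of level L.  ``ae_decrement`` applies for
    the duration of a cycle to on-treatment patients with an active AE.
    """

    base_utility: float
    mict_coefs: dict[int, float] = field(default_factory=dict)
    incont_coefs: dict[int, float] = field(default_factory=dict)
    ae_decrement: float = -0.0357
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def coef(self, dimension: str, level: int, n_levels: int) -> float:
        if level == n_levels:
            return 0.0
        coefs = self.mict_coefs if dimension == "micturition" else self.incont_coefs
        return coefs[level]


@dataclass
class CostSpec:
    """Resource use and unit costs (GBP, 2015-2016 values)."""

    pads_per_month: dict[int, float] = field(default_factory=dict)
    pad_unit_cost: float = 0.17
    gp_first_visit: float = 65.00
    gp_followup: float = 27.00
    specialist_visit: float = 94.00
    specialist_visits_at_initiation: float = 1.0
    btxa_injection_cost: float = 1151.98
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class Settings:
    """Global model settings."""

    cycle_length: int = 1  # months
    horizon: int = 60  # months
    annual_discount_rate: float = 0.035
    baseline_distribution: np.ndarray = field(
        default_factory=lambda: np.full((5, 5), 0.04)
    )
    severity_midpoints: dict[str, list[float]] = field(
        default_factory=lambda: {
            "micturition": [6.0, 9.0, 11.0, 13.0, 16.0],
            "incontinence": [0.0, 0.5, 1.5, 3.0, 6.0],
        }
    )
    wtp_grid: list[float] = field(
        default_factory=lambda: [float(w) for w in range(0, 50001, 2500)]
    )
    seed: int = 1
    half_cycle_correction: bool = False
    #: optional L x L symptom distribution applied while on BTX-A
    btxa_symptom_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.baseline_distribution = np.asarray(self.baseline_distribution, float)
        if self.btxa_symptom_distribution is not None:
            self.btxa_symptom_distribution = np.asarray(
                self.btxa_symptom_distribution, float
            )

    @property
    def n_levels(self) -> int:
        return self.baseline_distribution.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.horizon // self.cycle_length


@dataclass
class ParamSet:
    """The full model parameterization."""

    drugs: list[DrugSpec]
    pathway: PathwaySpec
    utility: UtilitySpec
    cost: CostSpec
    settings: Settings
    transition_models: dict[str, TransitionModel] = field(default_factory=dict)

    # -- lookups --------------------------------------------------------
    def drug(self, name: str) -> DrugSpec:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(f"unknown drug '{name}'")

    def drug_names(self) -> list[str]:
        return [d.name for d in self.drugs]

    @property
    def reference(self) -> DrugSpec:
        refs = [d for d in self.drugs if d.is_reference]
        if len(refs) != 1:
            raise ValidationError(f"expected exactly one reference drug, got {len(refs)}")
        return refs[0]

    def comparators(self) -> list[str]:
        return [d.name for d in self.drugs if not d.is_reference]

    @property
    def n_levels(self) -> int:
        return self.settings.n_levels

    def copy(self) -> "ParamSet":
        return copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParamSet):
            return NotImplemented
        return paramset_to_dict(self) == paramset_to_dict(other)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _prob_ok(p: float) -> bool:
    return isinstance(p, (int, float)) and math.isfinite(p) and 0.0 <= p <= 1.0


def validate_parameter_set(params: ParamSet) -> list[Violation]:
    """Check every invariant; returns an empty list iff the set is valid.

    Violations are data, not exceptions: each names the type, field and rule
    that failed, so a config author can fix all problems in one pass.
    """
    v: list[Violation] = []
    L = params.n_levels

    # drugs
    refs = 0
    for d in params.drugs:
        t = f"DrugSpec[{d.name}]"
        if d.monthly_cost < 0:
            v.append(Violation(t, "monthly_cost", "must be >= 0"))
        for ae, p in d.ae_prob_3m.items():
            if ae not in AE_TYPES:
                v.append(Violation(t, f"ae_prob_3m.{ae}", "unknown adverse event type"))
            elif not _prob_ok(p):
                v.append(Violation(t, f"ae_prob_3m.{ae}", "probability out of [0,1]"))
        if d.ae_odds_ratio is not None:
            for ae, r in d.ae_odds_ratio.items():
                if not (math.isfinite(r) and r > 0):
                    v.append(Violation(t, f"ae_odds_ratio.{ae}", "odds ratio must be > 0"))
        if d.discontinuation_monthly_no_ae is not None and not _prob_ok(d.discontinuation_monthly_no_ae):
            v.append(Violation(t, "discontinuation_monthly_no_ae", "probability out of [0,1]"))
        if d.discontinuation_monthly_ae is not None and not _prob_ok(d.discontinuation_monthly_ae):
            v.append(Violation(t, "discontinuation_monthly_ae", "probability out of [0,1]"))
        if d.nma_mean_diff is not None:
            for k, x in d.nma_mean_diff.items():
                if k not in NMA_OUTCOMES:
                    v.append(Violation(t, f"nma_mean_diff.{k}", "unknown NMA outcome"))
                elif not math.isfinite(x):
                    v.append(Violation(t, f"nma_mean_diff.{k}", "must be finite"))
        refs += bool(d.is_reference)
    if refs != 1:
        v.append(Violation("ParamSet", "drugs", f"exactly one reference drug required, found {refs}"))

    # pathway
    pw = params.pathway
    for f in ("p_discontinue_ae", "p_discontinue_no_ae", "p_switch_after_discontinuation",
              "p_restart_monthly", "p_btxa_monthly", "p_btxa_reinjection_6m"):
        if not _prob_ok(getattr(pw, f)):
            v.append(Violation("PathwaySpec", f, "probability out of [0,1]"))
    if abs(sum(pw.restart_split) - 1.0) > 1e-9:
        v.append(Violation("PathwaySpec", "restart_split", "fractions must sum to 1"))
    if any(x < 0 for x in pw.restart_split):
        v.append(Violation("PathwaySpec", "restart_split", "fractions must be >= 0"))
    names = set(params.drug_names())
    for f in ("next_line_a", "next_line_b", "next_line_transition_source"):
        if getattr(pw, f) not in names:
            v.append(Violation("PathwaySpec", f, f"unknown drug '{getattr(pw, f)}'"))

    # utility
    u = params.utility
    allc = [u.base_utility, u.ae_decrement, *u.mict_coefs.values(), *u.incont_coefs.values()]
    if not all(math.isfinite(x) for x in allc):
        v.append(Violation("UtilitySpec", "coefficients", "must be finite"))
    else:
        for coefs, fname in ((u.mict_coefs, "mict_coefs"), (u.incont_coefs, "incont_coefs")):
            missing = [k for k in range(1, L) if k not in coefs]
            if missing:
                v.append(Violation("UtilitySpec", fname, f"missing levels {missing}"))
        best = (u.base_utility
                + max([0.0, *u.mict_coefs.values()])
                + max([0.0, *u.incont_coefs.values()]))
        if best > 1.0 + 1e-12:
            v.append(Violation("UtilitySpec", "base_utility", "best state utility exceeds 1"))

    # cost
    c = params.cost
    for f in ("pad_unit_cost", "gp_first_visit", "gp_followup", "specialist_visit",
              "btxa_injection_cost"):
        if getattr(c, f) < 0:
            v.append(Violation("CostSpec", f, "must be >= 0"))
    if c.specialist_visits_at_initiation < 0:
        v.append(Violation("CostSpec", "specialist_visits_at_initiation", "must be >= 0"))
    pads = [c.pads_per_month.get(k) for k in range(1, L + 1)]
    if any(p is None for p in pads):
        v.append(Violation("CostSpec", "pads_per_month", f"must cover levels 1..{L}"))
    else:
        if any(p < 0 for p in pads):
            v.append(Violation("CostSpec", "pads_per_month", "counts must be >= 0"))
        if any(b < a for a, b in zip(pads, pads[1:])):
            v.append(Violation("CostSpec", "pads_per_month",
                               "counts must be nondecreasing in incontinence level"))

    # settings
    s = params.settings
    bd = s.baseline_distribution
    if bd.ndim != 2 or bd.shape[0] != bd.shape[1]:
        v.append(Violation("Settings", "baseline_distribution", "must be a square matrix"))
    else:
        if np.any(bd < 0):
            v.append(Violation("Settings", "baseline_distribution", "entries must be >= 0"))
        if abs(bd.sum() - 1.0) > 1e-9:
            v.append(Violation("Settings", "baseline_distribution",
                               f"entries must sum to 1 (got {bd.sum():.6f})"))
    if s.horizon % s.cycle_length != 0:
        v.append(Violation("Settings", "horizon", "must be a multiple of cycle_length"))
    if s.annual_discount_rate < 0:
        v.append(Violation("Settings", "annual_discount_rate", "must be >= 0"))
    for dim in DIMENSIONS:
        mids = s.severity_midpoints.get(dim)
        if mids is None or len(mids) != L:
            v.append(Violation("Settings", f"severity_midpoints.{dim}",
                               f"must list {L} level midpoints"))
    if s.btxa_symptom_distribution is not None:
        b2 = s.btxa_symptom_distribution
        if b2.shape != bd.shape or np.any(b2 < 0) or abs(b2.sum() - 1.0) > 1e-9:
            v.append(Violation("Settings", "btxa_symptom_distribution",
                               "must be a nonnegative matrix summing to 1, same shape as baseline"))

    # transition models
    for name, tm in params.transition_models.items():
        if name not in names:
            v.append(Violation("ParamSet", f"transition_models.{name}", "unknown drug"))
            continue
        for msg in tm.validate():
            v.append(Violation("TransitionModel", name, msg))
        if not tm.validate() and tm.n_levels != L:
            v.append(Violation("TransitionModel", name,
                               f"has {tm.n_levels} levels, settings define {L}"))
    return v


# ---------------------------------------------------------------------------
# (de)serialization: YAML config
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"restart_split"}


def _spec_to_dict(spec) -> dict:
    out = {}
    for f in dc_fields(spec):
        val = getattr(spec, f.name)
        if val is None:
            continue
        if isinstance(val, np.ndarray):
            val = val.tolist()
        elif isinstance(val, tuple):
            val = list(val)
        elif isinstance(val, dict):
            val = {k: (list(x) if isinstance(x, tuple) else x) for k, x in val.items()}
        out[f.name] = val
    return out


def _spec_from_dict(cls, data: dict, section: str):
    allowed = {f.name for f in dc_fields(cls)}
    kwargs = {}
    for k, val in data.items():
        if k not in allowed:
            raise SchemaError(f"unknown key '{k}' in section '{section}'")
        if k in _TUPLE_FIELDS:
            val = tuple(val)
        elif k == "dsa_ranges":
            val = {kk: tuple(vv) for kk, vv in val.items()}
        elif k in ("mict_coefs", "incont_coefs", "pads_per_month"):
            val = {int(kk): float(vv) for kk, vv in val.items()}
        kwargs[k] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise SchemaError(f"section '{section}': {exc}") from None


def paramset_to_dict(params: ParamSet) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "drugs": [_spec_to_dict(d) for d in params.drugs],
        "pathway": _spec_to_dict(params.pathway),
        "utility": _spec_to_dict(params.utility),
        "cost": _spec_to_dict(params.cost),
        "settings": _spec_to_dict(params.settings),
        "transition_models": {
            name: tm.to_dict() for name, tm in params.transition_models.items()
        },
    }


def paramset_from_dict(data: dict) -> ParamSet:
    allowed = {"schema_version", "drugs", "pathway", "utility", "cost",
               "settings", "transition_models"}
    for k in data:
        if k not in allowed:
            raise SchemaError(f"unknown top-level key '{k}'")
    version = data.get("schema_version")
    if version is not None and str(version) != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version '{version}'")
    if "drugs" not in data or "utility" not in data:
        raise SchemaError("config must define at least 'drugs' and 'utility'")
    drugs = [_spec_from_dict(DrugSpec, d, f"drugs[{i}]") for i, d in enumerate(data["drugs"])]
    params = ParamSet(
        drugs=drugs,
        pathway=_spec_from_dict(PathwaySpec, data.get("pathway", {}), "pathway"),
        utility=_spec_from_dict(UtilitySpec, data["utility"], "utility"),
        cost=_spec_from_dict(CostSpec, data.get("cost", {}), "cost"),
        settings=_spec_from_dict(Settings, data.get("settings", {}), "settings"),
        transition_models={
            name: TransitionModel.from_dict(name, tm)
            for name, tm in data.get("transition_models", {}).items()
        },
    )
    return params


def load_parameter_set(path: str, validate: bool = True) -> ParamSet:
    """Load and validate a ParamSet from a YAML config file.

    Raises :class:`SchemaError` on parse/schema problems (naming the
    offending key) and :class:`ValidationError` listing every failed
    invariant when ``validate`` is true.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"cannot parse '{path}': {exc}") from None
    if not isinstance(data, dict):
        raise SchemaError(f"'{path}' does not contain a mapping")
    params = paramset_from_dict(data)
    if validate:
        violations = validate_parameter_set(params)
        if violations:
            raise ValidationError(
                "invalid parameter set:\n" + "\n".join(f"  - {x}" for x in violations)
            )
    return params


def default_config_path() -> str:
    """Path of the packaged default (base-case) configuration file."""
    import importlib.resources as res

    return str(res.files("oabcea").joinpath("data/default_config.yaml"))


def write_parameter_set(params: ParamSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(paramset_to_dict(params), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV import helper for drug tables
# ---------------------------------------------------------------------------

DRUG_CSV_HEADER = [
    "name", "monthly_cost", "dry_mouth_prob_3m", "constipation_prob_3m",
    "discontinuation_monthly_no_ae", "is_reference",
]


def drugs_from_csv(path: str) -> list[DrugSpec]:
    """Import a drug table from CSV with the fixed header ``DRUG_CSV_HEADER``."""
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != DRUG_CSV_HEADER:
            raise SchemaError(
                f"drug CSV header must be {DRUG_CSV_HEADER}, got {header}")
        for row in reader:
            if not row:
                continue
            name, cost, dm, cons, disc, ref = row
            out.append(DrugSpec(
                name=name,
                monthly_cost=float(cost),
                ae_prob_3m={"dry_mouth": float(dm), "constipation": float(cons)},
                discontinuation_monthly_no_ae=float(disc) if disc.strip() else None,
                is_reference=ref.strip().lower() in ("1", "true", "yes"),
            ))
    return out
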