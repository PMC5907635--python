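"""Model/Results facade for the cost-utility analysis.

`CostUtilityModel` is constructed from a parameter set plus the pair of
arms to compare; `fit()` calibrates the comparator's transition matrices,
runs the cohort over the horizon for both arms and returns a
`CostUtilityResults` carrying discounted cost breakdowns, QALYs, the ICER
and its dominance classification, with a printable `summary()`.
Sensitivity analyses hang off the model: `one_way()` (tornado),
`psa()` (probabilistic, with acceptability-curve and cost-effectiveness
plane helpers) and `scenario_discontinuation()`.

Example
-------
>>> from oabcea import CostUtilityModel
>>> model = CostUtilityModel.from_synthetic(comparator="tolterodine_er_4mg")
>>> res = model.fit()
>>> print(res.summary())            # doctest: +SKIP
>>> psa = model.psa(n_iter=1000, seed=7)
>>> psa.prob_cost_effective(30000)  # doctest: +SKIP
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import (COST_CATEGORIES, ArmResult, CEAResult,
                        net_monetary_benefit)
from .parameters import ParamSet, ValidationError, load_parameter_set, \
    validate_parameter_set
from .sensitivity import (OneWayResult, PSASample, ceac, default_dsa_ranges,
                          evaluate_comparison, run_one_way, run_psa,
                          run_scenario_discontinuation)

_CATEGORY_LABELS = {
    "drug_acquisition": "Drug acquisition",
    "other_oab_drugs": "Other OAB drug(s)",
    "gp_visits": "GP visits",
    "specialist_visits": "Specialist visits",
    "btxa": "Botulinum toxin",
    "pads": "Incontinence pads",
}


class CostUtilityModel:
    """Markov cohort cost-utility comparison of two treatment strategies.

    Parameters
    ----------
    params : ParamSet
        Full model parameterization (validated on construction).
    comparator : str
        Comparator arm drug name.
    intervention : str, optional
        Intervention arm; defaults to the parameter set's reference drug.
    wtp : float
        Willingness-to-pay threshold (GBP/QALY) for classification.
    """

    def __init__(self, params: ParamSet, comparator: str,
                 intervention: str | None = None, wtp: float = 30000.0,
                 validate: bool = True):
        if validate:
            violations = validate_parameter_set(params)
            if violations:
                raise ValidationError(
                    "invalid parameter set:\n"
                    + "\n".join(f"  - {v}" for v in violations))
        self.params = params
        self.intervention = intervention or params.reference.name
        self.comparator = params.drug(comparator).name
        self.wtp = float(wtp)

    @classmethod
    def from_config(cls, path: str, comparator: str, **kwargs) -> "CostUtilityModel":
        return cls(load_parameter_set(path), comparator, **kwargs)

    @classmethod
    def from_synthetic(cls, comparator: str = "tolterodine_er_4mg",
                       seed: int = 1, **kwargs) -> "CostUtilityModel":
        from .synthetic import make_default_paramset
        params, _ = make_default_paramset(seed)
        return cls(params, comparator, **kwargs)

    # -- fitting --------------------------------------------------------
    def fit(self, keep_traces: bool = True) -> "CostUtilityResults":
        ev = evaluate_comparison(self.params, self.intervention, self.comparator,
                                 wtp=self.wtp, keep_traces=keep_traces)
        return CostUtilityResults(model=self, intervention_arm=ev.intervention,
                                  comparator_arm=ev.comparator, cea=ev.cea,
                                  calibrations=ev.calibrations, traces=ev.traces)

    def fit_all_comparators(self) -> dict[str, "CostUtilityResults"]:
        """One result per non-intervention drug in the parameter set."""
        out = {}
        for name in self.params.drug_names():
            if name == self.intervention:
                continue
            model = CostUtilityModel(self.params, name, self.intervention,
                                     self.wtp, validate=False)
            out[name] = model.fit(keep_traces=False)
        return out

    # -- sensitivity ----------------------------------------------------
    def one_way(self, ranges: dict[str, tuple[float, float]] | None = None,
                ) -> "OneWayResults":
        if ranges is None:
            ranges = default_dsa_ranges(self.params)
        base, results = run_one_way(self.params, ranges, self.comparator,
                                    self.intervention, self.wtp)
        return OneWayResults(base=base, results=results)

    def psa(self, n_iter: int = 1000, seed: int | None = None,
            ranges: dict[str, tuple[float, float]] | None = None) -> "PSAResults":
        seed = self.params.settings.seed if seed is None else seed
        samples = run_psa(self.params, n_iter, seed, self.comparator,
                          self.intervention, self.wtp, ranges)
        return PSAResults(samples=samples, wtp=self.wtp,
                          wtp_grid=list(self.params.settings.wtp_grid))

    def scenario_discontinuation(self, per_drug_rates: dict[str, float],
                                 ) -> dict[str, CEAResult]:
        return run_scenario_discontinuation(self.params, per_drug_rates,
                                            comparators=[self.comparator],
                                            wtp=self.wtp)


@dataclass
class CostUtilityResults:
    """Fitted comparison: per-arm discounted totals and incremental results."""

    model: CostUtilityModel
    intervention_arm: ArmResult
    comparator_arm: ArmResult
    cea: CEAResult
    calibrations: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)

    # -- views ----------------------------------------------------------
    def table(self) -> pd.DataFrame:
        """Cost-category breakdown, totals, increments and ICER."""
        rows = {}
        for key in COST_CATEGORIES:
            rows[_CATEGORY_LABELS[key]] = [
                self.intervention_arm.cost_by_category.get(key, float("nan")),
                self.comparator_arm.cost_by_category.get(key, float("nan"))]
        rows["Total costs"] = [self.intervention_arm.total_cost,
                               self.comparator_arm.total_cost]
        rows["Total QALYs"] = [self.intervention_arm.total_qalys,
                               self.comparator_arm.total_qalys]
        return pd.DataFrame(rows, index=[self.cea.intervention,
                                         self.cea.comparator]).T

    def summary(self) -> str:
        """Printable result table in the conventional layout."""
        df = self.table()
        width = max(len(i) for i in df.index) + 2
        colw = max(len(c) for c in df.columns) + 2
        header = " " * width + "".join(f"{c:>{colw}}" for c in df.columns)
        body = []
        for idx, row in df.iterrows():
            dp = 4 if idx == "Total QALYs" else 2
            body.append(f"{idx:<{width}}"
                        + "".join(f"{v:>{colw},.{dp}f}" for v in row))
        lines = [
            "Cost-utility analysis (discounted, per patient)",
            "=" * 64,
            header,
            *body,
            "-" * 64,
            f"Incremental cost (GBP):   {self.cea.incremental_cost:,.2f}",
            f"Incremental QALYs:        {self.cea.incremental_qalys:.4f}",
            f"ICER (GBP/QALY):          "
            + (f"{self.cea.icer:,.0f}" if self.cea.icer is not None else "undefined"),
            f"Classification at WTP {self.cea.wtp:,.0f}: {self.cea.classification}",
            f"Net monetary benefit:     {net_monetary_benefit(self.cea):,.2f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "intervention": self.cea.intervention,
            "comparator": self.cea.comparator,
            "wtp": self.cea.wtp,
            "arms": {
                arm.arm: {"total_cost": arm.total_cost,
                          "total_qalys": arm.total_qalys,
                          "cost_by_category": arm.cost_by_category}
                for arm in (self.intervention_arm, self.comparator_arm)
            },
            "incremental_cost": self.cea.incremental_cost,
            "incremental_qalys": self.cea.incremental_qalys,
            "icer": self.cea.icer,
            "classification": self.cea.classification,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table_to_csv(self, path: str) -> None:
        df = self.table()
        extra = pd.DataFrame(
            {df.columns[0]: [self.cea.incremental_cost, self.cea.incremental_qalys,
                             self.cea.icer if self.cea.icer is not None else np.nan],
             df.columns[1]: [np.nan, np.nan, np.nan]},
            index=["Incremental costs", "Incremental QALYs", "ICER"])
        pd.concat([df, extra]).to_csv(path)


@dataclass
class OneWayResults:
    """Tornado-style one-way sensitivity results."""

    base: CEAResult
    results: list[OneWayResult]

    _COLUMNS = ("parameter", "low_value", "high_value", "delta_cost_low",
                "delta_cost_high", "delta_qalys_low", "delta_qalys_high",
                "cost_range", "qalys_range")

    def to_frame(self, sort_by: str = "cost") -> pd.DataFrame:
        df = pd.DataFrame([{
            "parameter": r.parameter,
            "low_value": r.low_value, "high_value": r.high_value,
            "delta_cost_low": r.cost_low, "delta_cost_high": r.cost_high,
            "delta_qalys_low": r.qalys_low, "delta_qalys_high": r.qalys_high,
            "cost_range": r.cost_range, "qalys_range": r.qalys_range,
        } for r in self.results], columns=list(self._COLUMNS))
        if len(df):
            df = df.sort_values(f"{sort_by}_range", ascending=False,
                                kind="stable").reset_index(drop=True)
        return df

    def plot_tornado(self, outcome: str = "cost", top: int = 15, ax=None):
        import matplotlib.pyplot as plt

        df = self.to_frame(sort_by=outcome).head(top).iloc[::-1]
        base = (self.base.incremental_cost if outcome == "cost"
                else self.base.incremental_qalys)
        lo = df[f"delta_{outcome}_low" if outcome == "cost" else "delta_qalys_low"]
        hi = df[f"delta_{outcome}_high" if outcome == "cost" else "delta_qalys_high"]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
        y = np.arange(len(df))
        left = np.minimum(lo, hi)
        width = np.abs(hi - lo)
        ax.barh(y, width, left=left, color="#4878d0")
        ax.axvline(base, color="k", lw=1)
        ax.set_yticks(y, df["parameter"])
        ax.set_xlabel("Incremental " + ("cost (GBP)" if outcome == "cost" else "QALYs"))
        return ax


@dataclass
class PSAResults:
    """Probabilistic sensitivity results: samples, CEAC and plane views."""

    samples: list[PSASample]
    wtp: float
    wtp_grid: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"draw_id": s.draw_id, "delta_qalys": s.delta_qalys,
                              "delta_cost": s.delta_cost} for s in self.samples])

    def ceac(self, wtp_grid: list[float] | None = None) -> dict[float, float]:
        return ceac(self.samples, wtp_grid or self.wtp_grid)

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        return self.ceac([self.wtp if wtp is None else wtp]).popitem()[1]

    def plot_ce_plane(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.scatter(df["delta_qalys"], df["delta_cost"], s=8, alpha=0.5)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        qs = np.array(sorted(df["delta_qalys"]))
        ax.plot(qs, self.wtp * qs, "r--", lw=1, label=f"WTP {self.wtp:,.0f}/QALY")
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (GBP)")
        ax.legend()
        return ax

    def plot_ceac(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac()
        ax.plot(list(curve), list(curve.values()), marker="o", ms=3)
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel("Willingness to pay (GBP/QALY)")
        ax.set_ylabel("P(cost-effective)")
        return ax
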