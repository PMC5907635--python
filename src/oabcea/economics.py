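"""Discounted costs, QALYs and cost-effectiveness comparison.

Costs fall into six categories (drug acquisition of the initial drug,
other OAB drugs, GP visits, specialist visits, botulinum toxin,
incontinence pads).  Each cycle's costs and QALYs are computed from the
start-of-cycle distribution and the cycle's event tally, discounted at
the annual rate with monthly compounding (cycle 1 undiscounted), and
summed over the horizon.  Pairwise comparison yields incremental cost,
incremental QALYs, the ICER where defined, and a dominance / threshold
classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import (ON_PHASES, PATHWAY_STATES, PHASE_BTXA_OK, PHASE_FIRST,
                     PHASE_NEXT_A, PHASE_NEXT_B, CohortDistribution,
                     CycleTally, Trace)
from .parameters import ParamSet

COST_CATEGORIES = ("drug_acquisition", "other_oab_drugs", "gp_visits",
                   "specialist_visits", "btxa", "pads")

CLASS_DOMINANT = "dominant"
CLASS_DOMINATED = "dominated"
CLASS_CE = "cost_effective_at_wtp"
CLASS_NOT_CE = "not_cost_effective_at_wtp"
CLASS_EQUIVALENT = "equivalent"


@dataclass
class ArmResult:
    """Discounted per-patient totals for one treatment arm."""

    arm: str
    total_cost: float
    total_qalys: float
    cost_by_category: dict[str, float] = field(default_factory=dict)

    def reconciles(self, tol: float = 0.5) -> bool:
        if not self.cost_by_category:
            return True
        return abs(self.total_cost - sum(self.cost_by_category.values())) <= tol


@dataclass
class CEAResult:
    """Pairwise incremental result: intervention minus comparator."""

    intervention: str
    comparator: str
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    classification: str
    wtp: float


def discount_factor(cycle: int, annual_rate: float, cycle_length: int = 1) -> float:
    """Present-value multiplier for a given cycle (cycle 1 undiscounted)."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1, got {cycle}")
    months_elapsed = (cycle - 1) * cycle_length
    return float((1.0 + annual_rate) ** (-months_elapsed / 12.0))


def _phase_masses(dist: CohortDistribution) -> dict[str, float]:
    return dist.phase_mass()


def cycle_cost(dist: CohortDistribution, tally: CycleTally, params: ParamSet,
               drug: str) -> dict[str, float]:
    """Undiscounted cost by category for one cycle.

    Drug acquisition covers the first-line drug only (including after a
    restart back to it); next-line drugs fall under "other OAB drugs".
    Model entry is costed at the first-visit GP rate; later initiations
    (switch, restart, first BTX-A injection) at the follow-up rate.
    Reinjections carry no extra consultation.  Pads are driven solely by
    the incontinence level, in every phase.
    """
    dist.validate()
    c = params.cost
    pm = _phase_masses(dist)
    first_cost = params.drug(drug).monthly_cost
    a_cost = params.drug(params.pathway.next_line_a).monthly_cost
    b_cost = params.drug(params.pathway.next_line_b).monthly_cost

    later_inits = tally.switches + tally.restarts + tally.btxa_injections
    gp = tally.entries * c.gp_first_visit + later_inits * c.gp_followup
    specialist = ((tally.entries + later_inits)
                  * c.specialist_visits_at_initiation * c.specialist_visit)

    incont = dist.symptom_marginal("incontinence")
    pads = sum(incont[k - 1] * c.pads_per_month[k] for k in range(1, dist.n_levels + 1))

    return {
        "drug_acquisition": pm[PHASE_FIRST] * first_cost,
        "other_oab_drugs": pm[PHASE_NEXT_A] * a_cost + pm[PHASE_NEXT_B] * b_cost,
        "gp_visits": gp,
        "specialist_visits": specialist,
        "btxa": (tally.btxa_injections + tally.btxa_reinjections) * c.btxa_injection_cost,
        "pads": pads * c.pad_unit_cost,
    }


def cycle_qaly(dist: CohortDistribution, params: ParamSet) -> float:
    """Undiscounted QALYs accrued over one cycle.

    Each state contributes mass x utility x (cycle length / 12); the AE
    decrement applies to on-treatment mass with an active AE.
    """
    u = params.utility
    L = dist.n_levels
    state_u = np.empty(L * L)
    for s in range(L * L):
        mict, incont = s // L + 1, s % L + 1
        state_u[s] = (u.base_utility
                      + u.coef("micturition", mict, L)
                      + u.coef("incontinence", incont, L))
    total = 0.0
    for p, st in enumerate(PATHWAY_STATES):
        row = dist.mass[p]
        if not row.any():
            continue
        contrib = float(row @ state_u)
        if st.ae and st.phase in ON_PHASES:
            contrib += float(row.sum()) * u.ae_decrement
        total += contrib
    return total * params.settings.cycle_length / 12.0


def accumulate(trace: Trace, params: ParamSet) -> ArmResult:
    """Discount and sum per-cycle costs and QALYs over the horizon.

    With the half-cycle correction enabled, each cycle's occupancy-driven
    quantities are averaged between the cycle's start and end
    distributions; event-driven costs are untouched.
    """
    s = params.settings
    hcc = s.half_cycle_correction
    categories = {k: 0.0 for k in COST_CATEGORIES}
    qalys = 0.0
    n = len(trace.cycles)
    for i, rec in enumerate(trace.cycles):
        df = discount_factor(rec.cycle, s.annual_discount_rate, s.cycle_length)
        end = trace.cycles[i + 1].start if i + 1 < n else trace.final
        costs = cycle_cost(rec.start, rec.tally, params, trace.arm)
        q = cycle_qaly(rec.start, params)
        if hcc and end is not None:
            costs_end = cycle_cost(end, rec.tally, params, trace.arm)
            for k in ("drug_acquisition", "other_oab_drugs", "pads"):
                costs[k] = 0.5 * (costs[k] + costs_end[k])
            q = 0.5 * (q + cycle_qaly(end, params))
        for k, v in costs.items():
            categories[k] += df * v
        qalys += df * q
    return ArmResult(arm=trace.arm, total_cost=sum(categories.values()),
                     total_qalys=qalys, cost_by_category=categories)


def net_monetary_benefit_components(delta_cost: float, delta_qalys: float,
                                    wtp: float) -> float:
    return wtp * delta_qalys - delta_cost


def compare(intervention: ArmResult, comparator: ArmResult,
            wtp: float = 30000.0) -> CEAResult:
    """Incremental cost-effectiveness of intervention versus comparator.

    Classification: *dominant* when strictly cheaper and more effective;
    *dominated* when strictly costlier and less effective; *equivalent*
    when both increments are zero; otherwise cost-effective at the
    willingness-to-pay threshold iff the net monetary benefit
    ``wtp * dQALY - dCost`` is nonnegative.  The ICER is undefined (None)
    when the QALY increment is zero.
    """
    d_cost = intervention.total_cost - comparator.total_cost
    d_qalys = intervention.total_qalys - comparator.total_qalys
    icer = d_cost / d_qalys if d_qalys != 0.0 else None
    if d_cost == 0.0 and d_qalys == 0.0:
        cls = CLASS_EQUIVALENT
    elif d_cost < 0.0 and d_qalys > 0.0:
        cls = CLASS_DOMINANT
    elif d_cost > 0.0 and d_qalys < 0.0:
        cls = CLASS_DOMINATED
    else:
        nmb = net_monetary_benefit_components(d_cost, d_qalys, wtp)
        cls = CLASS_CE if nmb >= 0.0 else CLASS_NOT_CE
    return CEAResult(intervention=intervention.arm, comparator=comparator.arm,
                     incremental_cost=d_cost, incremental_qalys=d_qalys,
                     icer=icer, classification=cls, wtp=wtp)


def net_monetary_benefit(cea: CEAResult, wtp: float | None = None) -> float:
    """NMB = WTP x dQALY - dCost; nonnegative means cost-effective at WTP."""
    w = cea.wtp if wtp is None else wtp
    return net_monetary_benefit_components(cea.incremental_cost,
                                           cea.incremental_qalys, w)
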