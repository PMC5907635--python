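"""Markov cohort state-transition engine.

The cohort distributes probability mass over a finite state space
factored as (pathway state) x (symptom stratum):

* the **pathway state** tracks the treatment phase (first line, next-line
  A, next-line B, off treatment, BTX-A success, BTX-A failed), a capped
  months-on-current-drug counter (1, 2, 3, 4+; months 1-3 select the
  month-indexed symptom matrices and bound the adverse-event onset
  window), the number of failed lines (0, 1, 2; incremented on switching,
  which gates BTX-A eligibility at 2), an active-AE flag, and - while on
  BTX-A - a months-since-injection counter 1-6 driving the 6-monthly
  reinjection decision;
* the **symptom stratum** is the joint (micturition level, incontinence
  level) cell.

Within each 1-month cycle, events resolve in a fixed order: AE onset
(monthly constant-hazard probability of the current drug, possible only
during months 1-3 on that drug and while no AE is active), then
discontinuation (the with-AE probability if an AE is active or just
onset, else the no-AE probability), then - for discontinuers - an
immediate switch to the next oral line versus off-treatment with the
symptom distribution reset to baseline, then BTX-A injection or restart
for patients already off treatment, and finally the symptom-level
transition under the current drug's matrices (next-line therapies borrow
the configured source drug's matrices, tolterodine by default).

Because pathway dynamics are identical across symptom strata (only the
reset-to-baseline couples them), the cycle update factorizes into a small
set of "actions" - hold symptoms, reset symptoms, or apply the (drug,
month) joint transition - each with a pathway-transition matrix.  The
whole cycle is then a handful of dense matrix products over an (82 x L^2)
mass table, and the cohort run is exactly deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import NamedTuple

import numpy as np
import pandas as pd

from .estimation import resolve_ae_prob_3m, three_month_to_monthly_prob
from .parameters import ParamSet
from .transitions import TransitionModel

PHASE_FIRST = "on_first_line"
PHASE_NEXT_A = "on_next_line_a"
PHASE_NEXT_B = "on_next_line_b"
PHASE_OFF = "off_treatment"
PHASE_BTXA_OK = "btxa_success"
PHASE_BTXA_FAIL = "btxa_failed"

ON_PHASES = (PHASE_FIRST, PHASE_NEXT_A, PHASE_NEXT_B)
PHASES = (*ON_PHASES, PHASE_OFF, PHASE_BTXA_OK, PHASE_BTXA_FAIL)

_NEXT_PHASE = {PHASE_FIRST: PHASE_NEXT_A, PHASE_NEXT_A: PHASE_NEXT_B,
               PHASE_NEXT_B: None}

MASS_TOL = 1e-9


class PathwayState(NamedTuple):
    phase: str
    month: int   # 1..4 in on_* phases (4 = "4+"), else 0
    fails: int   # 0..2 ("2" = 2+)
    ae: int      # 0/1, on_* phases only
    tsi: int     # months since BTX-A injection, 1..6 in btxa_success, else 0


def build_pathway_states() -> list[PathwayState]:
    states = []
    for ph in ON_PHASES:
        for month in (1, 2, 3, 4):
            for fails in (0, 1, 2):
                for ae in (0, 1):
                    states.append(PathwayState(ph, month, fails, ae, 0))
    for fails in (0, 1, 2):
        states.append(PathwayState(PHASE_OFF, 0, fails, 0, 0))
    for tsi in range(1, 7):
        states.append(PathwayState(PHASE_BTXA_OK, 0, 2, 0, tsi))
    states.append(PathwayState(PHASE_BTXA_FAIL, 0, 2, 0, 0))
    return states


PATHWAY_STATES = build_pathway_states()
_PS_INDEX = {s: i for i, s in enumerate(PATHWAY_STATES)}
N_PATHWAY = len(PATHWAY_STATES)


def state_index(phase: str, month: int = 0, fails: int = 0, ae: int = 0,
                tsi: int = 0) -> int:
    """Index of a pathway state in the enumeration (KeyError if invalid)."""
    return _PS_INDEX[PathwayState(phase, month, fails, ae, tsi)]


_TALLY_FIELDS = ("dry_mouth_onsets", "constipation_onsets", "discontinuations",
                 "switches", "restarts", "btxa_injections", "btxa_reinjections",
                 "entries")


@dataclass
class CycleTally:
    """Expected per-capita event counts for one cycle."""

    dry_mouth_onsets: float = 0.0
    constipation_onsets: float = 0.0
    discontinuations: float = 0.0
    switches: float = 0.0
    restarts: float = 0.0
    btxa_injections: float = 0.0
    btxa_reinjections: float = 0.0
    entries: float = 0.0  # model entry (cycle 1 only)

    @property
    def treatment_initiations(self) -> float:
        """New-medication initiations this cycle (entry, switch, restart, BTX-A)."""
        return self.entries + self.switches + self.restarts + self.btxa_injections

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        d["treatment_initiations"] = self.treatment_initiations
        return d


class CohortDistribution:
    """Probability mass over (pathway state x symptom stratum)."""

    def __init__(self, mass: np.ndarray, n_levels: int):
        self.mass = np.asarray(mass, dtype=float)
        self.n_levels = int(n_levels)
        if self.mass.shape != (N_PATHWAY, n_levels * n_levels):
            raise ValueError(f"mass must have shape ({N_PATHWAY}, {n_levels**2})")

    def total(self) -> float:
        return float(self.mass.sum())

    def validate(self) -> None:
        if np.any(self.mass < -MASS_TOL):
            raise ValueError("negative probability mass")
        if abs(self.total() - 1.0) > MASS_TOL:
            raise ValueError(f"total mass {self.total():.12f} != 1")

    def phase_mass(self) -> dict[str, float]:
        out = {ph: 0.0 for ph in PHASES}
        row_mass = self.mass.sum(axis=1)
        for st, m in zip(PATHWAY_STATES, row_mass):
            out[st.phase] += float(m)
        return out

    def on_treatment_mass(self) -> float:
        pm = self.phase_mass()
        return sum(pm[ph] for ph in ON_PHASES)

    def symptom_marginal(self, dimension: str) -> np.ndarray:
        L = self.n_levels
        joint = self.mass.sum(axis=0).reshape(L, L)
        return joint.sum(axis=1) if dimension == "micturition" else joint.sum(axis=0)

    def ae_mass(self) -> float:
        row_mass = self.mass.sum(axis=1)
        return float(sum(m for st, m in zip(PATHWAY_STATES, row_mass) if st.ae))

    def expected_failed_lines(self) -> float:
        row_mass = self.mass.sum(axis=1)
        return float(sum(st.fails * m for st, m in zip(PATHWAY_STATES, row_mass)))

    def to_frame(self, threshold: float = 0.0) -> pd.DataFrame:
        L = self.n_levels
        rows = []
        for p, st in enumerate(PATHWAY_STATES):
            for s in range(L * L):
                m = self.mass[p, s]
                if m > threshold:
                    rows.append((st.phase, st.month, st.fails, st.ae, st.tsi,
                                 s // L + 1, s % L + 1, m))
        return pd.DataFrame(rows, columns=["phase", "month", "fails", "ae", "tsi",
                                           "mict_level", "incont_level", "mass"])

    def copy(self) -> "CohortDistribution":
        return CohortDistribution(self.mass.copy(), self.n_levels)


@dataclass
class CycleRecord:
    cycle: int
    start: CohortDistribution   # distribution at the start of the cycle
    tally: CycleTally


@dataclass
class Trace:
    """Per-cycle cohort history for one arm."""

    arm: str
    cycles: list[CycleRecord] = field(default_factory=list)
    final: CohortDistribution | None = None

    def __len__(self) -> int:
        return len(self.cycles)

    def phase_occupancy(self) -> pd.DataFrame:
        rows = []
        for rec in self.cycles:
            rows.append({"cycle": rec.cycle, **rec.start.phase_mass()})
        return pd.DataFrame(rows).set_index("cycle")

    def tally_frame(self) -> pd.DataFrame:
        rows = [{"cycle": rec.cycle, **rec.tally.as_dict()} for rec in self.cycles]
        return pd.DataFrame(rows).set_index("cycle")

    def to_csv(self, state_path: str, tally_path: str,
               threshold: float = 1e-12) -> None:
        frames = []
        for rec in self.cycles:
            df = rec.start.to_frame(threshold)
            df.insert(0, "cycle", rec.cycle)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(state_path, index=False)
        self.tally_frame().to_csv(tally_path)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

# action keys: ("hold",), ("reset",), ("btxa",), ("trans", model_key, month)
_HOLD = ("hold",)
_RESET = ("reset",)
_BTXA = ("btxa",)


class CohortEngine:
    """Precompiled cycle operator for one treatment arm.

    Parameters
    ----------
    params : ParamSet
    drug : str
        First-line drug of the arm.
    models : dict, optional
        Transition models by drug name; must cover the arm drug and the
        pathway's next-line transition source.  Defaults to
        ``params.transition_models``.
    """

    def __init__(self, params: ParamSet, drug: str,
                 models: dict[str, TransitionModel] | None = None):
        params.drug(drug)  # raises for unknown drug
        self.params = params
        self.arm_drug = drug
        models = models if models is not None else params.transition_models
        pw = params.pathway
        source = pw.next_line_transition_source
        for needed in (drug, source):
            if needed not in models:
                raise KeyError(
                    f"no transition model for '{needed}'; fit or calibrate it first")
        self._models = {"first": models[drug], "next": models[source]}
        self.L = params.n_levels
        self._baseline_flat = params.settings.baseline_distribution.reshape(-1)
        btxa_dist = params.settings.btxa_symptom_distribution
        self._btxa_flat = (btxa_dist.reshape(-1) if btxa_dist is not None else None)

        self._phase_drug = {
            PHASE_FIRST: params.drug(drug),
            PHASE_NEXT_A: params.drug(pw.next_line_a),
            PHASE_NEXT_B: params.drug(pw.next_line_b),
        }
        self._phase_model_key = {PHASE_FIRST: "first",
                                 PHASE_NEXT_A: "next", PHASE_NEXT_B: "next"}
        self._compile()

    # -- per-phase probabilities ---------------------------------------
    def _monthly_ae(self, phase: str) -> dict[str, float]:
        d = self._phase_drug[phase]
        ref = self.params.reference
        return {ae: three_month_to_monthly_prob(resolve_ae_prob_3m(d, ref, ae))
                for ae in ("dry_mouth", "constipation")}

    def _disc_probs(self, phase: str) -> tuple[float, float]:
        d = self._phase_drug[phase]
        pw = self.params.pathway
        q_no_ae = (d.discontinuation_monthly_no_ae
                   if d.discontinuation_monthly_no_ae is not None
                   else pw.p_discontinue_no_ae)
        q_ae = (d.discontinuation_monthly_ae
                if d.discontinuation_monthly_ae is not None
                else pw.p_discontinue_ae)
        return q_no_ae, q_ae

    # -- compilation ----------------------------------------------------
    def _branches(self, st: PathwayState) -> list[tuple[float, PathwayState, tuple, dict]]:
        pw = self.params.pathway
        out = []
        if st.phase in ON_PHASES:
            model_key = self._phase_model_key[st.phase]
            ae_p = self._monthly_ae(st.phase)
            q_no_ae, q_ae = self._disc_probs(st.phase)
            in_window = st.month <= 3 and st.ae == 0
            pdm = ae_p["dry_mouth"] if in_window else 0.0
            pc = ae_p["constipation"] if in_window else 0.0
            p_any = 1.0 - (1.0 - pdm) * (1.0 - pc)
            if st.ae == 1:
                subs = [(1.0, q_ae, 1)]
            else:
                subs = [(1.0 - p_any, q_no_ae, 0), (p_any, q_ae, 1)]
            next_ph = _NEXT_PHASE[st.phase]
            p_switch = pw.p_switch_after_discontinuation if next_ph else 0.0
            for w, q, ae_next in subs:
                if w == 0.0:
                    continue
                if q > 0.0:
                    if p_switch > 0.0:
                        dest = PathwayState(next_ph, 2, min(st.fails + 1, 2), 0, 0)
                        act = ("trans", self._phase_model_key[next_ph], 1)
                        out.append((w * q * p_switch, dest, act,
                                    {"discontinuations": 1.0, "switches": 1.0}))
                    if p_switch < 1.0:
                        dest = PathwayState(PHASE_OFF, 0, st.fails, 0, 0)
                        out.append((w * q * (1.0 - p_switch), dest, _RESET,
                                    {"discontinuations": 1.0}))
                if q < 1.0:
                    dest = PathwayState(st.phase, min(st.month + 1, 4),
                                        st.fails, ae_next, 0)
                    act = ("trans", model_key, min(st.month, 3))
                    out.append((w * (1.0 - q), dest, act, {}))
        elif st.phase == PHASE_OFF:
            if st.fails >= 2:
                pb = pw.p_btxa_monthly
                if pb > 0.0:
                    dest = PathwayState(PHASE_BTXA_OK, 0, 2, 0, 1)
                    out.append((pb, dest, _BTXA, {"btxa_injections": 1.0}))
                if pb < 1.0:
                    out.append((1.0 - pb, st, _HOLD, {}))
            else:
                pr = pw.p_restart_monthly
                prev_phase = ON_PHASES[st.fails]
                targets = (prev_phase, PHASE_NEXT_A, PHASE_NEXT_B)
                if pr > 0.0:
                    for target, share in zip(targets, pw.restart_split):
                        if share == 0.0:
                            continue
                        dest = PathwayState(target, 2, st.fails, 0, 0)
                        act = ("trans", self._phase_model_key[target], 1)
                        out.append((pr * share, dest, act, {"restarts": 1.0}))
                if pr < 1.0:
                    out.append((1.0 - pr, st, _HOLD, {}))
        elif st.phase == PHASE_BTXA_OK:
            if st.tsi < 6:
                dest = PathwayState(PHASE_BTXA_OK, 0, 2, 0, st.tsi + 1)
                out.append((1.0, dest, _HOLD, {}))
            else:
                p_re = pw.p_btxa_reinjection_6m
                if p_re > 0.0:
                    dest = PathwayState(PHASE_BTXA_OK, 0, 2, 0, 1)
                    out.append((p_re, dest, _HOLD, {"btxa_reinjections": 1.0}))
                if p_re < 1.0:
                    dest = PathwayState(PHASE_BTXA_FAIL, 0, 2, 0, 0)
                    out.append((1.0 - p_re, dest, _HOLD, {}))
        else:  # btxa_failed: absorbing, no further treatment
            out.append((1.0, st, _HOLD, {}))
        return out

    def _compile(self) -> None:
        actions: dict[tuple, np.ndarray] = {}
        tallies = {f: np.zeros(N_PATHWAY) for f in _TALLY_FIELDS}
        for p, st in enumerate(PATHWAY_STATES):
            branches = self._branches(st)
            total = sum(b[0] for b in branches)
            if abs(total - 1.0) > 1e-12:
                raise AssertionError(
                    f"branch probabilities for {st} sum to {total}")
            for prob, dest, act, events in branches:
                mat = actions.setdefault(act, np.zeros((N_PATHWAY, N_PATHWAY)))
                mat[p, _PS_INDEX[dest]] += prob
                for ev, count in events.items():
                    tallies[ev][p] += prob * count
            if st.phase in ON_PHASES and st.month <= 3 and st.ae == 0:
                ae_p = self._monthly_ae(st.phase)
                tallies["dry_mouth_onsets"][p] = ae_p["dry_mouth"]
                tallies["constipation_onsets"][p] = ae_p["constipation"]
        # precompute the joint symptom operators per (model, month)
        self._trans_ops: dict[tuple, np.ndarray] = {}
        for act in actions:
            if act[0] == "trans":
                _, key, month = act
                tm = self._models[key]
                self._trans_ops[act] = np.kron(tm.matrix("micturition", month),
                                               tm.matrix("incontinence", month))
        self._actions = actions
        self._tally_vectors = tallies

    # -- stepping -------------------------------------------------------
    @property
    def n_cycles(self) -> int:
        return self.params.settings.n_cycles

    def initial_distribution(self) -> CohortDistribution:
        mass = np.zeros((N_PATHWAY, self.L * self.L))
        start = PathwayState(PHASE_FIRST, 1, 0, 0, 0)
        mass[_PS_INDEX[start]] = self._baseline_flat
        return CohortDistribution(mass, self.L)

    def step(self, dist: CohortDistribution, cycle: int,
             ) -> tuple[CohortDistribution, CycleTally]:
        if not 1 <= cycle <= self.n_cycles:
            raise ValueError(f"cycle {cycle} outside 1..{self.n_cycles}")
        M = dist.mass
        row_mass = M.sum(axis=1)
        tally = CycleTally(**{f: float(self._tally_vectors[f] @ row_mass)
                              for f in _TALLY_FIELDS})
        out = np.zeros_like(M)
        for act, A in self._actions.items():
            if act == _HOLD:
                out += A.T @ M
            elif act == _RESET:
                out += np.outer(A.T @ row_mass, self._baseline_flat)
            elif act == _BTXA:
                target = (self._btxa_flat if self._btxa_flat is not None
                          else None)
                if target is None:
                    out += A.T @ M  # hold: BTX-A keeps the current distribution
                else:
                    out += np.outer(A.T @ row_mass, target)
            else:
                out += A.T @ M @ self._trans_ops[act]
        new = CohortDistribution(out, self.L)
        if abs(new.total() - dist.total()) > MASS_TOL:
            raise AssertionError(
                f"mass not conserved in cycle {cycle}: {new.total():.12f}")
        return new, tally

    def run(self) -> Trace:
        trace = Trace(arm=self.arm_drug)
        dist = self.initial_distribution()
        for cycle in range(1, self.n_cycles + 1):
            new, tally = self.step(dist, cycle)
            if cycle == 1:
                tally.entries = dist.total()
            trace.cycles.append(CycleRecord(cycle, dist, tally))
            dist = new
        trace.final = dist
        return trace


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def build_initial_distribution(params: ParamSet, drug: str) -> CohortDistribution:
    """All mass on first-line month 1, no failures, no AE, baseline symptoms."""
    params.drug(drug)  # raises for unknown drug
    L = params.n_levels
    mass = np.zeros((N_PATHWAY, L * L))
    mass[state_index(PHASE_FIRST, month=1)] = \
        params.settings.baseline_distribution.reshape(-1)
    return CohortDistribution(mass, L)


def step_cycle(dist: CohortDistribution, cycle: int, params: ParamSet,
               drug: str, models: dict[str, TransitionModel] | None = None,
               ) -> tuple[CohortDistribution, CycleTally]:
    """One cycle of the cohort model (convenience wrapper; recompiles the arm)."""
    return CohortEngine(params, drug, models).step(dist, cycle)


def run_cohort(params: ParamSet, drug: str,
               models: dict[str, TransitionModel] | None = None) -> Trace:
    """Deterministic cohort trace over the full horizon for one arm."""
    return CohortEngine(params, drug, models).run()
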