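"""Independent individual-level microsimulation oracle.

Re-implements the treatment-pathway and symptom rules walker by walker
with explicit random draws, sharing nothing with the cohort engine except
the parameter objects.  Used to cross-check the deterministic cohort
distribution against Monte-Carlo frequencies.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

PH_FIRST, PH_A, PH_B, PH_OFF, PH_BTXA, PH_FAIL = range(6)
PHASE_NAMES = ["on_first_line", "on_next_line_a", "on_next_line_b",
               "off_treatment", "btxa_success", "btxa_failed"]


def _monthly(p3m: float) -> float:
    return 1.0 - (1.0 - p3m) ** (1.0 / 3.0)


def _step_levels(levels: np.ndarray, matrix: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(matrix, axis=1)
    u = rng.random(len(levels))
    return 1 + (u[:, None] > cum[levels - 1]).sum(axis=1)


def microsimulate(params, drug: str, models: dict, n_walkers: int,
                  seed: int) -> pd.DataFrame:
    """Start-of-cycle phase occupancy fractions, cycles 1..horizon."""
    rng = np.random.default_rng(seed)
    pw = params.pathway
    L = params.n_levels
    n_cycles = params.settings.n_cycles

    phase_drugs = {PH_FIRST: params.drug(drug),
                   PH_A: params.drug(pw.next_line_a),
                   PH_B: params.drug(pw.next_line_b)}
    phase_models = {PH_FIRST: models[drug],
                    PH_A: models[pw.next_line_transition_source],
                    PH_B: models[pw.next_line_transition_source]}
    ref = params.reference

    def ae_probs(ph):
        d = phase_drugs[ph]
        out = {}
        for ae in ("dry_mouth", "constipation"):
            if ae in d.ae_prob_3m:
                p3 = d.ae_prob_3m[ae]
            else:
                o = d.ae_odds_ratio[ae] * ref.ae_prob_3m[ae] / (1 - ref.ae_prob_3m[ae])
                p3 = o / (1 + o)
            out[ae] = _monthly(p3)
        return out

    def disc_probs(ph):
        d = phase_drugs[ph]
        q0 = (d.discontinuation_monthly_no_ae
              if d.discontinuation_monthly_no_ae is not None
              else pw.p_discontinue_no_ae)
        qa = (d.discontinuation_monthly_ae
              if d.discontinuation_monthly_ae is not None
              else pw.p_discontinue_ae)
        return q0, qa

    # initial population: first line, month 1, baseline symptoms
    base = params.settings.baseline_distribution.reshape(-1)
    strata = rng.choice(L * L, size=n_walkers, p=base)
    mict = strata // L + 1
    incont = strata % L + 1
    phase = np.full(n_walkers, PH_FIRST)
    month = np.ones(n_walkers, dtype=int)
    fails = np.zeros(n_walkers, dtype=int)
    ae = np.zeros(n_walkers, dtype=bool)
    tsi = np.zeros(n_walkers, dtype=int)

    records = []
    for cycle in range(1, n_cycles + 1):
        counts = np.bincount(phase, minlength=6) / n_walkers
        records.append({"cycle": cycle,
                        **{PHASE_NAMES[i]: counts[i] for i in range(6)}})
        snap_phase = phase.copy()
        snap_month = month.copy()
        snap_fails = fails.copy()
        snap_tsi = tsi.copy()

        for ph in (PH_FIRST, PH_A, PH_B):
            idx = np.flatnonzero(snap_phase == ph)
            if idx.size == 0:
                continue
            pm = ae_probs(ph)
            q0, qa = disc_probs(ph)
            m = snap_month[idx]
            in_window = (m <= 3) & ~ae[idx]
            onset = in_window & ((rng.random(idx.size) < pm["dry_mouth"])
                                 | (rng.random(idx.size) < pm["constipation"]))
            ae_now = ae[idx] | onset
            disc = rng.random(idx.size) < np.where(ae_now, qa, q0)
            has_next = ph != PH_B
            switch = disc & has_next & (rng.random(idx.size) < pw.p_switch_after_discontinuation)
            to_off = disc & ~switch
            stay = ~disc

            sidx = idx[stay]
            if sidx.size:
                tm = phase_models[ph]
                mm = np.minimum(snap_month[sidx], 3)
                for mo in np.unique(mm):
                    sub = sidx[mm == mo]
                    mict[sub] = _step_levels(mict[sub], tm.matrix("micturition", mo), rng)
                    incont[sub] = _step_levels(incont[sub], tm.matrix("incontinence", mo), rng)
                month[sidx] = np.minimum(snap_month[sidx] + 1, 4)
                ae[sidx] = ae_now[stay]

            widx = idx[switch]
            if widx.size:
                nxt = PH_A if ph == PH_FIRST else PH_B
                tm = phase_models[nxt]
                mict[widx] = _step_levels(mict[widx], tm.matrix("micturition", 1), rng)
                incont[widx] = _step_levels(incont[widx], tm.matrix("incontinence", 1), rng)
                phase[widx] = nxt
                month[widx] = 2
                fails[widx] = np.minimum(snap_fails[widx] + 1, 2)
                ae[widx] = False

            oidx = idx[to_off]
            if oidx.size:
                phase[oidx] = PH_OFF
                month[oidx] = 0
                ae[oidx] = False
                s = rng.choice(L * L, size=oidx.size, p=base)
                mict[oidx] = s // L + 1
                incont[oidx] = s % L + 1

        off_idx = np.flatnonzero(snap_phase == PH_OFF)
        if off_idx.size:
            eligible = off_idx[snap_fails[off_idx] >= 2]
            if eligible.size:
                inject = eligible[rng.random(eligible.size) < pw.p_btxa_monthly]
                phase[inject] = PH_BTXA
                tsi[inject] = 1
            rest_pool = off_idx[snap_fails[off_idx] < 2]
            if rest_pool.size:
                restart = rest_pool[rng.random(rest_pool.size) < pw.p_restart_monthly]
                if restart.size:
                    split = np.asarray(pw.restart_split)
                    pick = rng.choice(3, size=restart.size, p=split / split.sum())
                    prev = np.array([PH_FIRST, PH_A, PH_B])[snap_fails[restart]]
                    target = np.where(pick == 0, prev, np.where(pick == 1, PH_A, PH_B))
                    for ph in (PH_FIRST, PH_A, PH_B):
                        sub = restart[target == ph]
                        if sub.size:
                            tm = phase_models[ph]
                            mict[sub] = _step_levels(mict[sub], tm.matrix("micturition", 1), rng)
                            incont[sub] = _step_levels(incont[sub], tm.matrix("incontinence", 1), rng)
                            phase[sub] = ph
                            month[sub] = 2

        btxa_idx = np.flatnonzero(snap_phase == PH_BTXA)
        if btxa_idx.size:
            young = btxa_idx[snap_tsi[btxa_idx] < 6]
            tsi[young] += 1
            due = btxa_idx[snap_tsi[btxa_idx] == 6]
            if due.size:
                re = rng.random(due.size) < pw.p_btxa_reinjection_6m
                tsi[due[re]] = 1
                phase[due[~re]] = PH_FAIL
                tsi[due[~re]] = 0

    return pd.DataFrame(records).set_index("cycle")
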