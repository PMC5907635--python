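# oabcea

Markov cohort cost-utility model of oral antimuscarinic treatment for
overactive bladder (OAB), from a UK NHS perspective.

OAB — urinary urgency with frequency, with or without incontinence — is a
chronic condition usually managed with oral antimuscarinics (solifenacin,
tolterodine, fesoterodine, oxybutynin, trospium). The drugs differ modestly
in efficacy, markedly in adverse-event (dry mouth, constipation) rates and
in acquisition cost, so the economically relevant comparison is a long-run
one: which first-line choice minimises cost per quality-adjusted life year
(QALY) once discontinuation, switching, restart and late-line botulinum
toxin A (BTX-A) are accounted for? This package is for health-economics
analysts who want that comparison as a tested, scriptable pipeline rather
than a spreadsheet.

## The model

A cohort state-transition model with 1-month cycles over a 5-year horizon.
The state is

- symptom severity: 5 levels each for daily micturition frequency and
  incontinence episodes (joint 5×5 strata);
- treatment phase: first line → next-line A → next-line B → off treatment,
  with BTX-A available after ≥2 failed oral lines;
- months on the current drug (capped), failed-line count, active-AE flag.

Per cycle, in order: AE onset (constant-hazard monthly probability from
3-month trial rates, possible only in the first 3 months on a drug),
discontinuation (90%/cycle with an active AE, 6.8% without), immediate
switch (26.1%) versus off-treatment with symptom reversion to baseline,
restart (5.6%/month, split between previous drug and the two next lines)
or BTX-A (0.1%/month, 6-monthly reinjection with probability 70%), then
the symptom-level transition under the current drug's monthly matrices.

Transition matrices for the reference drug (solifenacin 5 mg) come from a
multinomial regression on patient-level trial records; each comparator's
matrices are **calibrated**: a scalar latent shift δ on the cumulative-logit
scale of each row is solved (bracketed root search) so that the model's
predicted month-3 change in daily symptom counts reproduces the network-
meta-analysis (NMA) mean difference for that drug. Health-state utilities
are an OLS regression of the EQ-5D index on severity-level indicators
(worst level as reference) with an additive AE decrement (−0.0357). Costs
(drug acquisition, GP/specialist visits, incontinence pads by severity
level, BTX-A at £1,151.98 per injection) and QALYs are discounted at 3.5%
per year and compared as

    ICER = ΔC / ΔQ,   NMB(w) = w·ΔQ − ΔC

with dominance classification and a £30,000/QALY willingness-to-pay
threshold. One-way (tornado), probabilistic (1,000-draw, beta/normal/
lognormal/gamma by parameter class, CEAC) and observational-discontinuation
scenario analyses are built in.

The published supplementary inputs (trial transition probabilities,
baseline severity strata, NMA estimates) are not publicly deposited; the
`synthetic` module generates documented stand-ins with the statistical
structure the pipeline assumes, so every stage is testable end to end.
See `docs/methods.md` for what the stand-ins do and do not emulate.

## Worked example

```python
from oabcea import CostUtilityModel

model = CostUtilityModel.from_synthetic(comparator="tolterodine_er_4mg", seed=1)
res = model.fit()
print(res.summary())
```

```
Cost-utility analysis (discounted, per patient)
================================================================
                        solifenacin_5mg  tolterodine_er_4mg
Drug acquisition                 418.36              425.60
Other OAB drug(s)                257.06              255.50
GP visits                        115.32              115.05
Specialist visits                269.18              268.24
Botulinum toxin                    5.15                5.09
Incontinence pads                301.21              304.16
Total costs                    1,366.28            1,373.63
Total QALYs                      3.6024              3.6002
----------------------------------------------------------------
Incremental cost (GBP):   -7.36
Incremental QALYs:        0.0022
ICER (GBP/QALY):          -3,293
Classification at WTP 30,000: dominant
Net monetary benefit:     74.36
```

Solifenacin 5 mg/day accrues £7.36 less cost and 0.0022 more QALYs per
patient over 5 years than tolterodine ER 4 mg/day under the synthetic
stand-in inputs — cheaper and more effective, i.e. *dominant* (the ICER is
not meaningful for a dominant strategy; the positive net monetary benefit
is). Sensitivity analyses hang off the same object:

```python
tornado = model.one_way()                 # ΔC/ΔQ at each parameter bound
psa = model.psa(n_iter=1000, seed=7)      # probabilistic draws
psa.prob_cost_effective(30000)            # e.g. 0.809
```

The same pipeline is scriptable from the shell:

```sh
oabcea synth --seed 1 --out-dir out/          # synthetic trial + NMA stand-ins
oabcea run --comparator tolterodine_er_4mg --out-dir out/
oabcea psa --comparator tolterodine_er_4mg --n-iter 1000 --seed 7 --out-dir out/
```

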