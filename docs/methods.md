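# Methods

## Model structure

The cohort evolves over a finite state space factored as (pathway state) ×
(symptom stratum). Symptom severity has two dimensions — daily micturition
frequency and daily incontinence episodes — each on 5 ordinal levels
(level 1 best, level 5 worst); the joint stratum is their product. The
pathway state records the treatment phase (`on_first_line`,
`on_next_line_a`, `on_next_line_b`, `off_treatment`, `btxa_success`,
`btxa_failed`), a months-on-current-drug counter capped at 4+ (months 1–3
select the month-indexed transition matrices and bound the adverse-event
onset window; 4+ is absorbing), the number of failed lines capped at 2
(incremented on switching; 2 gates BTX-A eligibility), an active-AE flag,
and — in `btxa_success` — a months-since-injection counter 1–6. This gives
82 pathway states × 25 strata = 2,050 states; the cohort run is fully
deterministic.

Because the pathway dynamics are identical across symptom strata except
for the reset to baseline on entering `off_treatment`, the cycle update
factorizes into at most eight linear "actions" (hold symptoms, reset to
baseline, reset to a configurable BTX-A distribution, or apply one of the
(drug, month) joint symptom operators). Each action carries an 82×82
pathway-transition matrix compiled once per arm, so one cycle is a handful
of dense matrix products. An independent walker-level microsimulation in
the test suite reproduces the cohort phase occupancies within Monte-Carlo
error on a reduced (2-level, 12-cycle) configuration.

### Within-cycle event order

The source material does not specify an ordering; the implementation fixes
AE onset → discontinuation → switch/off → BTX-A/restart → symptom
transition. This makes AE-driven discontinuation act in the AE's own
cycle, which is the natural reading of a 90% "discontinuation with
adverse events" probability listed beside monthly probabilities. AEs can
onset only during the first 3 months on a drug (the published
probabilities are 3-month probabilities and antimuscarinic AEs onset
early); the flag persists until discontinuation and re-arms on each new
line. The two AE types (dry mouth, constipation) act as independent
monthly risks; either one sets the flag.

### Pathway conventions

* 3-month AE probabilities are converted to monthly ones by the
  constant-hazard formula `1 − (1 − p)^(1/3)`; composing three monthly
  risks reproduces the 3-month probability exactly.
* Switching follows the fixed order first line → next-line A → next-line
  B. From next-line B no further oral line exists, so all
  discontinuation from B flows off treatment. The failed-line counter
  increments only on switches; since the order is fixed, the counter of an
  off-treatment patient identifies their most recent line, which serves as
  the "previous treatment" restart target. Restarts split one third each
  to the previous drug and the two next lines, re-enter month-1 dynamics,
  and do not increment the counter.
* Off-treatment patients with ≥2 failed lines await BTX-A only (monthly
  probability 0.001) and do not restart; with <2 failed lines they restart
  (monthly 0.056) and cannot receive BTX-A.
* All BTX-A recipients count as successes until the 6-month reinjection
  decision: with probability 0.70 they are reinjected (counter restarts),
  otherwise they move to `btxa_failed` and receive no further treatment.
  BTX-A states hold the symptom distribution they entered with (baseline,
  since entry is from off treatment); a different BTX-A symptom
  distribution can be configured.
* Symptom severity reverts to the baseline distribution immediately on
  entering off treatment.
* Patients who switch or restart in a cycle undergo that cycle's symptom
  transition under the new drug's month-1 matrix and enter the next cycle
  with the month counter at 2.
* No background mortality (none in the modelled population over 5 years)
  and no half-cycle correction in the base case; a half-cycle option
  averages occupancy-driven costs and QALYs between cycle start and end.

## Estimation

**Transition regression.** Monthly matrices
P(level_m = j | level_{m−1} = i), months 1–3, are estimated from
patient-level records. The default specification is saturated in the
origin level, whose MLE is the observed destination frequencies per origin
row (origin rows with no observations receive a flagged identity row); a
multinomial-logit fit is available and coincides with the frequencies at
the optimum, which the tests use as a cross-check. Matrices after month 3
reuse the month-3 matrix: the treatment effect observed at 3 months is
assumed sustained.

**Utility regression.** OLS of the EQ-5D index on severity-level
indicators (worst level as reference in both dimensions) plus sex, age and
country. Coefficients are utility increments over the worst state; the
base utility is the prediction at the worst state with covariates at their
sample distribution. Rank-deficient designs raise an error naming the
offending terms.

**Calibration.** Comparator transition matrices are unobserved. Each
comparator is characterised by its NMA mean difference in the month-3
change of daily symptom counts versus the reference drug (positive = less
improvement), applied independently per symptom dimension. The reference
matrices are shifted by a scalar δ on the cumulative-logit (proportional-
odds) scale of each row — a one-parameter monotone family that keeps rows
stochastic and preserves structural zeros — applied uniformly to months
1–3. δ solves, by bracketed root search (`brentq`, deterministic), for the
calibrated model's predicted month-3 cumulative change equalling the
reference change plus the NMA difference, where predicted change pushes
the baseline marginal through M1·M2·M3 and values levels at configured
episode/day midpoints. Targets unreachable within δ ∈ [−8, 8] return the
closer bound with a warning. Next-line therapies use the tolterodine ER
4 mg transition model.

## Economics

Six cost categories: first-line drug acquisition (also after a restart
back to it), other OAB drugs (next-line acquisitions), GP visits (first
visit £65.00 at model entry; follow-up £27.00 per later initiation —
switch, restart, first BTX-A injection), specialist visits (£94.00 per
initiation; 1 visit by default, 1.5 configurable since the two published
statements conflict), BTX-A (£1,151.98 per injection and reinjection; no
extra consultation for reinjections), and incontinence pads (monthly count
by incontinence level × £0.17, in every phase — pads track symptoms, not
therapy). Utilities: base + level coefficients + AE decrement (−0.0357,
on-treatment with active AE only); QALYs accrue at utility × 1/12 per
cycle. Costs and QALYs are valued on the start-of-cycle distribution,
discounted at 3.5%/year with monthly compounding (cycle 1 undiscounted)
and summed over 60 cycles. Comparison yields ΔC, ΔQ, the ICER when
ΔQ ≠ 0, and a classification (dominant / dominated / equivalent /
cost-effective or not at the WTP via the net-monetary-benefit sign).

## Sensitivity analyses

*One-way:* each parameter (addressed by dotted path) is set to each bound
of its configured interval; all derived quantities are rebuilt —
comparator calibration included — and both arms rerun. *Probabilistic:*
families by parameter class — beta for probabilities (method of moments;
uniform-on-interval fallback when the implied variance is infeasible,
logged), normal for utility coefficients and NMA mean differences,
lognormal for odds ratios, gamma for resource counts; interval widths are
read as 95% CIs (SE = width/3.92); draws are independent (no correlation
structure is reported) and bit-reproducible per seed. *Scenario:*
observational per-drug discontinuation rates replace both the AE and
no-AE probabilities (observational sources cannot separate them).

## Synthetic stand-ins

The patient-level trial data, baseline severity strata, reference
transition matrices, NMA estimates and the utility-regression intercept
are not publicly available. The generator substitutes:

* **Baseline strata**: independent truncated-geometric marginals over
  levels 1–5 (ratio 0.7 per dimension) — monotonically decreasing
  occupancy with worsening severity.
* **Severity midpoints** (level ↔ episodes/day bridge, required by the
  calibration): micturition {6, 9, 11, 13, 16} voids/day, incontinence
  {0, 0.5, 1.5, 3, 6} episodes/day; config-overridable.
* **Reference transition matrices**: discretized-normal rows centred on
  origin − drift, with drift 0.9/0.45/0.2 (micturition) and 0.8/0.4/0.15
  (incontinence) over months 1–3 — early improvement that tapers.
* **NMA mean differences**: small effects (−0.08 to +0.18 micturitions/
  day; −0.03 to +0.06 incontinence episodes/day) with the higher-dose
  drugs more effective but more toxic, and stand-in interval half-widths
  (0.30 / 0.12).
* **EQ-5D generation**: truth linear predictor + Gaussian noise (SD 0.1)
  truncated to the UK tariff range [−0.594, 1]. The synthetic base
  utility is 0.70, chosen so that tariff-ceiling censoring is negligible
  (< 5% of draws in the best strata) and the implied 5-year QALY totals
  sit in the published range; with a higher base, censoring would bias
  the OLS recovery that the test suite checks.
* **Level-4 utility coefficients**: the published base-case table omits
  them (only sensitivity ranges are printed); the default uses the
  midpoint of the printed range (0.0210 micturition, 0.02485
  incontinence), flagged here and user-overridable.

Passing tests therefore demonstrate that the pipeline's statistical
machinery (generation → regression → calibration → simulation →
economics) is self-consistent and recovers known truths; they do not
certify the published arm totals, which depend on the unavailable inputs.
The worked-example tests instead verify the economics layer against the
published totals and increments directly. Note the published increments
for oxybutynin ER (−£5) and solifenacin 10 mg (−£46) differ by £1 from
the rounded totals (1733 − 1737 = −4; 1733 − 1778 = −45), an artefact of
independent rounding; the four arithmetically consistent headline
comparators are asserted exactly.

## Numerical choices

* Row-stochasticity and cohort mass conservation enforced at 1e−9.
* Cumulative probabilities of 0 or 1 are fixed points of the calibration
  shift (structural zeros stay zero).
* `brentq` with xtol 1e−12 for calibration; recovery of a known shift is
  tested to 1e−3.
* Currency inputs are 2-dp decimals; all arithmetic is double precision;
  reports round to £0.01 (tables) or £1 (summaries).
* Problem sizes in the test suite: recovery tests use 2,000 patients × 10
  seeds; the cohort–microsimulation cross-check uses 10,000 walkers on
  the 2-level, 12-cycle configuration; PSA property tests use 1,000
  iterations of that reduced configuration.

## Known limitations

* The calibration family (single δ per drug–dimension, uniform across
  months 1–3) is an identification choice; the original calibration is
  under-specified and may have differed.
* NMA mean differences are applied independently per symptom dimension;
  any correlation between micturition and incontinence effects is
  ignored.
* No adherence/wastage, no mortality, no urgency or nocturia dimensions,
  no societal costs.
* PSA draws are independent across parameters; no probabilistic
  correlation structure.
* Synthetic stand-ins are labelled as such throughout; conclusions about
  real comparative cost-effectiveness require the original supplementary
  inputs.
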