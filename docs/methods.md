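# Methods

## Model structure

The model is a two-period decision tree for bed-bound post-stroke
inpatients, evaluated separately for ischemic and hemorrhagic cohorts
because their baseline mortality differs. Two strategies are compared: the
VACOM soft robotic sock and IPC plus manual ankle movement. The horizon is
1 year, the perspective is the healthcare system, costs are 2019 S$, and no
discounting is applied (a discount rate would be a no-op at this horizon;
the timing machinery deliberately leaves room for one).

**Inpatient period (month 1).** Chance nodes in order: DVT; PE conditional
on DVT (PE is modelled as a DVT sequela, so the tree supplies
P(PE | DVT) and a pathway cannot carry PE without DVT); inpatient death.
Inpatient mortality is a single cohort-level probability by default; the
parameter table may override it per inpatient state
(`prob_death_inpatient_dnp`, `prob_death_inpatient_dp`) when evidence
distinguishes them. Deaths occur on day 15 of the stay: such pathways
accrue 15/365 of a year at the inpatient-state utility and half of the
1-month stay cost (the day-by-day accrual of a 30-day month).

**Post-discharge period (months 2–12).** Survivors face one chance node
with mutually exclusive outcomes — recurrent stroke, recurrent DVT,
recurrent PE, ankle contracture, death — all occurring at the start of
month 7, with a residual "well" branch taking the leftover probability.
Months 2–6 are always lived in the post-discharge well state; months 7–12
in the outcome state (none for death). This enumeration yields 21 leaves;
their probabilities sum to 1 by construction and the evaluator enforces it
to 1e−12.

**Intervention effect.** Strategy-modified probabilities are flagged in the
parameter table (`strategy_rr` column): by default the inpatient DVT risk
(via `rr_dvt_vac_ipc`) and the ankle-contracture risk (via
`rr_ankcon_vac`). Compliance enters as a cohort-level mixture,
RR_eff = c·RR + (1 − c), which in this linear model has the same
expectation as patient-level binary compliance; non-compliant VACOM
patients still incur the price premium (the conservative choice against the
intervention, since no refund rule is specified). Modified probabilities
are clipped to [0, 1]; when a (rare, harmful-tail) RR draw would push the
post-discharge node's sum above 1, the modified branches are saturated at
the probability mass the unmodified branches leave free — the multi-branch
analogue of the min(1, p·RR) clip. Baseline probabilities whose sum already
exceeds 1 are rejected as an invalid parameter set.

**QALY accounting.** Months are 1/12 of a year for QALY weights; only the
day-15 rule uses calendar days over 365, so a full-health year sums to
exactly 1. Utilities combine multiplicatively
(u_state = u_stroke · u_comorbidity · …), never exceeding any factor. The
parameter table can instead supply whole-pathway QALY values under the
`qaly_<inpatient>_1_12m_<outcome>` / `qaly_<inpatient>_1m_death` naming
convention (inpatient codes ndnp/dnp/dp); when present they are passed
through unchanged, and the synthetic generator computes them from its drawn
state utilities with the decomposed rule so the two modes agree at base
case (a tested round trip).

**Microsimulation oracle.** `microsimulate` draws individual patients
through the same chance nodes (staged Bernoulli/categorical draws) and is
used purely as an independent check on the exact enumeration; agreement is
asserted within Monte-Carlo standard error throughout the suite.

## Parameters and uncertainty

One CSV row per parameter: name, cohort (`ischemic`/`hemorrhagic`/`both`,
specific rows overriding `both`), role, base value, PSA distribution, DSA
range, and the optional `strategy_rr` flag. PSA families follow standard
health-economic convention by role — beta for probabilities, utilities and
whole-pathway QALYs; gamma for costs; lognormal for relative risks — fitted
by the method of moments from a supplied standard error. A row that omits
uncertainty entirely gets a default SE of 20 % of its base value; a missing
DSA range defaults to the central 95 % interval of the fitted distribution.
Rows declared `fixed` stay fixed everywhere, including under scenario
overrides. Both arms are evaluated on the same draws (common random
numbers), which reduces CEAC and VOI Monte-Carlo variance; sampling is
reproducible under a seed with a fixed column order.

Scenarios fix the effectiveness assumption and pricing: optimistic
(RR of ankle contracture for VACOM = 0.3) and conservative (0.9), premiums
S$150 (revised) and S$300 (original), threshold S$75,000/QALY, plus a
S$1,000-premium optimistic scenario used for VOI. Applying a scenario
overrides the `rr_ankcon_vac` base value and refits its distribution and
DSA range around the scenario value, preserving the row's relative SE.

## Analyses

* **Incremental statistics.** ΔC, ΔE, ICER (undefined at ΔE = 0),
  NMB = λ·ΔE − ΔC. Dominance is quadrant-aware: strictly cheaper and no
  less effective is cost-saving dominant; strictly costlier and no more
  effective is dominated; in the remaining quadrants (including the
  sign-ambiguous southwest) the NMB sign decides, with ties counted
  against the intervention.
* **CEAC.** Fraction of draws with λ·ΔE − ΔC > 0 per threshold, default
  grid S$0–150,000 in S$5,000 steps.
* **Tornado DSA.** Each parameter in turn to its DSA low/high, all others
  at base; the metric is percent change of incremental NMB at the scenario
  threshold, bars ranked by the larger absolute change, ties broken
  alphabetically; a base NMB of exactly 0 falls back to absolute S$
  changes, flagged in the output. Only deterministic values are varied;
  PSA distributions are untouched.
* **Threshold analysis.** Each S$1 of premium adds S$1 to ΔC and leaves ΔE
  unchanged, so NMB is affine in the premium and the maximum chargeable
  premium is premium₀ + NMB(premium₀); a Brent bisection over
  [0, max(10⁶, 2·closed form)] verifies the closed form to S$0.01 on every
  call unless disabled. A negative root is reported as 0 with a
  not-reimbursable flag. Premium-versus-parameter curves re-solve the
  closed form along a grid checked against the parameter's role bounds.
* **VOI.** EVPI(λ) = E[max_s NMB_s] − max_s E[NMB_s] over the PSA draws
  (computed with identical summation paths so degenerate draws give an
  exact 0, and clipped at 0 against float dust). EVPPI: the default
  estimator regresses incremental NMB on the target parameter with a
  lowess smoother (bandwidth recorded in the output metadata) —
  EVPPI = E[max(0, ĝ(θ))] − max(0, E[INB]); the validation path is a
  nested two-loop Monte-Carlo estimator whose outer loop can also take
  explicit draws (e.g. a discrete two-point design, enabling exact
  brute-force oracles). Negative estimates from Monte-Carlo noise are
  clipped to 0 with the raw value retained. Population scaling requires an
  explicit effective-population input; none is ever assumed. EVSI and ENBS
  are out of scope, but nothing in the interfaces precludes them.

## Synthetic parameter tables

The generator emulates the structure of a literature-derived parameter
table so the full pipeline runs and is testable without any external data.
Base values are drawn uniformly (once, under a profile seed) from ranges a
stroke-unit analyst would recognise as plausible: inpatient symptomatic DVT
risk under IPC plus manual movement 5–12 %; PE among DVT patients 15–30 %;
1-month inpatient case fatality 8–15 % (ischemic), with the hemorrhagic
value 1.8–3× higher (capped at 0.95), encoding the cohorts' mortality
difference; 11-month recurrence risks of a few percent;
ankle-specific contracture incidence 20–40 %; compliance 70–90 %;
protective default RRs (≤ 1); acute-stay and event costs in the
S$10²–10⁴ range typical of 2019 Singapore tariffs; post-stroke utility
0.60–0.80 with complication multipliers below 1. Every generated table
passes the full validation, and whole-pathway QALY rows are derived from
the drawn utilities as described above.

What the generator does **not** emulate: correlation between parameters
(none is modelled anywhere, as no joint evidence is assumed), skewed or
heavy-tailed cost data beyond the gamma family, structural uncertainty in
the tree itself, and — most importantly — the actual sourced values of the
real evaluation. Passing tests therefore demonstrate the correctness and
internal consistency of the machinery under realistic table structures,
not the numeric conclusions for any particular sourced table; those require
transcribing the sourced values into the template.

## Numerical choices and problem sizes

* Pathway-probability closure is asserted to 1e−12; expectation identities
  to 1e−9 relative.
* A relative risk of exactly 1 short-circuits the compliance mixture so a
  null intervention reproduces the comparator bit-for-bit (ΔC = ΔE = 0
  exactly), which float round-off in c·RR + (1 − c) would otherwise break.
* The premium bisection uses xtol 1e−6 against an agreement tolerance of
  S$0.01.
* Default analysis sizes: 5,000 PSA draws; 200,000 simulated patients per
  microsimulation check over 20 generated tables; 100 random models for
  the threshold-linearity check; 100,000 draws for distribution-fit
  round trips. These give Monte-Carlo errors at least an order of
  magnitude below every tolerance asserted on them.
* CEAC ties (NMB exactly 0) count as not cost-effective — measure-zero
  under continuous draws but deterministic for fixed tables.

## Known limitations

Single-year horizon with no state-transition extension; no interaction
with pharmacological DVT prophylaxis; no societal-perspective costs; no
parameter correlation; compliance is a cohort-level mixture rather than an
explicit patient-level process; the post-discharge complication month is a
single point in time rather than a distribution over the year.
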