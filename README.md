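# vacomhta

Early health-economic evaluation of **VACOM**, a soft robotic sock that
combines intermittent pneumatic compression (IPC) with soft pneumatic ankle
actuation for bed-bound post-stroke inpatients, against the current standard
of care (IPC plus manual ankle movement). The package is written for health
technology assessment (HTA) analysts and device innovators who need an
early, parameter-table-driven cost-utility model with full uncertainty
analysis before a first clinical trial.

## What it computes

A two-period decision tree follows a hypothetical cohort of stroke
inpatients (ischemic and hemorrhagic cohorts analysed separately) over a
1-year horizon from a healthcare-system perspective, costs in 2019
Singapore dollars:

* **Period 1 (inpatient, 1 month)** — deep vein thrombosis (DVT), pulmonary
  embolism (PE, a DVT sequela) and inpatient death (on day 15 of the stay).
* **Period 2 (months 2–12)** — one of recurrent stroke, recurrent DVT,
  recurrent PE, ankle contracture, or death, occurring at the start of
  month 7, with a residual "well" branch.

VACOM acts by multiplying the baseline DVT and ankle-contracture risks by
relative risks RR, diluted by the compliance rate *c*:
RR_eff = c·RR + (1 − c). QALYs are time-weighted utilities with
multiplicative comorbidity adjustment (u = u_stroke · u_DVT · …), or
whole-pathway QALY parameters (`qaly_ndnp_1_12m_well`, …) taken directly
from the table. On top of the tree the package computes:

* incremental statistics: ΔC, ΔE, ICER = ΔC/ΔE, NMB = λ·ΔE − ΔC at the
  ceiling threshold λ (default S$75,000/QALY), with quadrant-aware
  dominance classification;
* probabilistic sensitivity analysis (beta/gamma/lognormal by parameter
  role, common random numbers across arms) and the CEAC;
* one-way deterministic sensitivity analysis ranked as an NMB tornado;
* threshold (target-product-profile) analysis: the maximum price premium
  the innovator can charge while NMB ≥ 0, in closed form (the model is
  linear in the premium) verified by bisection, and premium-versus-RR
  curves;
* value of information: EVPI over a threshold grid and per-parameter EVPPI
  by a nested Monte-Carlo and a regression (lowess) estimator.

Two effectiveness scenarios are built in: **optimistic** (RR of ankle
contracture 0.3) and **conservative** (0.9), at the revised S$150 and
original S$300 price premiums, plus a S$1,000-premium scenario for VOI.

The packaged parameter table is **synthetic**: base values are drawn once
from literature-plausible ranges for the Singapore post-stroke setting (see
`docs/methods.md`), not transcribed study values. Analysts with sourced
values can transcribe them into the same CSV layout
(`src/vacomhta/templates/parameters_template.csv`) and run the identical
pipeline via `--params`.

## Worked example

```python
import vacomhta as v

table = v.default_parameter_table()
scenario = v.get_scenario("conservative_premium150")

inc = v.base_case("is", table, scenario)
print(f"delta cost : S${inc.delta_cost:9.2f}")
print(f"delta QALY :   {inc.delta_qaly:9.5f}")
print(f"NMB at S$75,000/QALY: S${inc.nmb:.2f}  ({inc.dominance})")

psa = v.run_psa("is", table, scenario, n=5000, seed=1)
p = v.ceac(psa, [75_000.0]).p_cost_effective.iloc[0]
print(f"P(cost-effective at S$75,000/QALY): {100*p:.1f}%")

mp = v.max_premium("is", table, scenario)
print(f"maximum chargeable premium: S${mp.premium:.2f}")
```

prints

```
delta cost : S$  -115.06
delta QALY :     0.00243
NMB at S$75,000/QALY: S$297.63  (cost_saving_dominant)
P(cost-effective at S$75,000/QALY): 61.9%
maximum chargeable premium: S$447.63
```

Read: for ischemic-stroke patients under the conservative effectiveness
assumption and a S$150 premium, VACOM saves about S$115 per patient while
adding 0.0024 QALYs — it *dominates* the comparator at base case. Under
joint parameter uncertainty the probability that it is cost-effective at
S$75,000/QALY is about 62%, and the premium could rise to about S$448
before the reimbursement decision flips.

The same analyses are available from a shell:

```sh
vacomhta run all --cohort both --scenario conservative_premium150 \
    --n-psa 5000 --seed 1 --out results_dir
vacomhta scenarios          # list the built-in presets
```

which writes the base-case table, pathway tables, CEAC, tornado, premium
and threshold curves, EVPI/EVPPI tables, and a `manifest.yaml` that makes
the run bit-reproducible.

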