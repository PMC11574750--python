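# Scenario configuration template for the VACOM decision-tree model.
# name: optimistic | conservative | custom.  Named scenarios must carry
# their defining ankle-contracture relative risk (0.3 / 0.9).
name: conservative
rr_ankle_contracture_vacom: 0.9
# Extra per-patient price of VACOM over IPC + manual ankle movement, 2019 S$.
price_premium: 150.0
# Stroke cohort to analyse (ischemic | hemorrhagic); null analyses both.
cohort: null
# Ceiling cost-effectiveness threshold, S$ per QALY.
threshold: 75000.0
timing:
  horizon_months: 12
  inpatient_months: 1
  inpatient_death_day: 15
  postdischarge_event_month: 7
seed: 0
n_psa: 5000
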