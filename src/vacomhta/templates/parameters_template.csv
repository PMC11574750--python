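# Parameter-table template for the VACOM decision-tree model.
# One row per parameter. Comma-separated, UTF-8, '.' decimal separator.
# Columns:
#   name        - mnemonic parameter name (prob_* / rr_* / cost_* / util_* / qaly_*)
#   cohort      - ischemic | hemorrhagic | both
#   role        - probability | relative_risk | cost | utility | whole_pathway_qaly
#   base_value  - deterministic base-case value
#   dist_family - beta | gamma | lognormal | fixed (blank: fitted from se)
#   dist_param1, dist_param2 - (alpha,beta) / (shape,rate) / (mu,sigma); blank: fitted
#   se          - standard error; blank: defaults to 20% of base_value
#   dsa_low, dsa_high - one-way DSA range; blank: 2.5th/97.5th percentile of the fit
#   strategy_rr - name of the relative-risk parameter applied to this probability
#                 in the intervention arm (blank: not strategy-modified)
# Replace the placeholder values below with transcribed source values to run
# the pipeline on real inputs. The qaly_* rows use the whole-pathway naming
# convention qaly_<inpatient>_1_12m_<outcome> with inpatient codes
# ndnp (no DVT/PE), dnp (DVT only), dp (DVT+PE) and outcome codes
# well, recstroke, recdvt, recpe, ankcon, death; inpatient deaths use
# qaly_<inpatient>_1m_death. Decomposed util_* rows may be supplied instead.
name,cohort,role,base_value,dist_family,dist_param1,dist_param2,se,dsa_low,dsa_high,strategy_rr
prob_dvt,both,probability,0.08,,,,0.016,,,rr_dvt_vac_ipc
prob_pe_dvt,both,probability,0.20,,,,0.04,,,
prob_death_inpatient,ischemic,probability,0.10,,,,0.02,,,
prob_death_inpatient,hemorrhagic,probability,0.28,,,,0.056,,,
prob_recur_stroke,both,probability,0.07,,,,0.014,,,
prob_recur_dvt,both,probability,0.03,,,,0.006,,,
prob_recur_pe,both,probability,0.01,,,,0.002,,,
prob_ankcon,both,probability,0.30,,,,0.06,,,rr_ankcon_vac
prob_death_postdis,ischemic,probability,0.07,,,,0.014,,,
prob_death_postdis,hemorrhagic,probability,0.16,,,,0.032,,,
prob_compliance_vac,both,probability,0.80,,,,0.08,,,
rr_dvt_vac_ipc,both,relative_risk,0.70,,,,0.14,,,
rr_ankcon_vac,both,relative_risk,0.90,,,,0.18,,,
cost_device,both,cost,500,,,,100,,,
cost_inpatient_stay,both,cost,20000,,,,4000,,,
cost_dvt,both,cost,3500,,,,700,,,
cost_pe,both,cost,9000,,,,1800,,,
cost_recstroke,both,cost,15000,,,,3000,,,
cost_recdvt,both,cost,3500,,,,700,,,
cost_recpe,both,cost,9000,,,,1800,,,
cost_ankcon,both,cost,5000,,,,1000,,,
cost_death_postdis,both,cost,1000,,,,200,,,
cost_monthly_postdis,both,cost,400,,,,80,,,
util_poststroke,both,utility,0.70,,,,0.07,,,
util_dvt,both,utility,0.90,,,,0.05,,,
util_pe,both,utility,0.82,,,,0.05,,,
util_recstroke,both,utility,0.70,,,,0.07,,,
util_recdvt,both,utility,0.90,,,,0.05,,,
util_recpe,both,utility,0.82,,,,0.05,,,
util_ankcon,both,utility,0.78,,,,0.05,,,
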