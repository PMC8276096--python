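# Baseline configuration: first-line AEP / DEP / EP for extensive-stage
# small-cell lung cancer, US payer perspective (2020 USD).
#
# Survival parameters, prices, cost aggregates, utilities, disutilities and
# proportions reproduce the published parameter table of the analysis.  The
# `treatment` block holds regimen details the main text leaves to standard
# practice (median ICI cycle counts, topotecan schedule, infusion hours);
# these are the model's calibration knobs and are safe to edit.

settings:
  cycle_days: 21
  horizon_years: 10
  annual_discount_rate: 0.03
  wtp_per_qaly: 100000
  body_surface_area: 1.80
  creatinine_clearance: 70.00
  half_cycle_correction: false

survival:
  aep:                       # log-logistic S(t) = 1/(1 + theta*t^kappa), t in months
    os:  {family: loglogistic, params: [0.003072, 2.297440]}
    pfs: {family: loglogistic, params: [0.008895, 2.852489]}
  ep:                        # Weibull S(t) = exp(-lambda*t^gamma), t in months
    os:  {family: weibull, params: [0.016073, 1.593409]}
    pfs: {family: weibull, params: [0.042826, 1.712046]}

dep_hr:                      # indirect comparison, DEP curves = AEP curves ^ HR
  os: 1.04
  pfs: 1.01

extrapolation:
  cutoff_months: 24.0
  os_mode: parametric_continuation   # external_hazard_table + a CSV overrides the OS tail
  pfs_mode: parametric_continuation
  hazard_table: null
  hazard_table_csv: null

prices:                      # USD per mg
  atezolizumab: 7.83
  durvalumab: 7.60
  etoposide: 1.51
  carboplatin: 0.06
  topotecan: 12.75

care_costs:                  # USD
  admin_first_hour: 142.55
  admin_additional_hour: 30.68
  monthly_physician_visit: 148.33
  three_monthly_imaging: 122.71
  monthly_supportive_care: 637.00
  death_cost: 9433.00

ae_costs:                    # one-time grade III/IV AE management aggregates, USD
  aep: 4959.82
  dep: 4743.05
  ep: 6100.94
  topotecan: 14487.33

utilities:
  pfs: 0.673
  ps: 0.473

disutilities:                # applied to the PFS utility during first-line cycles
  aep: 0.090
  dep: 0.094
  ep: 0.112

subsequent_proportion:       # fraction of progressors receiving topotecan
  aep: 0.517
  dep: 0.420
  ep: 0.516

treatment:
  chemo_cycles: 4
  etoposide_mg_per_m2: 100.0
  etoposide_days_per_cycle: 3
  carboplatin_auc: 5.0
  atezolizumab_mg: 1200.0
  durvalumab_mg: 1500.0
  ici_cycles_aep: 7          # median ICI cycles (calibration knob)
  ici_cycles_dep: 7
  ici_until_progression: false
  chemoimmuno_infusion_hours: 4
  chemo_infusion_hours: 3
  maintenance_infusion_hours: 1
  topotecan_mg_per_m2_per_day: 1.5
  topotecan_days_per_cycle: 5
  topotecan_max_cycles: 4

# One-way / probabilistic sensitivity parameters.  Baselines are read from
# the bound value above; ranges are the published 95% CIs (utilities,
# disutilities, proportions, HRs) or +/-25% of baseline (costs, patient
# constants); distributions as published.
sensitivity:
  - {name: HR OS DEP vs AEP,            binding: dep_hr.os,                          low: 0.83,     high: 1.25,     distribution: lognormal}
  - {name: HR PFS DEP vs AEP,           binding: dep_hr.pfs,                         low: 0.81,     high: 1.21,     distribution: lognormal}
  - {name: Atezolizumab price per mg,   binding: prices.atezolizumab,                low: 5.87,     high: 9.78,     distribution: gamma}
  - {name: Durvalumab price per mg,     binding: prices.durvalumab,                  low: 5.70,     high: 9.50,     distribution: gamma}
  - {name: Etoposide price per mg,      binding: prices.etoposide,                   low: 1.13,     high: 1.89,     distribution: gamma}
  - {name: Carboplatin price per mg,    binding: prices.carboplatin,                 low: 0.04,     high: 0.07,     distribution: gamma}
  - {name: Topotecan price per mg,      binding: prices.topotecan,                   low: 9.56,     high: 15.94,    distribution: gamma}
  - {name: AE cost first-line AEP,      binding: ae_costs.aep,                       low: 3719.87,  high: 6199.78,  distribution: gamma}
  - {name: AE cost first-line DEP,      binding: ae_costs.dep,                       low: 3557.29,  high: 5928.81,  distribution: gamma}
  - {name: AE cost first-line EP,       binding: ae_costs.ep,                        low: 4508.96,  high: 7514.93,  distribution: gamma}
  - {name: AE cost second-line topotecan, binding: ae_costs.topotecan,               low: 10865.50, high: 18109.16, distribution: gamma}
  - {name: IV administration first hour, binding: care_costs.admin_first_hour,       low: 106.91,   high: 178.19,   distribution: gamma}
  - {name: IV administration additional hour, binding: care_costs.admin_additional_hour, low: 23.01, high: 38.35,  distribution: gamma}
  - {name: Monthly physician visit,     binding: care_costs.monthly_physician_visit, low: 111.25,   high: 185.41,   distribution: gamma}
  - {name: Three-monthly imaging,       binding: care_costs.three_monthly_imaging,   low: 92.03,    high: 153.39,   distribution: gamma}
  - {name: Monthly supportive care,     binding: care_costs.monthly_supportive_care, low: 477.75,   high: 796.25,   distribution: gamma}
  - {name: Death associated costs,      binding: care_costs.death_cost,              low: 7074.75,  high: 11791.25, distribution: gamma}
  - {name: Utility PFS,                 binding: utilities.pfs,                      low: 0.538,    high: 0.808,    distribution: beta}
  - {name: Utility PS,                  binding: utilities.ps,                       low: 0.378,    high: 0.568,    distribution: beta}
  - {name: Disutility EP,               binding: disutilities.ep,                    low: 0.090,    high: 0.134,    distribution: beta}
  - {name: Disutility AEP,              binding: disutilities.aep,                   low: 0.072,    high: 0.108,    distribution: beta}
  - {name: Disutility DEP,              binding: disutilities.dep,                   low: 0.075,    high: 0.113,    distribution: beta}
  - {name: Subsequent therapy AEP,      binding: subsequent_proportion.aep,          low: 0.414,    high: 0.620,    distribution: beta}
  - {name: Subsequent therapy DEP,      binding: subsequent_proportion.dep,          low: 0.336,    high: 0.504,    distribution: beta}
  - {name: Subsequent therapy EP,       binding: subsequent_proportion.ep,           low: 0.413,    high: 0.619,    distribution: beta}
  - {name: Body surface area,           binding: settings.body_surface_area,         low: 1.35,     high: 2.25,     distribution: gamma}
  - {name: Creatinine clearance,        binding: settings.creatinine_clearance,      low: 52.50,    high: 87.50,    distribution: gamma}

psa:
  n_draws: 10000
  seed: 20210629
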