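# Minimal valid parameter set: three first-line drugs plus clozapine,
# tiny cohort sizes.  Intended for tests and quick desk runs.
schema_version: 1

treatments:
  - name: drug_a
    route: oral
    relapse_risk_ratio: 0.30
    annual_discontinuation_prob: 0.30
    annual_td_prob: 0.01
    metabolic_deltas: {bmi: 0.5, glucose: 0.1}
    short_term_se_probs: {eps: 0.10, sedation: 0.05}
    annual_drug_cost: 100
  - name: drug_b
    route: oral
    relapse_risk_ratio: 0.40
    annual_discontinuation_prob: 0.40
    annual_td_prob: 0.01
    metabolic_deltas: {bmi: 1.0, glucose: 0.3}
    short_term_se_probs: {weight_gain: 0.20}
    annual_drug_cost: 50
  - name: drug_c_lai
    route: lai
    relapse_risk_ratio: 0.35
    annual_discontinuation_prob: 0.30
    annual_td_prob: 0.01
    metabolic_deltas: {}
    short_term_se_probs: {sexual_dysfunction: 0.10}
    annual_drug_cost: 1500
  - name: clozapine
    route: oral
    is_clozapine: true
    relapse_risk_ratio: 0.25
    annual_discontinuation_prob: 0.28
    annual_td_prob: 0.005
    metabolic_deltas: {bmi: 1.0, glucose: 0.3}
    short_term_se_probs: {agranulocytosis: 0.008, sedation: 0.2}
    annual_drug_cost: 250

epidemiology:
  annual_relapse_prob_no_treatment: 0.50
  remission_duration: 0.5
  switch_prob_after_relapse: 0.5
  adherence_distribution: {full: 0.5, partial: 0.3, none: 0.2}
  adherence_relapse_weights: {full: 0.0, partial: 0.5, none: 1.0}
  smr_schizophrenia: 2.5
  case_fatality: {agranulocytosis: 0.05, chd: 0.25, stroke: 0.20}

utilities:
  u_stable: 0.85
  u_relapse: 0.60
  decrement_per_condition:
    eps: 0.045
    sedation: 0.020
    sexual_dysfunction: 0.020
    weight_gain: 0.040
    tardive_dyskinesia: 0.026
    agranulocytosis: 0.100
    post_chd: 0.090
    post_stroke: 0.116
    diabetes: 0.070
  short_term_se_duration: 0.25

costs:
  annual_stable_care_cost: 11500
  relapse_episode_cost: 17800
  relapse_cost_dialect: per_episode
  per_event_acute_cost:
    agranulocytosis: 5200
    eps: 310
    sedation: 120
    sexual_dysfunction: 120
    weight_gain: 210
    chd: 5100
    stroke: 11900
  annual_chronic_cost:
    post_chd: 1550
    post_stroke: 4050
    diabetes: 1520
    tardive_dyskinesia: 510
  death_cost: 3120
  currency_year: 2020

risk_coefficients:
  chd:
    variant: illustrative
    form: logistic
    horizon_years: 10
    intercept: -9.0
    terms:
      - {covariate: age, coef: 0.07}
      - {covariate: male, coef: 0.70}
      - {covariate: total_cholesterol, coef: 0.35}
      - {covariate: hdl, coef: -0.80}
      - {covariate: sbp, coef: 0.018}
      - {covariate: smoker, coef: 0.60}
      - {covariate: diabetes, coef: 0.60}
  stroke:
    variant: illustrative
    form: logistic
    horizon_years: 10
    intercept: -10.5
    terms:
      - {covariate: age, coef: 0.08}
      - {covariate: sbp, coef: 0.030}
      - {covariate: smoker, coef: 0.50}
      - {covariate: diabetes, coef: 0.70}
  diabetes:
    variant: illustrative
    form: logistic
    horizon_years: 8
    intercept: -11.5
    terms:
      - {covariate: age, coef: 0.03}
      - {covariate: bmi, coef: 0.15}
      - {covariate: glucose, coef: 0.60}

life_table_csv: life_table_synthetic_uk.csv

baseline:
  continuous:
    age: {mean: 26.5, sd: 6.0, lower: 16.0, upper: 60.0}
    bmi: {mean: 25.5, sd: 4.5, lower: 15.0, upper: 50.0}
    total_cholesterol: {mean: 4.9, sd: 1.0, lower: 2.0, upper: 10.0}
    hdl: {mean: 1.30, sd: 0.35, lower: 0.4, upper: 3.0}
    triglyceride: {mean: 1.40, sd: 0.85, lower: 0.2, upper: 6.0}
    glucose: {mean: 4.9, sd: 0.7, lower: 3.0, upper: 9.0}
    sbp: {mean: 120.0, sd: 12.0, lower: 85.0, upper: 180.0}
  categorical:
    sex: {male: 0.63, female: 0.37}
    smoking: {current: 0.55, non: 0.45}
    alcohol: {none: 0.30, moderate: 0.55, high: 0.15}
    adherence: {full: 0.5, partial: 0.3, none: 0.2}
    prior_chd: {"yes": 0.005, "no": 0.995}
    prior_stroke: {"yes": 0.003, "no": 0.997}
    prior_diabetes: {"yes": 0.02, "no": 0.98}
    on_antihypertensive: {"yes": 0.03, "no": 0.97}

sim:
  n_patients: 20
  n_replications: 2
  horizon: 10.0
  annual_discount_rate: 0.035
  wtp_grid: [0, 20000, 100000]
  base_wtp: 20000
  n_psa_draws: 10
  psa_n_patients: 10
  psa_n_replications: 1
  master_seed: 777

uncertainty:
  "treatments[drug_a].relapse_risk_ratio": {distribution: lognormal, params: {mu: -1.204, sigma: 0.15}}
  "treatments[drug_b].relapse_risk_ratio": {distribution: lognormal, params: {mu: -0.916, sigma: 0.15}}
  "treatments[drug_c_lai].relapse_risk_ratio": {distribution: lognormal, params: {mu: -1.050, sigma: 0.15}}
  "epidemiology.switch_prob_after_relapse": {distribution: beta, params: {alpha: 25.0, beta: 25.0}}
  "costs.annual_stable_care_cost": {distribution: gamma, params: {shape: 25.0, scale: 460.0}}
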