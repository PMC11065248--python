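# Default population specification: sex-stratified marginal parameters for
# adults aged 40-80 in Gaza, taken from a 2020 interviewer-administered
# household survey (n = 4,576; 2,103 men, 2,473 women; a subset of 1,938
# respondents had linked laboratory results).
#
# Booleans are prevalences in [0, 1]; continuous variables are (mean, sd)
# pairs with truncation bounds.  Treatment (rx_*) flags are conditional
# rates among the corresponding diagnosis.  HbA1c is specified conditional
# on diabetes diagnosis because the laboratory subset measured it almost
# exclusively among people already diagnosed.

n_default: 4576
female_fraction: 0.540428         # 2473 / 4576
refugee_fraction: 0.685
lab_observed_fraction: 0.423514   # 1938 / 4576

male:
  age:            {mean: 58.6, sd: 10.2, lo: 40.0, hi: 80.0}
  sbp:            {mean: 132.2, sd: 17.1, lo: 70.0, hi: 260.0}
  bmi:            {mean: 28.9, sd: 5.4, lo: 12.0, hi: 70.0}
  total_chol:     {mean: 170.5, sd: 38.8, lo: 60.0, hi: 400.0}
  triglycerides:  {mean: 178.8, sd: 144.1, lo: 20.0, hi: 2000.0, dist: lognormal}
  ldl:            {mean: 106.3, sd: 37.7, lo: 20.0, hi: 350.0}
  hdl:            {mean: 41.5, sd: 14.0, lo: 10.0, hi: 130.0}
  creatinine:     {mean: 1.0, sd: 0.5, lo: 0.2, hi: 12.0, dist: lognormal}
  hba1c_diabetic: {mean: 13.3, sd: 1.5, lo: 4.0, hi: 20.0}
  hba1c_normal:   {mean: 5.4, sd: 0.4, lo: 4.0, hi: 20.0}
  prevalence:
    dx_diabetes: 0.250
    dx_hypertension: 0.379
    dx_dyslipidemia: 0.214
    dx_asthma_copd: 0.101
    smoker: 0.609
    waterpipe: 0.145
  treated_given_dx:
    rx_diabetes: 0.9486      # 498 / 525
    rx_hypertension: 0.9536  # 761 / 798
    rx_statin: 0.796

female:
  age:            {mean: 55.4, sd: 10.5, lo: 40.0, hi: 80.0}
  sbp:            {mean: 128.0, sd: 18.7, lo: 70.0, hi: 260.0}
  bmi:            {mean: 33.5, sd: 6.4, lo: 12.0, hi: 70.0}
  total_chol:     {mean: 181.9, sd: 40.5, lo: 60.0, hi: 400.0}
  triglycerides:  {mean: 167.4, sd: 121.5, lo: 20.0, hi: 2000.0, dist: lognormal}
  ldl:            {mean: 112.9, sd: 39.2, lo: 20.0, hi: 350.0}
  hdl:            {mean: 46.5, sd: 16.5, lo: 10.0, hi: 130.0}
  creatinine:     {mean: 0.8, sd: 0.4, lo: 0.2, hi: 12.0, dist: lognormal}
  hba1c_diabetic: {mean: 11.5, sd: 1.4, lo: 4.0, hi: 20.0}
  hba1c_normal:   {mean: 5.4, sd: 0.4, lo: 4.0, hi: 20.0}
  prevalence:
    dx_diabetes: 0.262
    dx_hypertension: 0.425
    dx_dyslipidemia: 0.223
    dx_asthma_copd: 0.096
    smoker: 0.012
    waterpipe: 0.009
  treated_given_dx:
    rx_diabetes: 0.9567      # 619 / 647
    rx_hypertension: 0.9572  # 1006 / 1051
    rx_statin: 0.796

# Latent Gaussian rank dependence between variables (applied within each sex
# stratum).  Booleans are thresholded latent normals, so these entries are
# tetrachoric/polyserial-scale correlations, not Pearson correlations of the
# realized variables.  Only relationships the survey tables imply are encoded;
# unlisted pairs are independent.  The assembled matrix must be positive
# semidefinite (validated at load time).
dependence:
  - [age, sbp, 0.30]
  - [age, dx_diabetes, 0.25]
  - [age, dx_hypertension, 0.30]
  - [age, dx_dyslipidemia, 0.20]
  - [age, creatinine, 0.15]
  - [age, dx_asthma_copd, 0.10]
  - [bmi, sbp, 0.20]
  - [bmi, dx_diabetes, 0.25]
  - [bmi, dx_hypertension, 0.20]
  - [bmi, dx_dyslipidemia, 0.15]
  - [sbp, dx_hypertension, 0.35]
  - [total_chol, ldl, 0.85]
  - [total_chol, hdl, 0.15]
  - [total_chol, triglycerides, 0.30]
  - [total_chol, dx_dyslipidemia, 0.15]
  - [triglycerides, hdl, -0.30]
  - [triglycerides, dx_diabetes, 0.10]
  - [ldl, dx_dyslipidemia, 0.15]
  - [dx_diabetes, dx_hypertension, 0.30]
  - [dx_diabetes, dx_dyslipidemia, 0.25]
  - [dx_hypertension, dx_dyslipidemia, 0.25]
  - [smoker, dx_asthma_copd, 0.15]
  - [smoker, waterpipe, 0.20]
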