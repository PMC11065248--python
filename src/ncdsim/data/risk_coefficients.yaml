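# Coefficient fixtures for the five per-condition annual-risk score families.
#
# These are replaceable, literature-informed parameter sets in the style of
# the published score families they name (Globorisk laboratory-based scores
# averaged over Jordan/Lebanon/Syria for CVD; FINDRISC for diabetes; an
# age x prior-diagnosis x smoke-exposure multiplicative model for
# asthma/COPD; a Gail-style age-baseline model for breast cancer; a
# CRC-PRO-style model for colorectal cancer).  Because every condition's
# hazard is subsequently rescaled by calibration to external incidence
# targets, downstream burden estimates are insensitive to modest coefficient
# differences; what matters here is the relative risk gradient across
# individuals.

cvd:
  score_family: globorisk_lab_mean3
  params:
    # 10-year baseline cumulative hazard at the reference profile
    # (age 60, female, non-smoker, non-diabetic, SBP 130, total chol 180)
    country_h0_10yr: {jordan: 0.14, lebanon: 0.11, syria: 0.12}
    horizon_years: 10
    # log-hazard-ratio coefficients (per unit)
    beta_age: 0.075          # per year, centered at 60
    beta_male: 0.35
    beta_sbp: 0.016          # per mmHg, centered at 130
    beta_tchol: 0.0055       # per mg/dL, centered at 180
    beta_diabetes: 0.60
    beta_smoker: 0.55
    centers: {age: 60.0, sbp: 130.0, total_chol: 180.0}

diabetes:
  score_family: findrisc
  params:
    horizon_years: 10
    # points by category; waist-circumference points are carried by the BMI
    # category because waist was not surveyed (documented mapping)
    age_points: [[0, 45, 0], [45, 55, 2], [55, 65, 3], [65, 999, 4]]
    bmi_points: [[0, 25, 0], [25, 30, 4], [30, 999, 7]]   # BMI pts + mapped waist pts
    antihypertensive_points: 2     # uses rx_hypertension
    inactivity_points: 0           # physical activity not surveyed; population-average
    # score band -> 10-year diabetes probability
    risk_table: [[0, 6, 0.01], [7, 11, 0.04], [12, 14, 0.17], [15, 20, 0.33], [21, 99, 0.50]]

asthma_copd:
  score_family: rr_multiplicative
  params:
    baseline_annual_hazard: 0.004   # incident exacerbation/disease events at age 60
    beta_age: 0.03                  # log-hazard per year, centered at 60
    center_age: 60.0
    prior_dx_rr: 4.0                # self-reported asthma/COPD diagnosis
    active_smoking_rr: 2.0
    secondhand_rr: 1.3

breast_cancer:
  score_family: gail_style
  params:
    # annual baseline incidence by age band [lo, hi, hazard]; women only
    age_hazard:
      [[40, 45, 0.0008], [45, 50, 0.0010], [50, 55, 0.0013], [55, 60, 0.0015],
       [60, 65, 0.0017], [65, 70, 0.0019], [70, 75, 0.0021], [75, 999, 0.0022]]
    # multiplicative relative risks; family-history inputs were not surveyed
    # and default to the population average (RR 1)
    rr_family_history: 1.0

colorectal_cancer:
  score_family: crcpro_style
  params:
    baseline_annual_hazard: 0.0002  # at age 60
    beta_age: 0.06                  # log-hazard per year, centered at 60
    center_age: 60.0
    male_rr: 1.2
    smoker_rr: 1.2
    bmi_rr_per_5: 1.1               # per 5 kg/m^2 above 25
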