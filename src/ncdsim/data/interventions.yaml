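# The nine WHO NCD interventions judged feasible for modeling in Gaza by a
# local expert panel, with their published unit costs (2023 international
# dollars) and mechanism defaults.
#
# Unit costs are the published per-intervention figures.  Effect magnitudes
# (rate ratios among reached, eligible individuals) were NOT published in the
# main results; the values below are literature-informed defaults shipped as a
# clearly replaceable fixture, and every quantitative check that matters
# configures scenario deltas directly from the published burden panel instead
# of relying on these rate ratios.
#
# cost basis conventions:
#   per_person_year          - accrues for every living simulated person
#   per_eligible_person_year - accrues for reached, living, eligible persons
#   per_incident_case        - accrues once per reached incident case of the
#                              target condition
# eligible_fraction is the population fraction used by delta-configured
# (panel-based) costing for per_eligible_person_year interventions.

default_reach:
  final_reach: 0.64
  ramp: linear_over_horizon

interventions:
  - who_id: "1.4"
    name: "Eliminate exposure to second-hand tobacco smoke in indoor workplaces, public places and public transport"
    effects:
      - {target: cvd, channel: incidence_rr, magnitude: 0.87}
      - {target: asthma_copd, channel: incidence_rr, magnitude: 0.96}
    eligibility: {}
    cost_model: {per_person_year: 0.20}
  - who_id: "2.11"
    name: "Nutrition education and counseling in preschools, schools, workplaces and hospitals"
    effects:
      - {target: cvd, channel: incidence_rr, magnitude: 0.995}
      - {target: diabetes, channel: incidence_rr, magnitude: 0.996}
    eligibility: {}
    cost_model: {per_person_year: 4.00}
  - who_id: "2.13"
    name: "Mass media campaign on healthy diets"
    effects:
      - {target: cvd, channel: incidence_rr, magnitude: 0.993}
      - {target: diabetes, channel: incidence_rr, magnitude: 0.995}
    eligibility: {}
    cost_model: {per_person_year: 0.30}
  - who_id: "3.1"
    name: "Community-wide public education and awareness campaign for physical activity"
    effects:
      - {target: cvd, channel: incidence_rr, magnitude: 0.995}
      - {target: diabetes, channel: incidence_rr, magnitude: 0.994}
      - {target: asthma_copd, channel: incidence_rr, magnitude: 0.993}
      - {target: breast_cancer, channel: incidence_rr, magnitude: 0.995}
      - {target: colorectal_cancer, channel: incidence_rr, magnitude: 0.99}
    eligibility: {}
    cost_model: {per_person_year: 19.00}
  - who_id: "3.2"
    name: "Physical-activity counseling and referral in routine primary care"
    effects:
      - {target: cvd, channel: incidence_rr, magnitude: 0.987}
      - {target: diabetes, channel: incidence_rr, magnitude: 0.983}
      - {target: asthma_copd, channel: incidence_rr, magnitude: 0.984}
      - {target: breast_cancer, channel: incidence_rr, magnitude: 0.985}
      - {target: colorectal_cancer, channel: incidence_rr, magnitude: 0.985}
    eligibility: {}
    cost_model: {per_person_year: 110.00}
  - who_id: "6.2"
    name: "Mammography screening every two years for women aged 50-69, linked to timely treatment"
    effects:
      - {target: breast_cancer, channel: mortality_rr, magnitude: 0.80}
    eligibility: {sex: female, age_min: 50, age_max: 69}
    cost_model: {per_person_year: 20.00}   # already averaged over sex and biennial frequency
  - who_id: "6.3"
    name: "Treatment of colorectal cancer stages I and II with surgery +/- chemotherapy and radiotherapy"
    effects:
      - {target: colorectal_cancer, channel: mortality_rr, magnitude: 0.80}
    eligibility: {incident_condition: colorectal_cancer}
    cost_model: {per_incident_case: 14736.00}
  - who_id: "6.4"
    name: "Treatment of breast cancer stages I and II with surgery +/- systemic therapy"
    effects:
      - {target: breast_cancer, channel: mortality_rr, magnitude: 0.72}
    eligibility: {incident_condition: breast_cancer}
    cost_model: {per_incident_case: 1423.00}
  - who_id: "7.3"
    name: "Treatment of asthma with low-dose inhaled beclometasone and short-acting beta-agonist"
    effects:
      - {target: asthma_copd, channel: incidence_rr, magnitude: 0.93}
      - {target: asthma_copd, channel: mortality_rr, magnitude: 0.93}
    eligibility: {requires_dx: dx_asthma_copd}
    eligible_fraction: 0.098
    cost_model: {per_eligible_person_year: 24.00}
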