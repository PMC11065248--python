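# DALY accounting parameters.
#
# disability_weights: per-condition weights in [0, 1], GBD-style averages over
#   severity states (a single "with condition" state per condition).
# case_fatality: pre-calibration annual death probability among prevalent
#   cases; mortality calibration rescales these to external death targets.
# life_table: synthetic abridged reference life table (Gompertz-derived,
#   stylized to an Eastern-Mediterranean mortality level; NOT an official
#   extract).  qx is the annual all-cause death probability at the age-band
#   start; ex the remaining life expectancy.  Other-cause mortality in the
#   simulation is a Gompertz fit to qx, with sex multipliers.

disability_weights:
  cvd: 0.08
  diabetes: 0.068
  asthma_copd: 0.12
  breast_cancer: 0.30
  colorectal_cancer: 0.29

case_fatality:
  cvd: 0.010
  diabetes: 0.015
  asthma_copd: 0.010
  breast_cancer: 0.060
  colorectal_cancer: 0.080

other_cause_sex_multiplier: {male: 1.2, female: 0.85}

life_table:
  40:  {qx: 0.00220, ex: 37.93}
  45:  {qx: 0.00336, ex: 33.39}
  50:  {qx: 0.00513, ex: 29.01}
  55:  {qx: 0.00784, ex: 24.84}
  60:  {qx: 0.01197, ex: 20.90}
  65:  {qx: 0.01825, ex: 17.26}
  70:  {qx: 0.02777, ex: 13.97}
  75:  {qx: 0.04217, ex: 11.05}
  80:  {qx: 0.06378, ex: 8.53}
  85:  {qx: 0.09589, ex: 6.44}
  90:  {qx: 0.14289, ex: 4.74}
  95:  {qx: 0.21010, ex: 3.42}
  100: {qx: 0.30284, ex: 2.42}
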