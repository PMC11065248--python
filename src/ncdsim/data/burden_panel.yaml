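# Published 10-year burden panel for adults aged 40+ in Gaza, per 10,000
# population (2023 model estimates).  The baseline block is used as the
# default calibration target set; the intervention blocks give the published
# change-from-baseline (scenario minus baseline) for each modeled WHO
# intervention, used to configure delta-based cost-effectiveness runs and as
# reference values in tests.  Each entry is [point, ci_low, ci_high]; change
# entries are negative (reductions).  Intervals are stored (low, high) sorted.

conditions: [cvd, diabetes, asthma_copd, breast_cancer, colorectal_cancer]

baseline:
  cvd:               {incidence: [3417, 3334, 3512], mortality: [163, 140, 190], dalys: [3718, 3299, 4174]}
  diabetes:          {incidence: [1393, 1327, 1463], mortality: [294, 258, 331], dalys: [2088, 1787, 2402]}
  asthma_copd:       {incidence: [699, 651, 746],    mortality: [86, 69, 105],   dalys: [1856, 1465, 2270]}
  breast_cancer:     {incidence: [90, 74, 110],      mortality: [48, 35, 63],    dalys: [900, 639, 1190]}
  colorectal_cancer: {incidence: [114, 94, 136],     mortality: [84, 67, 102],   dalys: [954, 757, 1165]}

interventions:
  "1.4":   # smoke-free indoor workplaces, public places, public transport
    cvd:               {incidence: [-303, -310, -307], mortality: [-14, -17, -15], dalys: [-404, -431, -403]}
    diabetes:          {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    asthma_copd:       {incidence: [-11, -13, -10], mortality: [-1, -2, -1], dalys: [-29, -26, -16]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
  "2.11":  # nutrition education and counseling
    cvd:               {incidence: [-9, -12, -9], mortality: [-1, -2, 0], dalys: [-12, -15, -4]}
    diabetes:          {incidence: [-3, -3, -1], mortality: [0, 0, 0], dalys: [-4, -6, -3]}
    asthma_copd:       {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
  "2.13":  # mass-media campaign on healthy diets
    cvd:               {incidence: [-14, -17, -14], mortality: [-1, -2, 0], dalys: [-19, -20, -10]}
    diabetes:          {incidence: [-4, -5, -3], mortality: [-1, -1, 0], dalys: [-5, -8, -5]}
    asthma_copd:       {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [-1, -2, 0]}
    colorectal_cancer: {incidence: [0, -1, 0], mortality: [0, 0, 0], dalys: [-1, -2, 0]}
  "3.1":   # community-wide physical-activity campaign
    cvd:               {incidence: [-11, -13, -10], mortality: [-1, -2, 0], dalys: [-15, -18, -5]}
    diabetes:          {incidence: [-5, -7, -4], mortality: [-1, -2, 0], dalys: [-9, -9, -5]}
    asthma_copd:       {incidence: [-3, -3, -2], mortality: [0, -1, 0], dalys: [-7, -13, -1]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [-3, -6, 0]}
    colorectal_cancer: {incidence: [-1, -1, -1], mortality: [0, -1, 0], dalys: [-3, -7, 0]}
  "3.2":   # physical-activity counseling in primary care
    cvd:               {incidence: [-28, -30, -27], mortality: [-1, -3, -2], dalys: [-38, -54, -33]}
    diabetes:          {incidence: [-15, -17, -13], mortality: [-3, -3, -2], dalys: [-24, -30, -12]}
    asthma_copd:       {incidence: [-7, -8, -6], mortality: [-1, -1, -1], dalys: [-18, -27, -9]}
    breast_cancer:     {incidence: [-1, -2, 0], mortality: [-1, -1, 0], dalys: [-6, -7, -2]}
    colorectal_cancer: {incidence: [-1, -2, -1], mortality: [-1, -1, -1], dalys: [-8, -12, -4]}
  "6.2":   # mammography screening, women 50-69, every two years
    cvd:               {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    diabetes:          {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    asthma_copd:       {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [-5, -7, -4], dalys: [-87, -127, -59]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
  "6.3":   # treatment of colorectal cancer stages I-II
    cvd:               {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    diabetes:          {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    asthma_copd:       {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [-14, -15, -13], dalys: [-160, -177, -148]}
  "6.4":   # treatment of breast cancer stages I-II
    cvd:               {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    diabetes:          {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    asthma_copd:       {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [-12, -14, -10], dalys: [-217, -258, -180]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
  "7.3":   # asthma treatment with low-dose inhaled beclometasone + SABA
    cvd:               {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    diabetes:          {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    asthma_copd:       {incidence: [-33, -36, -31], mortality: [-4, -5, -3], dalys: [-90, -97, -85]}
    breast_cancer:     {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
    colorectal_cancer: {incidence: [0, 0, 0], mortality: [0, 0, 0], dalys: [0, 0, 0]}
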