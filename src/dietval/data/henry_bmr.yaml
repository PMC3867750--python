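# Basal metabolic rate prediction coefficients (weight-and-height form).
# BMR (MJ/day) = c_weight * weight_kg + c_height * height_m + c_intercept
# Transcribed from Henry CJK (2005) "Basal metabolic rate studies in humans:
# measurement and development of new equations", Public Health Nutrition
# 8(7A):1133-1152 (Oxford equations, weight & height).
# Age bands are half-open: age_min <= age < age_max.
version: 1
source: "Henry 2005, Public Health Nutrition 8(7A):1133-1152"
rows:
  - {sex: M, age_min: 0, age_max: 3, c_weight: 0.118, c_height: 3.59, c_intercept: -1.55}
  - {sex: M, age_min: 3, age_max: 10, c_weight: 0.0632, c_height: 1.31, c_intercept: 1.28}
  - {sex: M, age_min: 10, age_max: 18, c_weight: 0.0651, c_height: 1.11, c_intercept: 1.25}
  - {sex: M, age_min: 18, age_max: 30, c_weight: 0.06, c_height: 1.31, c_intercept: 0.473}
  - {sex: F, age_min: 0, age_max: 3, c_weight: 0.127, c_height: 2.94, c_intercept: -1.2}
  - {sex: F, age_min: 3, age_max: 10, c_weight: 0.0666, c_height: 0.878, c_intercept: 1.46}
  - {sex: F, age_min: 10, age_max: 18, c_weight: 0.0393, c_height: 1.04, c_intercept: 1.93}
  - {sex: F, age_min: 18, age_max: 30, c_weight: 0.0433, c_height: 2.57, c_intercept: -1.18}
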