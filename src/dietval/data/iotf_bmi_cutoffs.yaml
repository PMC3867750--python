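# International (IOTF) age- and sex-specific child BMI cut-off points for
# overweight and obesity, i.e. the childhood BMI values that pass through
# adult BMI 25 and 30 kg/m^2 at age 18.
# Transcribed from Cole TJ, Bellizzi MC, Flegal KM, Dietz WH (2000),
# BMJ 320:1240-1243, Table 4, for the age range relevant to 8-11 year olds.
# Values at intermediate ages are obtained by linear interpolation.
version: 1
source: "Cole et al. 2000, BMJ 320:1240-1243"
male:
  - {age: 7.0, overweight: 17.92, obese: 20.63}
  - {age: 7.5, overweight: 18.16, obese: 21.09}
  - {age: 8.0, overweight: 18.44, obese: 21.60}
  - {age: 8.5, overweight: 18.76, obese: 22.17}
  - {age: 9.0, overweight: 19.10, obese: 22.77}
  - {age: 9.5, overweight: 19.46, obese: 23.39}
  - {age: 10.0, overweight: 19.84, obese: 24.00}
  - {age: 10.5, overweight: 20.20, obese: 24.57}
  - {age: 11.0, overweight: 20.55, obese: 25.10}
  - {age: 11.5, overweight: 20.89, obese: 25.58}
  - {age: 12.0, overweight: 21.22, obese: 26.02}
female:
  - {age: 7.0, overweight: 17.75, obese: 20.51}
  - {age: 7.5, overweight: 18.03, obese: 21.01}
  - {age: 8.0, overweight: 18.35, obese: 21.57}
  - {age: 8.5, overweight: 18.69, obese: 22.18}
  - {age: 9.0, overweight: 19.07, obese: 22.81}
  - {age: 9.5, overweight: 19.45, obese: 23.46}
  - {age: 10.0, overweight: 19.86, obese: 24.11}
  - {age: 10.5, overweight: 20.29, obese: 24.77}
  - {age: 11.0, overweight: 20.74, obese: 25.42}
  - {age: 11.5, overweight: 21.20, obese: 26.05}
  - {age: 12.0, overweight: 21.68, obese: 26.67}
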