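# SYNTHETIC stand-in reference tables for child BMI and BP classification.
#
# These values are illustrative fixtures with realistic shapes (cut-offs rise
# with age; BP thresholds rise with age and height band).  They are NOT the
# published IOTF child-BMI cut-offs or AAP paediatric BP percentiles; deploy
# real tables by pointing ReferenceTables.from_yaml at a file with this schema.
#
# Schema
#   height_bands: ascending upper bounds (cm); a child falls in the first band
#     whose bound is >= their height (taller than all bounds -> last band).
#   iotf_child_bmi_cutoffs: rows of {sex, age, underweight, overweight, obese}
#     (kg/m^2); bmi < underweight -> underweight, >= overweight -> overweight,
#     >= obese -> obese, else normal.
#   aap_child_bp_percentiles: rows of
#     {sex, age, height_band, p90_sbp, p90_dbp, p95_sbp, p95_dbp} (mm Hg).
#   child_lvmi_p95: LVMI threshold (g/m^2) above which a child has LVH.

child_lvmi_p95: 109.4

height_bands: [110, 125, 200]

iotf_child_bmi_cutoffs:
  - {sex: female, age: 4,  underweight: 13.3, overweight: 17.3, obese: 19.1}
  - {sex: female, age: 5,  underweight: 13.2, overweight: 17.1, obese: 19.2}
  - {sex: female, age: 6,  underweight: 13.1, overweight: 17.3, obese: 19.7}
  - {sex: female, age: 7,  underweight: 13.2, overweight: 17.8, obese: 20.5}
  - {sex: female, age: 8,  underweight: 13.3, overweight: 18.3, obese: 21.6}
  - {sex: female, age: 9,  underweight: 13.5, overweight: 19.1, obese: 22.8}
  - {sex: female, age: 10, underweight: 13.8, overweight: 19.9, obese: 24.1}
  - {sex: male, age: 4,  underweight: 13.5, overweight: 17.5, obese: 19.3}
  - {sex: male, age: 5,  underweight: 13.4, overweight: 17.4, obese: 19.3}
  - {sex: male, age: 6,  underweight: 13.4, overweight: 17.5, obese: 19.8}
  - {sex: male, age: 7,  underweight: 13.4, overweight: 17.9, obese: 20.6}
  - {sex: male, age: 8,  underweight: 13.5, overweight: 18.4, obese: 21.6}
  - {sex: male, age: 9,  underweight: 13.6, overweight: 19.1, obese: 22.8}
  - {sex: male, age: 10, underweight: 13.9, overweight: 19.8, obese: 24.0}

aap_child_bp_percentiles:
  - {sex: female, age: 4,  height_band: 0, p90_sbp: 103, p90_dbp: 65, p95_sbp: 107, p95_dbp: 69}
  - {sex: female, age: 4,  height_band: 1, p90_sbp: 105, p90_dbp: 66, p95_sbp: 109, p95_dbp: 70}
  - {sex: female, age: 4,  height_band: 2, p90_sbp: 107, p90_dbp: 67, p95_sbp: 111, p95_dbp: 71}
  - {sex: female, age: 5,  height_band: 0, p90_sbp: 104, p90_dbp: 66, p95_sbp: 108, p95_dbp: 70}
  - {sex: female, age: 5,  height_band: 1, p90_sbp: 106, p90_dbp: 67, p95_sbp: 110, p95_dbp: 71}
  - {sex: female, age: 5,  height_band: 2, p90_sbp: 108, p90_dbp: 68, p95_sbp: 112, p95_dbp: 72}
  - {sex: female, age: 6,  height_band: 0, p90_sbp: 105, p90_dbp: 67, p95_sbp: 109, p95_dbp: 71}
  - {sex: female, age: 6,  height_band: 1, p90_sbp: 107, p90_dbp: 68, p95_sbp: 111, p95_dbp: 72}
  - {sex: female, age: 6,  height_band: 2, p90_sbp: 109, p90_dbp: 69, p95_sbp: 113, p95_dbp: 73}
  - {sex: female, age: 7,  height_band: 0, p90_sbp: 106, p90_dbp: 68, p95_sbp: 110, p95_dbp: 72}
  - {sex: female, age: 7,  height_band: 1, p90_sbp: 108, p90_dbp: 69, p95_sbp: 112, p95_dbp: 73}
  - {sex: female, age: 7,  height_band: 2, p90_sbp: 110, p90_dbp: 70, p95_sbp: 114, p95_dbp: 74}
  - {sex: female, age: 8,  height_band: 0, p90_sbp: 107, p90_dbp: 69, p95_sbp: 111, p95_dbp: 73}
  - {sex: female, age: 8,  height_band: 1, p90_sbp: 109, p90_dbp: 70, p95_sbp: 113, p95_dbp: 74}
  - {sex: female, age: 8,  height_band: 2, p90_sbp: 111, p90_dbp: 71, p95_sbp: 115, p95_dbp: 75}
  - {sex: female, age: 9,  height_band: 0, p90_sbp: 108, p90_dbp: 70, p95_sbp: 112, p95_dbp: 74}
  - {sex: female, age: 9,  height_band: 1, p90_sbp: 110, p90_dbp: 71, p95_sbp: 114, p95_dbp: 75}
  - {sex: female, age: 9,  height_band: 2, p90_sbp: 112, p90_dbp: 72, p95_sbp: 116, p95_dbp: 76}
  - {sex: female, age: 10, height_band: 0, p90_sbp: 110, p90_dbp: 71, p95_sbp: 114, p95_dbp: 75}
  - {sex: female, age: 10, height_band: 1, p90_sbp: 112, p90_dbp: 72, p95_sbp: 116, p95_dbp: 76}
  - {sex: female, age: 10, height_band: 2, p90_sbp: 114, p90_dbp: 73, p95_sbp: 118, p95_dbp: 77}
  - {sex: male, age: 4,  height_band: 0, p90_sbp: 104, p90_dbp: 64, p95_sbp: 108, p95_dbp: 68}
  - {sex: male, age: 4,  height_band: 1, p90_sbp: 106, p90_dbp: 65, p95_sbp: 110, p95_dbp: 69}
  - {sex: male, age: 4,  height_band: 2, p90_sbp: 108, p90_dbp: 66, p95_sbp: 112, p95_dbp: 70}
  - {sex: male, age: 5,  height_band: 0, p90_sbp: 105, p90_dbp: 65, p95_sbp: 109, p95_dbp: 69}
  - {sex: male, age: 5,  height_band: 1, p90_sbp: 107, p90_dbp: 66, p95_sbp: 111, p95_dbp: 70}
  - {sex: male, age: 5,  height_band: 2, p90_sbp: 109, p90_dbp: 67, p95_sbp: 113, p95_dbp: 71}
  - {sex: male, age: 6,  height_band: 0, p90_sbp: 106, p90_dbp: 66, p95_sbp: 110, p95_dbp: 70}
  - {sex: male, age: 6,  height_band: 1, p90_sbp: 108, p90_dbp: 67, p95_sbp: 112, p95_dbp: 71}
  - {sex: male, age: 6,  height_band: 2, p90_sbp: 110, p90_dbp: 68, p95_sbp: 114, p95_dbp: 72}
  - {sex: male, age: 7,  height_band: 0, p90_sbp: 107, p90_dbp: 67, p95_sbp: 111, p95_dbp: 71}
  - {sex: male, age: 7,  height_band: 1, p90_sbp: 109, p90_dbp: 68, p95_sbp: 113, p95_dbp: 72}
  - {sex: male, age: 7,  height_band: 2, p90_sbp: 111, p90_dbp: 69, p95_sbp: 115, p95_dbp: 73}
  - {sex: male, age: 8,  height_band: 0, p90_sbp: 108, p90_dbp: 68, p95_sbp: 112, p95_dbp: 72}
  - {sex: male, age: 8,  height_band: 1, p90_sbp: 110, p90_dbp: 69, p95_sbp: 114, p95_dbp: 73}
  - {sex: male, age: 8,  height_band: 2, p90_sbp: 112, p90_dbp: 70, p95_sbp: 116, p95_dbp: 74}
  - {sex: male, age: 9,  height_band: 0, p90_sbp: 109, p90_dbp: 69, p95_sbp: 113, p95_dbp: 73}
  - {sex: male, age: 9,  height_band: 1, p90_sbp: 111, p90_dbp: 70, p95_sbp: 115, p95_dbp: 74}
  - {sex: male, age: 9,  height_band: 2, p90_sbp: 113, p90_dbp: 71, p95_sbp: 117, p95_dbp: 75}
  - {sex: male, age: 10, height_band: 0, p90_sbp: 111, p90_dbp: 70, p95_sbp: 115, p95_dbp: 74}
  - {sex: male, age: 10, height_band: 1, p90_sbp: 113, p90_dbp: 71, p95_sbp: 117, p95_dbp: 75}
  - {sex: male, age: 10, height_band: 2, p90_sbp: 115, p90_dbp: 72, p95_sbp: 119, p95_dbp: 76}
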