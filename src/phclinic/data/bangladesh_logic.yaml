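# Default four-grade ("Bangladesh-logic") risk-stratification rule table.
#
# Numeric bins are half-open intervals [lo, hi): the lower edge always
# belongs to the higher-risk bin. `null` means unbounded. A bin may span
# several disjoint intervals (pulse rate). Items graded against
# sex-specific or fasting-specific thresholds carry `by_sex` / `by_fasting`
# sub-tables; blood pressure is the worst of its systolic and diastolic
# component grades.
fasting_cutoff_hours: 8.0
items:
  waist:
    measurement: waist_cm
    by_sex:
      male:
        bins:
          - {grade: green, intervals: [[null, 90]]}
          - {grade: yellow, intervals: [[90, null]]}
      female:
        bins:
          - {grade: green, intervals: [[null, 80]]}
          - {grade: yellow, intervals: [[80, null]]}
  waist_hip_ratio:
    measurement: waist_hip_ratio
    by_sex:
      male:
        bins:
          - {grade: green, intervals: [[null, 0.90]]}
          - {grade: yellow, intervals: [[0.90, null]]}
      female:
        bins:
          - {grade: green, intervals: [[null, 0.85]]}
          - {grade: yellow, intervals: [[0.85, null]]}
  bmi:
    measurement: bmi
    bins:
      - {grade: green, intervals: [[null, 25]]}
      - {grade: yellow, intervals: [[25, 30]]}
      - {grade: orange, intervals: [[30, 35]]}
      - {grade: red, intervals: [[35, null]]}
  blood_pressure:
    components:
      systolic:
        measurement: sbp_mmHg
        bins:
          - {grade: green, intervals: [[null, 130]]}
          - {grade: yellow, intervals: [[130, 140]]}
          - {grade: orange, intervals: [[140, 180]]}
          - {grade: red, intervals: [[180, null]]}
      diastolic:
        measurement: dbp_mmHg
        bins:
          - {grade: green, intervals: [[null, 85]]}
          - {grade: yellow, intervals: [[85, 90]]}
          - {grade: orange, intervals: [[90, 110]]}
          - {grade: red, intervals: [[110, null]]}
  blood_sugar:
    measurement: blood_sugar_mg_dl
    by_fasting:
      fasting:
        bins:
          - {grade: green, intervals: [[null, 100]]}
          - {grade: yellow, intervals: [[100, 126]]}
          - {grade: orange, intervals: [[126, 200]]}
          - {grade: red, intervals: [[200, null]]}
      postprandial:
        bins:
          - {grade: green, intervals: [[null, 140]]}
          - {grade: yellow, intervals: [[140, 200]]}
          - {grade: orange, intervals: [[200, 300]]}
          - {grade: red, intervals: [[300, null]]}
  urine_protein:
    measurement: urine_protein
    categories: {negative: green, trace: yellow, positive: orange}
  urine_sugar:
    measurement: urine_sugar
    categories: {negative: green, trace: yellow, positive: orange}
  urine_urobilinogen:
    measurement: urine_urobilinogen
    # normal urobilinogen is "trace"; the printed table leaves the yellow
    # cell blank, so "positive" maps straight to orange (overridable here)
    categories: {negative: green, trace: green, positive: orange}
  pulse:
    measurement: pulse_bpm
    bins:
      - {grade: green, intervals: [[60, 100]]}
      - {grade: yellow, intervals: [[50, 60], [100, 120]]}
      - {grade: orange, intervals: [[null, 50], [120, null]]}
  arrhythmia:
    measurement: arrhythmia
    categories: {"no": green, "yes": orange}
  smoking:
    measurement: smoker
    categories: {none: green, smoker: yellow}
  temperature:
    measurement: temperature_c
    bins:
      - {grade: green, intervals: [[null, 37]]}
      - {grade: yellow, intervals: [[37, 37.5]]}
      - {grade: orange, intervals: [[37.5, null]]}
  spo2:
    measurement: spo2_pct
    bins:
      - {grade: green, intervals: [[96, null]]}
      - {grade: yellow, intervals: [[93, 96]]}
      - {grade: orange, intervals: [[90, 93]]}
      - {grade: red, intervals: [[null, 90]]}
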