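arrivals:
  acuity_fractions:
    1: 0.01
    2: 0.09
    3: 0.4
    4: 0.35
    5: 0.15
  daily_mean: 155.0
  hourly_shape:
  - 0.38
  - 0.3
  - 0.26
  - 0.23
  - 0.22
  - 0.25
  - 0.36
  - 0.55
  - 0.85
  - 1.15
  - 1.35
  - 1.45
  - 1.45
  - 1.4
  - 1.35
  - 1.3
  - 1.32
  - 1.42
  - 1.52
  - 1.58
  - 1.48
  - 1.22
  - 0.88
  - 0.58
beds:
  ft: 0
  mta: 32
  trauma: 2
boarding_nurse_factor: 0.5
complexity:
  overall_admit_rate: 0.128
  per_acuity:
    1:
      admit_rate: 0.9
      cycle_continuation: 0.55
      max_cycles: 3
      p_imaging: 0.9
      p_lab: 0.95
    2:
      admit_rate: 0.45
      cycle_continuation: 0.55
      max_cycles: 3
      p_imaging: 0.8
      p_lab: 0.9
    3:
      admit_rate: 0.176875
      cycle_continuation: 0.56
      max_cycles: 3
      p_imaging: 0.7
      p_lab: 0.85
    4:
      admit_rate: 0.02
      cycle_continuation: 0.33
      max_cycles: 3
      p_imaging: 0.35
      p_lab: 0.55
    5:
      admit_rate: 0.005
      cycle_continuation: 0.17
      max_cycles: 3
      p_imaging: 0.1
      p_lab: 0.25
durations:
  boarding:
    mean: 97.8
    variance: 2391.21
  discharge_delay:
    mean: 30.0
    variance: 225.0
  imaging_tat:
    mean: 75.0
    variance: 1406.25
  lab_tat:
    mean: 30.0
    variance: 225.0
  nurse_assessment:
    mean: 5.0
    variance: 6.25
  physician_assessment:
    mean: 10.0
    variance: 25.0
  review_assessment:
    mean: 6.5
    variance: 10.5625
  triage:
    mean: 15.0
    variance: 56.25
esi2_bypass_fraction: 0.2
lwbs_tolerance:
  1:
    mean: 353.9325842696629
    variance: 8468.135336447418
  2:
    mean: 294.9438202247191
    variance: 5880.649539199597
  3:
    mean: 241.85393258426967
    variance: 3954.148750157809
  4:
    mean: 176.96629213483146
    variance: 2117.0338341118545
  5:
    mean: 141.5730337078652
    variance: 1354.9016538315877
name: national
nurse_ratio:
  1: 1.0
  2: 4.0
  3: 4.0
  4: 4.0
  5: 4.0
staff:
  nurse_schedule: null
  nurses: 8
  pa_schedule: null
  pas: 0
  physician_schedule:
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 2
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 3
  - 2
  - 2
  physicians: 3
travel_time_mean:
  nurse: 0.5
  pa: 1.0
  physician: 1.25
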