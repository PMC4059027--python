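arrivals:
  acuity_fractions:
    1: 0.02
    2: 0.24
    3: 0.46
    4: 0.19
    5: 0.09
  daily_mean: 195.0
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
  ft: 6
  mta: 41
  trauma: 3
boarding_nurse_factor: 0.5
complexity:
  overall_admit_rate: 0.258
  per_acuity:
    1:
      admit_rate: 0.95
      cycle_continuation: 0.5
      max_cycles: 3
      p_imaging: 0.9
      p_lab: 0.95
    2:
      admit_rate: 0.55
      cycle_continuation: 0.5
      max_cycles: 3
      p_imaging: 0.8
      p_lab: 0.9
    3:
      admit_rate: 0.21826086956521737
      cycle_continuation: 0.45
      max_cycles: 3
      p_imaging: 0.7
      p_lab: 0.85
    4:
      admit_rate: 0.03
      cycle_continuation: 0.28
      max_cycles: 3
      p_imaging: 0.35
      p_lab: 0.55
    5:
      admit_rate: 0.01
      cycle_continuation: 0.15
      max_cycles: 3
      p_imaging: 0.1
      p_lab: 0.25
durations:
  boarding:
    mean: 265.79999999999995
    variance: 17662.409999999993
  discharge_delay:
    mean: 85.0
    variance: 1806.25
  imaging_tat:
    mean: 90.0
    variance: 2025.0
  lab_tat:
    mean: 45.0
    variance: 506.25
  nurse_assessment:
    mean: 5.0
    variance: 6.25
  physician_assessment:
    mean: 10.0
    variance: 25.0
  review_assessment:
    mean: 5.0
    variance: 6.25
  triage:
    mean: 30.0
    variance: 225.0
esi2_bypass_fraction: 0.2
lwbs_tolerance:
  1:
    mean: 266.42984014209594
    variance: 3435.6672103581113
  2:
    mean: 245.1154529307282
    variance: 2907.948726847104
  3:
    mean: 213.1438721136767
    variance: 2198.82701462919
  4:
    mean: 175.8436944937833
    variance: 1496.576636831993
  5:
    mean: 159.85790408525753
    variance: 1236.8401957289198
name: academic
nurse_ratio:
  1: 1.0
  2: 4.0
  3: 4.0
  4: 4.0
  5: 4.0
staff:
  nurse_schedule: null
  nurses: 13
  pa_schedule:
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  - 1
  pas: 1
  physician_schedule:
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
  - 4
  - 4
  - 4
  - 4
  - 2
  - 2
  physicians: 4
travel_time_mean:
  nurse: 0.5
  pa: 1.0
  physician: 1.0
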