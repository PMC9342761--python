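globals:
  discount_rate_annual: 0.05
  gdp_per_capita: 700473.0
  wtp_multipliers:
  - 1
  - 2
  - 3
  - 4
  - 5
  device_price: 7104276.0
  cohort_size: 1000
  exchange_rate_ars_per_usd: 59.95
model1:
  mean_age: 59.0
  p_death_medtx:
    base: 0.106
    low: 0.079
    high: 0.132
  u_medtx:
    base: 0.53
    se: 0.135
  hosp_fraction_medtx: 0.25
model2:
  mean_age: 51.0
  wait_ht:
    base: 3.05
    low: 2.0
    high: 9.0
  wait_ht_btt:
    base: 6.07
    low: 3.05
    high: 12.0
  p_death_ht_periop:
    base: 0.074
    low: 0.055
    high: 0.092
  p_death_post_ht:
    base: 0.0024
    low: 0.0018
    high: 0.003
pump:
  mortality:
    starts:
    - 1
    - 2
    - 4
    - 7
    - 13
    - 25
    - 37
    - 49
    values:
    - 0.06
    - 0.025
    - 0.013
    - 0.01
    - 0.008
    - 0.008
    - 0.007
    - 0.006
    lows:
    - 0.045
    - 0.019
    - 0.01
    - 0.008
    - 0.0075
    - 0.006
    - 0.006
    - 0.004
    highs:
    - 0.075
    - 0.032
    - 0.017
    - 0.013
    - 0.019
    - 0.011
    - 0.009
    - 0.007
  u_first_month:
    base: 0.51
    se: 0.13
  u_after:
    base: 0.72
    se: 0.184
  complications:
  - name: gi_bleeding
    rate:
      starts:
      - 1
      - 13
      values:
      - 0.016
      - 0.005
      lows:
      - 0.012
      - 0.003
      highs:
      - 0.02
      - 0.006
    utility:
      base: 0.6
      se: 0.153
  - name: pump_failure
    rate:
      starts:
      - 1
      values:
      - 0.0008
      lows:
      - 0.0006
      highs:
      - 0.001
    utility:
      base: 0.53
      se: 0.135
  - name: disabling_stroke
    rate:
      starts:
      - 1
      - 2
      values:
      - 0.003
      - 0.0011
      lows:
      - 0.002
      - 0.0007
      highs:
      - 0.004
      - 0.0013
    utility:
      base: 0.44
      se: 0.112
  - name: nondisabling_stroke
    rate:
      starts:
      - 1
      - 2
      - 7
      values:
      - 0.037
      - 0.038
      - 0.03
      lows:
      - 0.027
      - 0.028
      - 0.022
      highs:
      - 0.046
      - 0.047
      - 0.037
    utility:
      base: 0.71
      se: 0.181
  - name: driveline_infection
    rate:
      starts:
      - 1
      - 13
      values:
      - 0.015
      - 0.004
      lows:
      - 0.011
      - 0.003
      highs:
      - 0.019
      - 0.006
    utility:
      base: 0.6
      se: 0.153
  - name: right_heart_failure
    rate:
      starts:
      - 1
      - 13
      values:
      - 0.024
      - 0.007
      lows:
      - 0.018
      - 0.005
      highs:
      - 0.03
      - 0.009
    utility:
      base: 0.53
      se: 0.135
  - name: sepsis
    rate:
      starts:
      - 1
      - 13
      values:
      - 0.01
      - 0.003
      lows:
      - 0.007
      - 0.002
      highs:
      - 0.012
      - 0.004
    utility:
      base: 0.47
      se: 0.12
  - name: ventricular_arrhythmia
    rate:
      starts:
      - 1
      - 13
      values:
      - 0.014
      - 0.004
      lows:
      - 0.01
      - 0.003
      highs:
      - 0.017
      - 0.005
    disutility: true
    utility:
      base: -0.02
      se: 0.005
transplant:
  u_stable:
    base: 0.76
    se: 0.193
  complications:
  - name: transplant_rejection
    rate:
      starts:
      - 1
      values:
      - 0.011
    utility:
      base: 0.76
      se: 0.193
  - name: allograft_vasculopathy
    rate:
      starts:
      - 1
      values:
      - 0.005
    utility:
      base: 0.76
      se: 0.193
  - name: skin_malignancy
    rate:
      starts:
      - 1
      values:
      - 0.001
    utility:
      base: 0.65
      se: 0.175
  - name: lymphoma
    rate:
      starts:
      - 1
      values:
      - 0.0001
    utility:
      base: 0.55
      se: 0.137
  - name: renal_dysfunction_dialysis
    rate:
      starts:
      - 1
      values:
      - 0.003
    utility: 0.57
  - name: ht_sepsis
    rate:
      starts:
      - 1
      values:
      - 0.009
    utility:
      base: 0.47
      se: 0.12
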