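# Built-in parameter registry for the heart-failure treatment model.
#
# Euro values are per-event or per-year fees; reimbursement of inpatient
# stays is expressed in DRG points (1 point = point_value euro).
# Distribution parameters follow the convention declared in `param_order`:
# weibull: (scale, shape); gamma: (shape, scale).
# Age-sex tables are indexed by the five age bins
# [0-55, 56-65, 66-75, 76-85, 86+] (closed integer ranges on current age).

point_value: 1.0

param_order:
  weibull: scale_shape
  gamma: shape_scale

# Daily transition probabilities out of the patient pool, expressed as
# events per year (converted to probability/day by dividing by 365).
daily_rates_per_year:
  outpatient_mortality: 0.0
  outpatient_clinic: 1.0
  physician: 12.0
  specialist: 0.0

fees:
  physician_annual: 544.0      # mean reimbursement per patient-year, 12 visits
  clinic_first: 209.0
  clinic_followup: 134.0

medication:
  # ATCxx residual booked on top of the three group draws:
  # ATCxx = residual_factor * (C03 + C07 + C09 draws).
  residual_factor: 3.33
  specs:
    C03:
      male:   {family: weibull, param1: 59.83, param2: 0.78}
      female: {family: weibull, param1: 43.27, param2: 0.93}
    C07:
      male:   {family: gamma, param1: 51.30, param2: 1.33}
      female: {family: gamma, param1: 56.67, param2: 1.25}
    C09:
      male:   {family: weibull, param1: 153.11, param2: 1.12}
      female: {family: weibull, param1: 165.84, param2: 1.13}

admission:
  rate_per_year: {I: 0.0186, II: 0.4287, III: 0.7643, IV: 1.6590}
  los:
    I:   {family: point, param1: 3.0, rounding: nearest_int_min1}
    II:  {family: gamma, param1: 10.66, param2: 0.63, rounding: nearest_int_min1}
    III: {family: gamma, param1: 8.84, param2: 1.27, rounding: nearest_int_min1}
    IV:  {family: gamma, param1: 7.56, param2: 1.83, rounding: nearest_int_min1}

intensive_care:
  points_per_day: 1664.0       # TISS-28 score 32
  probability:
    male:   [0.1610, 0.1610, 0.1160, 0.0860, 0.0390]
    female: [0.1550, 0.1440, 0.1000, 0.0710, 0.0330]
  los_days: [4, 4, 4, 3, 2]    # median days by age bin

intermediate_care:
  points_per_day: 480.0
  probability:
    male:   [0.2778, 0.2183, 0.1796, 0.1222, 0.0825]
    female: [0.2105, 0.1535, 0.1354, 0.0930, 0.0519]
  los_days: [3, 3, 2, 2, 2]

imp:                           # individual medical procedures
  probability:
    male:   [0.5721, 0.5450, 0.5611, 0.4761, 0.4676]
    female: [0.5476, 0.5593, 0.5109, 0.4334, 0.4163]
  points:
    male:   [236.43, 242.60, 205.60, 179.55, 146.65]
    female: [181.37, 155.00, 178.68, 136.16, 106.56]

mortality_per_admission:
  male:   [0.084, 0.088, 0.093, 0.133, 0.182]
  female: [0.068, 0.106, 0.089, 0.123, 0.156]

# NYHA transition matrices (row percentages as printed; rows are
# renormalized to sum exactly to 1 on load).
nyha_transitions:
  outpatient:
    I:   [23.08, 43.95, 28.57, 4.40]
    II:  [4.26, 52.41, 38.29, 5.04]
    III: [2.97, 43.93, 44.77, 8.33]
    IV:  [2.06, 25.77, 45.36, 26.81]
  inpatient:
    I:   [16.22, 35.14, 27.03, 21.62]
    II:  [2.96, 39.65, 35.30, 22.09]
    III: [2.17, 31.83, 40.00, 26.00]
    IV:  [2.16, 27.88, 34.86, 35.10]

drg:
  # Case flat rates with [min_los, max_los] treatment windows by age band.
  # supplement_per_day / short_stay_rate_per_day default to
  # flat_rate / max_los when null (pro-rata policy).
  le64: {min_los: 3, max_los: 10, flat_rate: 2688.0,
         supplement_per_day: null, short_stay_rate_per_day: null}
  ge65: {min_los: 4, max_los: 11, flat_rate: 3134.0,
         supplement_per_day: null, short_stay_rate_per_day: null}

telemonitoring:
  acquisition_cost: 1000.0
  monthly_fee: 45.0
  admission_rate_factor: 0.79
  los_mean_factor: 0.65
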