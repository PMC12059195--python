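# Default calibration for the synthetic wearable cohort and the analysis stages.
#
# Physiology marginals (resting HR/CBT, target strain components) follow the
# sex-specific summary statistics of the source study's cohort; environment
# parameters reproduce its indoor/outdoor WBGT climatology (overall daily
# means 20.5 / 19.3 degC, afternoon peak 14:00-15:00); missingness parameters
# reproduce its device feasibility profile (ACT availability 88%, GPS
# completeness median 79%). All values are plain data: nothing in the code
# hard-codes physiology.

cohort:
  n_pairs: 24
  n_days: 14                 # actigraphy + indoor WBGT deployment length
  start_date: "2023-02-06"   # arbitrary fixed local date; warm-season Kenya
  age_range: [20, 45]
  hr_cbt_day: 13             # 24-h HR/CBT and 22-h GPS run on this study day (1-based)

physiology:
  female:
    rhr_mean: 51.66          # bpm
    rhr_sd: 4.94
    resting_cbt_mean: 36.11  # degC
    resting_cbt_sd: 0.14
    target_cardiac_pct: 34.86   # mean cardiac strain the generator is calibrated to
    target_thermal_pct: 29.48   # mean thermal strain, %
    height_mean: 161.2       # cm
    height_sd: 7.1
    weight_mean: 55.1        # kg
    weight_sd: 9.1
    fat_mass_mean: 17.0      # %
    fat_mass_sd: 4.87
  male:
    rhr_mean: 47.94
    rhr_sd: 7.35
    resting_cbt_mean: 36.07
    resting_cbt_sd: 0.11
    target_cardiac_pct: 30.95
    target_thermal_pct: 27.28
    height_mean: 171.4
    height_sd: 6.55
    weight_mean: 64.3
    weight_sd: 8.19
    fat_mass_mean: 12.7
    fat_mass_sd: 4.75
  hr_noise_sd: 2.0           # bpm, white noise on each 1-min HR sample
  cbt_noise_sd: 0.04         # degC
  hr_peak_hour: 14.5         # circadian uplift peak (local hour)
  hr_halfwidth_h: 9.5        # half-width of the positive circadian lobe
  cbt_peak_hour: 16.5
  cbt_halfwidth_h: 10.5
  hr_weights:    {circadian: 0.5, activity: 0.3, heat: 0.2}
  cbt_weights:   {circadian: 0.7, activity: 0.2, heat: 0.1}
  heat_reference_c: 18.0     # outdoor WBGT above this couples into HR/CBT
  cadence_s: 60              # HR and CBT sample interval

environment:
  outdoor:
    mesor: 19.3              # degC; daily mean of the sinusoid
    amplitude: 5.0
    peak_hour: 14.5
    noise_sd: 1.0
  indoor:
    mesor: 20.5
    amplitude: 2.5
    peak_hour: 16.0          # indoor thermal mass lags outdoors
    noise_sd: 0.5
    household_sd: 0.3        # between-household offset SD
  cadence_min: 10            # logger writes every 10 min

activity:
  # Per-epoch (60 s) acceleration magnitude is drawn inside the bin of the
  # epoch's true state, so intensity classification against the same
  # cutpoints recovers the state ledger exactly.
  cutpoints: {sedentary_light: 0.08, light_moderate: 0.30, moderate_vigorous: 0.90}
  sleep_threshold: 0.02      # below: asleep; sleep-state draws stay under this
  epoch_s: 60
  steps_per_min: {sleep: 0, sedentary: 0, light: 20, moderate: 50, vigorous: 80}
  intensity_level: {sleep: 0.0, sedentary: 0.15, light: 0.35, moderate: 0.7, vigorous: 1.0}
  mvpa_hours_mean: {female: 3.0, male: 2.3}
  mvpa_hours_sd: {female: 1.5, male: 1.4}
  mvpa_day_jitter_h: 0.5
  light_hours_mean: 3.0
  light_hours_sd: 1.0

sleep:
  bed_hours_mean: {female: 8.4, male: 9.1}
  bed_hours_sd: 1.0
  bed_start_hour_mean: 21.0
  bed_start_hour_sd: 0.75
  efficiency_mean: {female: 0.618, male: 0.597}
  efficiency_sd: 0.12
  efficiency_range: [0.25, 0.98]
  wake_bout_min_epochs: 2
  wake_bout_max_epochs: 15   # kept below the detector's default bridge length

gps:
  home_lat: 0.06             # Siaya county, western Kenya
  home_lon: 34.29
  home_spacing_deg: 0.01     # households placed on a grid this far apart
  home_radius_m: 50.0
  farm_area_acres: 3.0       # buffered farm size used for geofencing
  farm_distance_km: 1.65     # home-to-farm leg; round trip = 3.3 km route
  farm_bearing_deg: 90.0
  farm_dwell_h: 3.5
  walk_speed_ms: 1.2
  fix_interval_s: 60
  duration_h: 22
  noise_sd_m: 0.0            # fix jitter; 0 keeps route length exact

missingness:
  # failure_prob: whole recording lost. gap_prob: recording has gap intervals.
  # Gap total fraction ~ Beta(a, b); split over 1..max_gaps intervals.
  ACT:         {failure_prob: 0.12, gap_prob: 0.3, gap_frac_beta: [1.0, 9.0], max_gaps: 4}
  HR:          {failure_prob: 0.04, gap_prob: 0.3, gap_frac_beta: [1.0, 9.0], max_gaps: 3}
  CBT:         {failure_prob: 0.00, gap_prob: 0.3, gap_frac_beta: [1.0, 9.0], max_gaps: 3}
  GPS:         {failure_prob: 0.04, gap_prob: 1.0, gap_frac_beta: [4.2, 15.8], max_gaps: 5}
  WBGT_indoor: {failure_prob: 0.00, gap_prob: 0.3, gap_frac_beta: [1.0, 9.0], max_gaps: 3}

artifacts:
  hr_rate: 0.005             # fraction of HR samples replaced by implausible values
  cbt_rate: 0.005
  hr_low: [20.0, 39.0]       # implausible draws: just outside the QC bounds
  hr_high_above_max: [1.0, 40.0]   # added to the participant's predicted peak
  cbt_low: [33.0, 34.9]
  cbt_high: [42.1, 43.5]

qc:
  hr_lower: 40.0             # bpm
  cbt_lower: 35.0            # degC
  cbt_upper: 42.0

strain:
  critical_cbt: 39.5         # degC
  component_weight: 5.0
  scale_bounds: [0.0, 10.0]
  tanaka_intercept: 208.0    # bpm
  tanaka_slope: -0.7         # bpm per year
  clamp: true
  epoch_min: 5               # averaging grid applied before strain computation

devices:
  intended_hours: {ACT: 336, CBT: 24, HR: 24, GPS: 22, WBGT_indoor: 336, WBGT_outdoor: 336}
  nominal_interval_s: {ACT: 60, CBT: 60, HR: 60, GPS: 60, WBGT_indoor: 600, WBGT_outdoor: 600}

surveys:
  # Likert sentiment generator: probability of high/neutral/low per response.
  p_high: 0.75
  p_neutral: 0.10
  p_low: 0.15
  n_social_pairs: 14         # social-experience questions went to 14 pairs only
  p_social_yes: {female: 0.45, male: 0.2}

lme_truth:
  # Ground-truth fixed effects for the PSI ~ WBGT mixed model simulator.
  # The WBGT, sex(male), WBGT x sex and MVPA coefficients are the study's
  # published estimates; the remaining entries are synthetic defaults chosen
  # to keep simulated PSI on its 0-10 scale.
  beta0: -5.0
  sex_male: 5.33
  wbgt: 0.32
  wbgt_sex: -0.27
  mvpa: -0.16
  sleep: 0.05
  bmi: 0.05
  fat_mass: 0.02
  random_intercept_sd: 0.5
  residual_sd: 0.8
  covariates:
    mvpa_mean: 2.65
    mvpa_sd: 1.9
    mvpa_range: [0.0, 8.0]
    sleep_mean: 4.75
    sleep_sd: 2.3
    sleep_range: [0.0, 12.0]
    bmi_mean: 21.5
    bmi_sd: 2.9
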