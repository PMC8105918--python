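# Desk-scale preset: 50 units x 1 year (260 weekdays), one outcome series.
# Exposure moments and cross-pollutant correlations follow the study area's
# summary statistics; the outcome is calibrated to ~1.42 counts per
# unit-day (asthma/COPD/URTI, all ages, per-unit scale) with a true
# short-term PM10 effect of +2% per temporal IQR (9.1 ug/m3) and a null
# long-term effect.
n_units: 50
start: 2012-01-02
end: 2012-12-28
seed: 0
unit_covariates:
  pct_elderly_mean: 9.0
  pct_elderly_sd: 3.0
  deprivation_mean: 25.0
  deprivation_sd: 8.0
exposure:
  pollutants:
    no2:  {mean: 50.7, spatial_sd: 16.3, temporal_sd: 15.4, unit_noise_sd: 1.54, seasonal_amplitude: 6.0,  peak_doy: 15,  ar1: 0.7}
    pm10: {mean: 21.2, spatial_sd: 2.6,  temporal_sd: 8.8,  unit_noise_sd: 0.88, seasonal_amplitude: 3.0,  peak_doy: 60,  ar1: 0.7}
    pm25: {mean: 15.6, spatial_sd: 1.2,  temporal_sd: 8.2,  unit_noise_sd: 0.82, seasonal_amplitude: 3.0,  peak_doy: 60,  ar1: 0.7}
    o3:   {mean: 49.9, spatial_sd: 4.7,  temporal_sd: 18.5, unit_noise_sd: 1.85, seasonal_amplitude: 12.0, peak_doy: 181, ar1: 0.7}
  # order: no2, pm10, pm25, o3
  temporal_corr:
    - [ 1.00,  0.55,  0.61, -0.60]
    - [ 0.55,  1.00,  0.96, -0.19]
    - [ 0.61,  0.96,  1.00, -0.29]
    - [-0.60, -0.19, -0.29,  1.00]
  spatial_corr:
    - [ 1.00,  0.70,  0.58, -0.55]
    - [ 0.70,  1.00,  0.75, -0.83]
    - [ 0.58,  0.75,  1.00, -0.80]
    - [-0.55, -0.83, -0.80,  1.00]
meteorology:
  temperature: {mean: 11.0, sd: 5.7,  seasonal_amplitude: 7.0, peak_doy: 196, ar1: 0.8}
  humidity:    {mean: 77.2, sd: 10.1, seasonal_amplitude: 4.0, peak_doy: 15,  ar1: 0.6}
outcomes:
  asthma_copd_urti:
    all_ages:
      pollutant: pm10
      intercept: 0.238871
      beta_short: 0.0021766076963976384   # ln(1.02) / 9.1 ug/m3
      beta_long: 0.0
      temperature: [-0.08, -0.04, 0.06]
      humidity: [0.02, 0.01, -0.02]
      trend: [0.03, -0.02, 0.04, -0.03, 0.02, -0.01]
      weekday: {Tue: 0.02, Wed: 0.01, Thu: -0.01, Fri: -0.03}
      pct_elderly: 0.004
      deprivation: 0.006
      gamma0: -2.4423470353692043   # pi = 0.08
      theta: 1.5
      sigma_b: 0.25
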