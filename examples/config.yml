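# Small end-to-end pipeline configuration (see README).
# `heatosa all -c examples/config.yml -o out/` finishes in under a minute.
seed: 7
exposure: mean          # mean | min | max daily temperature
max_lag: 4
spline_df: 4
weather:
  country: SYN
  start_year: 1985
  end_year: 2023
  mean_temp: 13.2
  seasonal_amplitude: 10.3
  noise_sd: 2.8
  trend_per_decade: 0.35
cohort:
  n_users: 100
  nights_per_user: 365
  rr: 1.45              # generative cumulative RR at 27.3 vs 6.4 degC
  rr_severe: 1.49
attribution_window: [1985, 1995]
attribution_year: 2023
burden_mode: primary
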