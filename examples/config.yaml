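# Full configuration schema for `lakebloom run` / `lakebloom simulate`.
simulation:
  n_lakes: 20
  year_start: 2003
  year_end: 2022
  grid_size: 16            # pixels per raster side (>= 8)
  cloud_prob: 0.2          # mean per-day censored pixel fraction, in [0, 1]
  ice_fraction: 0.25       # fraction of lakes with a winter ice season
  southern_fraction: 0.25  # fraction of Southern-Hemisphere lakes
  freeze_doy: 330          # NH freeze day of year (mirrored for SH lakes)
  melt_doy: 120
  fringe_width: 2          # low water-presence border strip, pixels
  pixel_area_km2: 1.0
  temp_mean_c: 12.0
  temp_amplitude_c: 12.0
  warming_trend_c_per_yr: 0.02
  temp_noise_sd: 1.5
  reflectance_noise_sd: 0.0
  seed: 1
  bloom_model:
    intercept: -8.0        # logit-scale baseline
    temp_coef: 0.35        # logit increase per degree C
    year_trend: 0.03       # logit increase per year
    # season: [150, 260]   # designed-season mode (window-relative days)
    # p_in_season: 0.9
    # p_off_season: 0.0

detection:
  nfai_threshold: 0.02
  water_presence_min: 0.75
  # green_region: [[0.0, 0.35], [0.35, 0.35], [0.35, 0.65], [0.0, 1.0]]

period_a: [2003, 2015]
period_b: [2016, 2022]
alpha: 0.05
write_scenes: false        # also persist NetCDF scene stacks during `run`
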