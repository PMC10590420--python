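# Demo pipeline configuration: two coupled bubbles under a 50%-duty-cycle
# pulse train, rendered at 50 fps and re-tracked end to end.
acoustics:
  prf_hz: 1.0
  duty: 0.5
  n_pulses: 5
  pressure_mpa: 0.035
  f0_mhz: 1.25
  delta_tot: 0.16
  rho0: 1000.0
  c: 1500.0
scene:
  bubbles:
    - {id: b0, x_um: 8.0, y_um: 12.0, radius_um: 2.0}
    - {id: b1, x_um: 8.0, y_um: 22.0, radius_um: 2.0}
  kv:
    duty_calibration: 0.5
  primary_direction: [1.0, 0.0]
  bjerknes_coupling: 0.0
  radius_decay_rate: 0.002
  noise_sd_um: 0.0
  pixel_size_um: 0.33
  frame_rate_hz: 50.0
  fov_px: [96, 96]
  background_level: 100.0
  spot_peak: 1000.0
  image_noise_sd: 0.0
tracking:
  diameter_px: 13
  min_mass: 5000.0
  max_disp_px: 5.0
  memory: 3
metrics:
  origin_frames: 1
duration_s: 5.0
rng_seed: 0
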