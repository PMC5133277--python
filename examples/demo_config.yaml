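# Scaled-down demo configuration for `mtverify run --config` (a full run at
# the reference design size fits six maximal mixed models on 6,400 trials
# and takes considerably longer).
seed: 1
design:
  n_scenes: 40
  n_lists: 4
  n_participants: 16
  per_participant: 40
geometry: {}          # ScreenGeometry overrides, e.g. width_px: 1280
params: {}            # SimulationParams overrides, e.g. motor_noise_px: 5.0
filter:
  k_sd: 4.0           # RT exclusion: mean + k_sd * SD (upper tail)
  jitter_px: 3.0      # x-flip jitter threshold, raw pixels
  n_bins: 101         # time-normalization bins for angle profiles
model:
  measures: [rt_s, initial_degree, latency_s, xflips, auc]
  accuracy: true
  accuracy_random: intercepts   # or: maximal
  gca: false                    # growth-curve analysis of angle profiles
  gca_poly_order: 3
  df_policy: normal
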