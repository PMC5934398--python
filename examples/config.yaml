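# Example end-to-end run on a synthetic two-condition ensemble.
# Protocol defaults (order 10, 5-90 Hz, B=1000, n_null=1000, p<0.001
# asymmetry, SVM cost 1 / 200 exemplars / 5000 repeats) are scaled down
# here so the demo finishes in a couple of minutes.
schema_version: 1
simulation:
  n_lower: 3
  n_higher: 2
  osc_freq: 16.0
  osc_damping: 0.9
  pink_noise_gain: 2.0
  coupling:
    - [H1, L1, 0.25, 1]
    - [H2, L2, 0.15, 1]
  condition_deltas:
    contingency1: {"H1->L1": 1.3}
    contingency2: {"H1->L1": 0.7}
  trials_per_condition: 1000
  samples_per_trial: 17
  seed: 7
input_path: null
order: 10
order_scan: [5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
band: [5.0, 90.0]
freq_step: 1.0
fit_band: [5.0, 30.0]
B: 200
n_null: 200
alpha_asymmetry: 0.001
alpha_peaks: 0.05
alpha_trtest: 0.05
target_freq: 16.0
B_exemplars: 100
repeats: 100
cost: 1.0
control_freq_range: [5.0, 50.0]
seed: 0
out_dir: results/example
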