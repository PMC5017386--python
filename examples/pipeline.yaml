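# Full pipeline configuration (all values shown are the defaults).
# Any section or key may be omitted; CLI flags override file values.

sim:
  n_subjects: 17
  n_repetitions: 3
  gesture_duration_s: 5.0
  seed: 0
  separation: 1.0          # 1.0 = fully distinct gesture templates
  placement_max_angle: 0.3926990816987241   # pi/8 armband rotation bound
  gain_sigma: 0.25         # lognormal sigma of per-channel subject gains
  noise_floor: 2.0         # baseline EMG noise RMS (int8 counts)
  acc_noise_std: 0.05      # m/s^2
  gyro_noise_std: 0.5      # rad/s
  transition_fade_s: 0.0   # optional EMG cross-fade at gesture boundaries

features:
  wavelet_level: 10        # D = 36 + 36*(L+1) features per frame
  wavelet_order: 4         # Daubechies family index (db4)
  emg_window: 128          # samples at 200 Hz (0.64 s)
  imu_window: 32           # samples at 50 Hz (0.64 s)
  energy_epsilon: 1.0e-12

train:
  hidden_nodes: 25
  hidden_layers: 1
  max_iter: 300
  grad_tol: 1.0e-6
  seed: 0
  scg_sigma: 1.0e-4
  scg_lambda0: 1.0e-6
  scg_ftol: 1.0e-5         # plateau stop on mean cross-entropy (0 disables)
  train_frame_stride: 4    # train on every 4th frame; predict on all

hmm:
  self_prob: 0.995
  emission_correct: 0.9
  start_at_first: true

eval:
  k: 5
  seed: 0
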