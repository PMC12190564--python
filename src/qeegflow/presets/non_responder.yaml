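n_subjects: 6
coupling:
- channel_a: C3
  channel_b: C4
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: F3
  channel_b: F4
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: P3
  channel_b: P4
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: O1
  channel_b: O2
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: T7
  channel_b: T8
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: F7
  channel_b: F8
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: P7
  channel_b: P8
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: Fp1
  channel_b: Fp2
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
- channel_a: Fz
  channel_b: Pz
  band: theta
  phase_lag_rad: 1.570796
  gains:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  - 1.0
seed: 2025
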