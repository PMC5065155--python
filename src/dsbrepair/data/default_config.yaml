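# Default study configuration: the eight-knockout repair-curve panel.
# Channel modes: full (recruitment + ligation), binding_only (recruitment
# governed by mu_4, no ligation), absent.  mu indices 1..4 name the shared
# hyperparameters (1 fast, 2 slow, 3 intermediate, 4 binding-only).
prior:
  rate_lower_hr: 0.001    # alpha_i = log(rate_lower_hr), equal for all mu_i
  rate_upper_hr: 20.0     # beta_i  = log(rate_upper_hr)
  sigma2: 0.25            # lognormal variance in log-rate space (fixed)
timepoints_hr: [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0]
datasets:
  - id: D1
    dose_gy: 20.0
    phase: asynchronous
    channels:
      fast: {mode: full, mu: 1}
      slow: {mode: full, mu: 2}
      aej: {mode: full, mu: 3}
  - id: D2
    dose_gy: 20.0
    phase: G1
    channels:
      fast: {mode: binding_only, mu: 4}
      slow: {mode: full, mu: 2}
      aej: {mode: full, mu: 3}
  - id: D3
    dose_gy: 20.0
    phase: G2
    channels:
      fast: {mode: binding_only, mu: 4}
      slow: {mode: full, mu: 2}
      aej: {mode: full, mu: 3}
  - id: D4
    dose_gy: 80.0
    phase: asynchronous
    channels:
      fast: {mode: full, mu: 1}
      slow: {mode: binding_only, mu: 4}
      aej: {mode: full, mu: 3}
  - id: D5
    dose_gy: 80.0
    phase: asynchronous
    channels:
      slow: {mode: full, mu: 2}
      aej: {mode: full, mu: 3}
  - id: D6
    dose_gy: 54.0
    phase: asynchronous
    channels:
      slow: {mode: full, mu: 2}
      aej: {mode: full, mu: 3}
  - id: D7
    dose_gy: 52.0
    phase: asynchronous
    channels:
      slow: {mode: full, mu: 2}
  - id: D8
    dose_gy: 32.0
    phase: asynchronous
    channels:
      fast: {mode: full, mu: 1}
      slow: {mode: full, mu: 2}
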