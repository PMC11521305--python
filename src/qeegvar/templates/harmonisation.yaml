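# Harmonisation-style study: common recording parameters and a single
# central analysis convention; residual lab differences are small gain
# offsets (log10 SD 0.15).  Surgeon quality can be degraded per lab to
# emulate a poor-signal site (all 1.0 here; override for that scenario).
phase: harmonisation
n_labs: 5
groups: [WT, TG]
n_per_group: 12
duration_s: 600
gain_log10_sd: 0.15
native_rates: [250]
noise_floor_uV: 1.0
artifact_rate_per_h: 20
artifact_amplitude: 8.0
surgeon_quality: [1.0, 1.0, 1.0, 1.0, 1.0]
effects:
  TG:
    total: 0.7
    theta: 1.15
dialects:
  - {}
biological_power_log10_sd: 0.3
theta_jitter_log10_sd: 0.05
session_power_log10_sd: 0.05
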