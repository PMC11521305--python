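# Localisation-style study: every laboratory runs its own acquisition and
# analysis conventions.  Gains span orders of magnitude (log10 SD 2),
# native rates and analysis dialects differ per lab, and some labs report
# relative power as a percentage rather than a fraction.
phase: localisation
n_labs: 5
groups: [WT, TG]
n_per_group: 12
duration_s: 600
gain_log10_sd: 2.0
native_rates: [200, 250, 500, 1000, 256]
noise_floor_uV: 1.0
artifact_rate_per_h: 20
artifact_amplitude: 8.0
effects:
  TG:
    total: 0.7
    theta: 1.15
dialects:
  - {total_range: [1, 48], theta_band: [4, 8], artifact_multiplier: 6, report_scale: 1}
  - {total_range: [0.5, 48], theta_band: [4, 8], artifact_multiplier: 5, report_scale: 100}
  - {total_range: [1, 30], theta_band: [4, 7], artifact_multiplier: 8, report_scale: 1}
  - {total_range: [1, 48], theta_band: [5, 9], artifact_multiplier: 6, report_scale: 100}
  - {total_range: [2, 48], theta_band: [4, 8], artifact_multiplier: 4, report_scale: 1}
biological_power_log10_sd: 0.3
theta_jitter_log10_sd: 0.05
session_power_log10_sd: 0.05
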