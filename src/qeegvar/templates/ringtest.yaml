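# Ring-testing study: harmonised protocol, blinded reference compound in
# a vehicle / 0.05 / 0.2 mg/kg cross-over (every animal receives every
# dose; washout between sessions is modelled as independence).  The dose
# is given at 3600 s so the 30-60 min pre/post windows fit exactly.
# Local analysis dialects differ in total-power range, gamma band edges,
# artifact threshold and reporting scale (fraction vs percent).
phase: ringtest
n_labs: 6
groups: [vehicle, MK801_0.05, MK801_0.2]
n_per_group: 12
duration_s: 7200
dose_time_s: 3600
gain_log10_sd: 0.15
native_rates: [100, 125, 200, 250, 100, 200]
noise_floor_uV: 1.0
artifact_rate_per_h: 20
artifact_amplitude: 8.0
effects:
  MK801_0.05:
    gamma: 1.05
  MK801_0.2:
    gamma: 1.4
dialects:
  - {total_range: [1, 48], gamma_band: [32, 48], artifact_multiplier: 6, report_scale: 1}
  - {total_range: [0.5, 48], gamma_band: [30, 48], artifact_multiplier: 5, report_scale: 100}
  - {total_range: [1, 30], gamma_band: [32, 48], artifact_multiplier: 8, report_scale: 1}
  - {total_range: [2, 48], gamma_band: [30, 45], artifact_multiplier: 6, report_scale: 100}
  - {total_range: [1, 48], gamma_band: [35, 48], artifact_multiplier: 4, report_scale: 100}
  - {total_range: [0.5, 48], gamma_band: [32, 48], artifact_multiplier: 6, report_scale: 1}
biological_power_log10_sd: 0.3
theta_jitter_log10_sd: 0.05
session_power_log10_sd: 0.05
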