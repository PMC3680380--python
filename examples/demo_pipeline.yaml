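# Demo end-to-end analysis: three symmetric-KCl i-V arms, a voltage-dependent
# open-channel block arm, and GHK analyses of the KCl-gradient reversal
# potential. Durations are kept short so the demo runs in well under a
# minute; raise duration_s for production-quality statistics.
seed: 1
out_dir: demo_out
analysis:
  idealization: hmm
  po_method: binomial
  alpha: 0.005
arms:
  - name: kcl210
    kind: iv
    salt_mM: 210
    ensemble:
      n_channels: 3
      conductance_pS: 395
      reversal_mV: 0.0
      scheme: {k_co: 40.0, k_oc: 10.0}
    recording: {duration_s: 2.0, sample_rate_hz: 10000, filter_corner_hz: 1000, noise_sd_pA: 1.0}
    voltages_mV: [-40, -30, -20, 20, 30, 40]
  - name: kcl610
    kind: iv
    salt_mM: 610
    ensemble:
      n_channels: 3
      conductance_pS: 960
      reversal_mV: 0.0
      scheme: {k_co: 40.0, k_oc: 10.0}
    recording: {duration_s: 2.0, sample_rate_hz: 10000, filter_corner_hz: 1000, noise_sd_pA: 1.0}
    voltages_mV: [-40, -30, -20, 20, 30, 40]
  - name: kcl810
    kind: iv
    salt_mM: 810
    ensemble:
      n_channels: 3
      conductance_pS: 1123
      reversal_mV: 0.0
      scheme: {k_co: 40.0, k_oc: 10.0}
    recording: {duration_s: 2.0, sample_rate_hz: 10000, filter_corner_hz: 1000, noise_sd_pA: 1.0}
    voltages_mV: [-40, -30, -20, 20, 30, 40]
  - name: neomycin_p60
    kind: block
    voltage_mV: 60
    n_recordings: 6
    ensemble:
      n_channels: 1
      conductance_pS: 395
      reversal_mV: 0.0
      scheme: {k_co: 245.0, k_oc: 5.0}
    block: {k_on_per_uM_s: 0.406, blocker_conc_uM: 100.0, k_off_s: 2000.0, v_e_on_mV: 20.0}
    recording: {duration_s: 2.0, sample_rate_hz: 10000, filter_corner_hz: 1000, noise_sd_pA: 1.0}
ghk:
  - name: kcl_gradient_ratio
    solutions:
      cis: {K: 810, Cl: 810}
      trans: {K: 210, Cl: 210}
      temperature_C: 22
    measured_erev_mV: -15.3
  - name: kcl_gradient_erev
    solutions:
      cis: {K: 810, Cl: 810}
      trans: {K: 210, Cl: 210}
      temperature_C: 22
      permeabilities: {K: 3.03, Cl: 1.0}
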