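# Pulmonary-artery-banded (PAB) phenotype: more NREM time, fewer light-period
# REM bouts, longer dark-period NREM bouts, faster return to sleep, and a
# blunted decline of NREM delta power across the light period.
group: pab
n_animals: 10
duration_hours: 48.0
epoch_length: 10.0
sampling_rate: 100.0
light_onset: 7.0
photoperiod: [12.0, 12.0]
seed: 1
targets:
  light:
    nrem_fraction: 0.648
    nrem_bout_min: 7.3
    rem_bout_count: 27.2
    rem_bout_min: 0.8
    resume_latency_min: 2.3
  dark:
    nrem_fraction: 0.424
    nrem_bout_min: 5.8
    rem_bout_count: 13.4
    rem_bout_min: 0.5
    resume_latency_min: 6.6
delta_decline: 0.15
band_power:
  wake: {delta: 30.0, theta: 50.0, sigma: 20.0, emg: 40.0, dispersion: 0.25}
  nrem: {delta: 200.0, theta: 50.0, sigma: 60.0, emg: 8.0, dispersion: 0.25}
  rem: {delta: 30.0, theta: 120.0, sigma: 25.0, emg: 4.0, dispersion: 0.25}
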