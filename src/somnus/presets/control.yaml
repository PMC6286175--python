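# Sham-operated (control) phenotype: published group statistics used to
# calibrate the light/dark transition matrices at load time.
group: control
n_animals: 7
duration_hours: 48.0
epoch_length: 10.0
sampling_rate: 100.0
light_onset: 7.0
photoperiod: [12.0, 12.0]
seed: 0
targets:
  light:
    nrem_fraction: 0.606        # % of 12-h light period in NREM / 100
    nrem_bout_min: 6.2          # mean NREM bout duration, minutes
    rem_bout_count: 37.0        # REM bouts per 12-h light period
    rem_bout_min: 0.9           # mean REM bout duration, minutes
    resume_latency_min: 3.2     # mean time to resume sleep, minutes
  dark:
    nrem_fraction: 0.333
    nrem_bout_min: 4.2
    rem_bout_count: 9.8
    rem_bout_min: 0.4
    resume_latency_min: 6.0
# fractional decrease of NREM delta power across the light period
delta_decline: 0.35
band_power:        # per-state mean band power (uV^2) / EMG amplitude (uV)
  wake: {delta: 30.0, theta: 50.0, sigma: 20.0, emg: 40.0, dispersion: 0.25}
  nrem: {delta: 200.0, theta: 50.0, sigma: 60.0, emg: 8.0, dispersion: 0.25}
  rem: {delta: 30.0, theta: 120.0, sigma: 25.0, emg: 4.0, dispersion: 0.25}
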