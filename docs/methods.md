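# Methods

This note documents the models, conventions and numerical choices in
`somnus`, in the order the pipeline runs: simulation, spectral
features, scoring, architecture metrics, and group statistics. It also
states what the synthetic data do and do not emulate, so that passing
tests are interpreted correctly.

## Sleep-state simulation

### Model

A mouse's epoch-resolution sleep sequence is modelled as a first-order
Markov chain on (WAKE, NREM, REM) with a 3×3 row-stochastic transition
matrix per photoperiod phase: one matrix governs epochs whose start
time falls in the 12-h light (rest) phase, another the 12-h dark
(active) phase. Epochs are half-open intervals [t, t+10 s); an epoch
belongs to the light period iff its start lies in the light phase.
Recordings start at light onset (07:00 by default — configurable,
since lights-on clock time varies between facilities) and chains are
initialised from the stationary distribution of the light-phase
matrix. Within a phase the chain is homogeneous: circadian structure
beyond the light/dark dichotomy (e.g. the progressive rise of REM
propensity across the rest phase) is not modelled, which is sufficient
to reproduce 2-h-binned circadian profiles that differ between phases
but is a deliberate simplification of real sleep.

A first-order chain has geometric dwell (run-length) distributions.
That is the key property the calibration exploits, and also the main
respect in which the generator is idealised: real rodent sleep has
heavier-tailed bout durations and more short intra-bout wake
intrusions than a geometric model produces.

### Calibration to published statistics

`matrix_from_occupancy_dwell(pi, D)` builds the unique-up-to-one-dof
chain with stationary distribution `pi` and mean dwells `D`: the
self-transition of state s is exactly `1 − 1/D[s]`, and the
off-diagonal jump probabilities are obtained by solving the jump-chain
stationarity equations. The jump chain's stationary law is
`phi ∝ pi/D`; feasibility requires every `phi[s] ≤ 1/2` (no state may
carry more than half of all transitions). The remaining
one-dimensional freedom is resolved by projecting the
proportional-entry solution (destination probability proportional to
each state's entry flow) onto the feasible interval — for symmetric
targets this yields a symmetric matrix. One consequence of flow
balance worth noting: with realistic dwells some wake→REM probability
is unavoidable in this 3-state closure, although in real mice REM is
entered almost exclusively from NREM.

`calibrate_phase` maps per-phase published statistics onto `(pi, D)`:

- **NREM dwell** from the mean NREM bout duration: a geometric run
  with mean `D` conditioned on reaching the m-epoch bout minimum has
  mean `(m−1) + D`, so `D = duration_epochs − 2` for NREM (m = 3) and
  `D = duration_epochs − 1` for REM (m = 2).
- **REM occupancy** from the REM bout count: the published count is of
  qualifying runs (≥ 2 epochs), so the run count is un-conditioned by
  dividing by `P(L ≥ 2) = 1 − 1/D_REM` before converting to occupancy.
- **NREM occupancy** is the published percentage, taken directly.
- **WAKE dwell** from the published time-to-resume-sleep: the expected
  latency from the onset of a ≥3-epoch wake run to the next three
  consecutive sleep epochs is computed *exactly* by first-step
  analysis on a 5-state augmented chain over (state,
  consecutive-sleep-count) pairs, and the wake dwell is found by
  Brent root-finding of this expectation against the published value
  (tolerance 1e-6 epochs), clipped to the flow-balance feasibility
  interval with a 2% margin.

Residual, documented biases of this inversion: interruptions shorter
than the terminating minimum merge adjacent runs into one bout, so
measured bout durations run a few percent above the dwell-based target
and counts a few percent below; and when the published latency lies
below the feasibility floor (the PAB light phase, whose 2.3-min target
would require more wake entries than the long published bouts allow),
the dwell is clipped and the simulated latency lands near the floor
(~3.3 min) rather than at the target. Arousal frequency is
deliberately left uncalibrated: the published arousal indices imply
more brief awakenings than a 3-state geometric chain can host at the
published bout durations, which is exactly the intra-bout-intrusion
realism the model does not attempt.

The shipped presets (`control`, `pab`) store the published group
statistics as YAML; matrices are calibrated at load time, never stored.

### Signal synthesis

Per epoch the EEG is a sum of three independent band-limited Gaussian
noise components (delta, theta, sigma). Each component's variance is
the state's configured band power (µV²) modulated by an independent
log-normal factor with mean 1 and log-sd `dispersion` (default 0.25);
band powers are approximately log-normal in real recordings and no
better-motivated noise model is available. Components are synthesised
in the frequency domain with support 0.5 Hz inside each nominal band
(the guard margin), so that finite-window spectral estimation (Hann
main lobe ≈ 1 Hz at 2-s segments) attributes the power to the correct
band; each epoch's component is normalised to its exact target
variance. The EMG is white noise with state-dependent amplitude.
Epochs are synthesised independently — there is no waveform continuity
across epoch boundaries and no transient morphology (spindles,
K-complexes, artifacts). Consequently, scoring accuracy on synthetic
data (≥ 97% in tests) is an upper bound relative to real recordings,
where state transitions inside epochs and artifacts blur the feature
clusters.

Default per-state parameters (µV² / µV): WAKE δ30 θ50 σ20 EMG 40;
NREM δ200 θ50 σ60 EMG 8; REM δ30 θ120 σ25 EMG 4. These encode the
standard electrographic signatures — slow-wave-dominant NREM with
spindle-band activity and moderate tone, theta-dominant REM with
atonia, mixed-frequency wake with high tone — at amplitudes typical of
murine cortical screw electrodes.

The homeostatic decline of slow-wave activity is injected as a linear
ramp on NREM delta power across the light period: multiplier 1 at
light onset falling to `1 − delta_decline` at light end, constant 1 in
the dark. A linear form is the simplest shape consistent with a
monotone 2-h-binned decline; presets use 0.35 (control) and 0.15
(PAB — the blunted-dissipation phenotype).

Default sampling rate is 100 Hz (Nyquist 50 Hz comfortably covers the
14-Hz top analysis band) so that multi-day cohorts stay desk-scale;
300 Hz acquisition can be configured where fidelity to hardware
matters.

## Spectral features

Band power per 10-s epoch is the trapezoidal integral of the Welch
power spectral density (Hann window, 2-s segments, 50% overlap, no
detrending) over each band, inclusive band edges. 2-s segments give
0.5-Hz resolution — fine enough to separate the bands, coarse enough
for 9 averaged segments per epoch. The gaps between bands (4–6,
9–10, > 14 Hz) are excluded. A pure tone of amplitude A inside a band
is recovered as A²/2 within 5% (Parseval check). EMG amplitude is the
epoch mean of the rectified signal after a 1-s moving average; the
window length is a convention (the published descriptions of such
pipelines do not fix it) and only rescales the feature monotonically,
which the scale-free threshold calibration absorbs. Trailing partial
epochs are discarded; NaN samples raise with the offending epoch
named.

## Scoring

Classification is per-epoch and stateless: SLEEP iff log(σθ) lies
strictly above the discriminant line in log EMG (ties score WAKE);
sleep is NREM iff δ/θ ≥ threshold (ties NREM; zero θ scores NREM with
a warning). Log-transformed axes are the default because band powers
are log-normal-ish and the scatter-plane construction is scale-free; a
linear domain is available. No temporal smoothing or minimum-duration
rule is applied at this stage — all temporal structure belongs to the
downstream bout state machine, keeping the two stages independently
testable.

Automatic calibration is per recording block (one threshold set per
animal, ≥ 24 h of data required): a two-component Gaussian mixture on
log EMG (deterministic quantile initialisation) separates the
quiescent from the active muscle-tone regime; the sleep/wake line is
the perpendicular bisector of the two cluster centroids in the
(log EMG, log σθ) plane; and the NREM/REM cutoff is the deepest
density minimum between the two largest modes of log(δ/θ) among
putative sleep epochs. The density estimate uses a fixed-bandwidth
Gaussian kernel (0.2 × sd on a 512-point grid) so the result is
deterministic and invariant to duplicating the data. Fallbacks, each
with a warning: mixture-midpoint when no interior minimum exists but
the mixture separates; otherwise the median. Fewer than 100 putative
sleep epochs is an error. Whether the original laboratory workflows
set such thresholds manually or algorithmically is generally not
reported; the automatic procedure is this package's own, and fitted
thresholds are serialised to JSON for audit.

## Architecture metrics

Bout and arousal definitions follow the standard rodent rules stated
in the README. Conventions that the verbal rules leave open, fixed
here:

- **Bout duration** spans first to last own-state epoch inclusive of
  interior interruptions (`interruptions="span"`, the default); an
  own-state-epochs-only accounting is available. The span convention
  makes duration equal to the bout's temporal extent.
- **Arousal precondition** — "three consecutive sleep epochs" — admits
  mixed NREM/REM, consistent with every other epoch-based rule.
- **Resume latency** targets the *first* epoch of the qualifying sleep
  run; events unresolved at the recording end are censored (excluded),
  not imputed. A ≥3-epoch wake run both counts as an arousal and
  opens a latency event; the two metrics deliberately overlap.
- **Multi-day recordings**: every per-period metric is computed per
  24-h day and averaged within animal; bouts are detected within days,
  so a bout straddling midnight of the recording clock is split (a
  ≤ 0.5% edge effect at 48 h).
- **Delta density**: per 2-h clock bin (aligned to light onset), raw =
  mean delta power over NREM epochs, per-day means averaged across
  days, then normalised by the mean over non-missing bins — the
  normalised profile averages exactly 1 by construction. Bins with no
  NREM sleep are missing (NaN), never zero.

All three scanners (bouts, arousals, latency) are validated
exhaustively against independent regex-based re-implementations of the
verbatim rules on every hypnogram of length 8 and on 10⁴ random
length-500 sequences.

## Group statistics

The design is a split plot: surgical group (between, possibly unequal
n) × 2-h clock bin (within, complete). Sums of squares use the
observation-weighted decomposition, which for this proportional design
coincides with the sequential and hierarchical types; the group effect
is tested against subjects-within-groups, time and group × time
against the subject × time error. Light and dark periods are analysed
as separate 6-bin ANOVAs, matching how 12-h phases are reported.
Per-period scalar metrics use the unpaired pooled-variance t-test.

Sphericity: Mauchly's W is computed from the eigenvalues of the pooled
within-group covariance projected onto orthonormal (Helmert)
contrasts, with the first-order Box chi-square approximation
(R's `mauchly.test` adds a second-order series term; W itself agrees
to machine precision, p-values to ~0.02 in small samples).
Greenhouse–Geisser ε = (Σλ)² / ((k−1)Σλ²) on the same eigenvalues,
clipped to its exact bounds [1/(k−1), 1]. Both the unadjusted and
ε-adjusted p-values are always reported; the headline `p_reported`
adjusts only when Mauchly rejects at 0.05. This gated procedure is
the one whose type-I error is calibrated in the acceptance suite
(5% nominal over 500 null cohorts of 17 simulated animals); applying ε
unconditionally is measurably conservative on near-spherical profiles.
Fisher LSD simple effects use the pooled error
(SS_subjects + SS_error)/(df_subjects + df_error) and are unadjusted
by definition; with one time bin they reduce exactly to the pooled
t-test. No multiplicity correction is applied across the metric
battery. Unbalanced within-subject data raise rather than impute.

## Problem sizes and tolerances

Test and acceptance runs use cohorts at the published sizes (7 control
/ 10 PAB animals, 48 h, 10-s epochs → 17,280 epochs/animal) for
hypnogram-level checks; full signal-path checks synthesise 24 h per
preset at 100 Hz, and generator unit checks use 0.5–12 h at 50 Hz.
Statistic-recovery tolerances are ±2–3 percentage points on state
percentages and ±15–20% on bout/latency metrics, reflecting the
calibration biases described above plus cohort-level sampling noise;
oracle-equivalence checks are exact, and linear-algebra cross-checks
assert at 1e-8.

## Known limitations

- Geometric dwells: no heavy-tailed bout structure, no within-phase
  circadian drift, arousal frequency below published values.
- No waveform realism: band-power structure only; no spindles,
  K-complexes, movement artifacts, or epoch-boundary continuity.
- The EDF writer emits minimal two-channel 16-bit files (1-s records,
  per-channel physical scaling) sufficient for round-tripping this
  pipeline, not a general-purpose EDF+ implementation.
- The statistics module handles the balanced-within, two-group designs
  it was built for; it is not a general mixed-model engine.
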