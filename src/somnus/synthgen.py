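"""Synthetic hypnogram and EEG/EMG generator for a 12:12 light-dark mouse.

The state sequence is modelled as two phase-specific first-order Markov
chains on (WAKE, NREM, REM) at 10-s epoch resolution: one transition
matrix governs the light (rest) phase, another the dark (active) phase.
A chain of this form has geometric dwell times, so a small closed-form
calibration maps published sleep-architecture statistics (state
occupancy, bout counts and durations, time to resume sleep) onto the
two matrices; the shipped ``control`` and ``pab`` presets carry those
published group statistics and are calibrated at load time.

Signals are synthesised per epoch as sums of band-limited Gaussian
noise whose per-band variance follows the epoch's state, which is
exactly the structure the downstream spectral scorer consumes.  No
attempt is made at waveform-level realism (spindles, K-complexes).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .hypnogram import NREM, REM, WAKE, Hypnogram

__all__ = [
    "BandPowerParams",
    "PhaseTargets",
    "GeneratorConfig",
    "matrix_from_occupancy_dwell",
    "calibrate_phase",
    "calibrate_to_targets",
    "stationary_distribution",
    "simulate_hypnogram",
    "simulate_cohort",
    "synthesize_signals",
    "load_preset",
    "available_presets",
]

#: EEG analysis bands (Hz) shared with the features module
BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 9.0), "sigma": (10.0, 14.0)}

#: synthesis guard margin (Hz): band noise is placed this far inside each
#: nominal band so finite-window spectral estimates (Hann main lobe ~1 Hz
#: at 2-s segments) attribute the power to the correct band
BAND_GUARD_HZ = 0.5


@dataclass
class BandPowerParams:
    """Per-state spectral parameters.

    ``delta``/``theta``/``sigma`` are mean band powers in µV²; ``emg``
    is the mean EMG noise amplitude in µV; ``dispersion`` is the
    standard deviation of the log-normal epoch-to-epoch modulation
    applied to every band (natural-log scale).
    """

    delta: float
    theta: float
    sigma: float
    emg: float
    dispersion: float = 0.25

    def validate(self) -> None:
        for name in ("delta", "theta", "sigma", "emg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"band power parameter {name!r} must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class PhaseTargets:
    """Published per-phase (12-h light or dark) architecture statistics."""

    nrem_fraction: float          # fraction of phase time in NREM
    nrem_bout_min: float          # mean NREM bout duration, minutes
    rem_bout_count: float         # REM bouts per 12-h phase
    rem_bout_min: float           # mean REM bout duration, minutes
    resume_latency_min: float     # mean time to resume sleep, minutes


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a cohort.

    ``transition_light``/``transition_dark`` are row-stochastic 3x3
    matrices over (WAKE, NREM, REM).  ``delta_decline`` is the
    fractional decrease of NREM delta power from the start to the end
    of the light phase (0 disables the homeostatic ramp).
    """

    transition_light: np.ndarray
    transition_dark: np.ndarray
    band_power: dict[int, BandPowerParams] = field(default_factory=dict)
    epoch_length: float = 10.0
    sampling_rate: float = 100.0
    light_onset: float = 7.0
    photoperiod: tuple[float, float] = (12.0, 12.0)
    delta_decline: float = 0.0
    n_animals: int = 1
    duration_hours: float = 48.0
    seed: int = 0
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.transition_light = np.asarray(self.transition_light, dtype=float)
        self.transition_dark = np.asarray(self.transition_dark, dtype=float)

    def validate(self) -> None:
        for name, P in (("light", self.transition_light), ("dark", self.transition_dark)):
            if P.shape != (3, 3):
                raise ValueError(f"{name} transition matrix must be 3x3")
            if (P < 0).any():
                raise ValueError(f"{name} transition matrix has negative entries")
            if not np.allclose(P.sum(axis=1), 1.0, rtol=0, atol=1e-12):
                raise ValueError(f"{name} transition matrix rows must sum to 1")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        n_ep = self.duration_hours * 3600.0 / self.epoch_length
        if abs(n_ep - round(n_ep)) > 1e-9:
            raise ValueError("duration must be an integer number of epochs")
        if sum(self.photoperiod) != 24.0:
            raise ValueError("photoperiod must sum to 24 h")
        for bp in self.band_power.values():
            bp.validate()

    @property
    def n_epochs(self) -> int:
        return int(round(self.duration_hours * 3600.0 / self.epoch_length))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigenvector at 1)."""
    w, v = np.linalg.eig(np.asarray(P, float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def matrix_from_occupancy_dwell(occupancy, dwell_epochs) -> np.ndarray:
    """Closed-form 3-state chain with given stationary law and mean dwells.

    ``occupancy`` is the target stationary distribution over
    (WAKE, NREM, REM) and ``dwell_epochs`` the target mean run length of
    each state in epochs; the self-transition of state ``s`` is exactly
    ``1 - 1/dwell_epochs[s]``.  The off-diagonal (jump) probabilities
    are the exactly-stationary solution nearest to proportional entry
    (destination probability proportional to each state's entry flow),
    which for symmetric targets yields a symmetric matrix.  The
    remaining freedom is one-dimensional and is resolved by projecting
    the proportional solution onto the feasible interval.

    Raises
    ------
    ValueError
        If the targets are infeasible (a dwell below one epoch, or one
        state demanding more than half of all transitions).
    """
    pi = np.asarray(occupancy, dtype=float)
    D = np.asarray(dwell_epochs, dtype=float)
    if pi.shape != (3,) or D.shape != (3,):
        raise ValueError("occupancy and dwell_epochs must have length 3")
    if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must be strictly positive and sum to 1")
    if (D < 1).any():
        raise ValueError("mean dwell cannot be shorter than one epoch")
    exit_rate = 1.0 / D
    flow = pi * exit_rate
    phi = flow / flow.sum()          # jump-chain stationary distribution
    if (phi > 0.5 + 1e-12).any():
        s = int(np.argmax(phi))
        raise ValueError(
            f"infeasible targets: state {s} would carry {phi[s]:.3f} of all "
            "transitions (> 1/2); lengthen its dwell or raise its occupancy"
        )
    pW, pN, pR = phi
    # One-parameter family of zero-diagonal chains with stationary phi:
    #   x = q(W->R);  q(R->W) = (pW(1-x)+pR-pN)/pR;  q(N->W) = (pW x+pN-pR)/pN
    lo = max(0.0, 1.0 - pN / pW, (pR - pN) / pW)
    hi = min(1.0, (pW + pR - pN) / pW, pR / pW)
    if lo > hi + 1e-12:
        raise ValueError("no feasible jump chain for the requested targets")
    x = float(np.clip(pR / (1.0 - pW), lo, hi))   # proportional-entry preference
    q_rw = (pW * (1.0 - x) + pR - pN) / pR
    q_nw = (pW * x + pN - pR) / pN
    Q = np.array([
        [0.0, 1.0 - x, x],
        [q_nw, 0.0, 1.0 - q_nw],
        [q_rw, 1.0 - q_rw, 0.0],
    ])
    P = np.diag(1.0 - exit_rate) + exit_rate[:, None] * Q
    return np.clip(P, 0.0, 1.0)


def expected_resume_latency_epochs(P: np.ndarray) -> float:
    """Exact mean resume-sleep latency (in epochs) of a phase chain.

    The latency event starts at the onset of a wake run of >= 3 epochs
    and ends at the first epoch of the next run of 3 consecutive sleep
    epochs.  By memorylessness the onset condition fixes the first
    three epochs as wake, after which the latency equals the expected
    hitting time of "three consecutive sleep epochs" from wake, which
    solves a 5-state first-step linear system over (state,
    consecutive-sleep-count) pairs.
    """
    P = np.asarray(P, float)
    # augmented states: (W,0), (N,1), (N,2), (R,1), (R,2); count 3 absorbs
    idx = {(WAKE, 0): 0, (NREM, 1): 1, (NREM, 2): 2, (REM, 1): 3, (REM, 2): 4}
    A = np.eye(5)
    b = np.ones(5)
    for (s, c), i in idx.items():
        for s2 in (WAKE, NREM, REM):
            c2 = 0 if s2 == WAKE else c + 1
            if c2 < 3:
                A[i, idx[(s2, c2)]] -= P[s, s2]
    v = np.linalg.solve(A, b)
    return float(v[idx[(WAKE, 0)]])


def calibrate_phase(targets: PhaseTargets, epoch_length: float = 10.0,
                    phase_hours: float = 12.0, wake_margin: float = 1.02) -> np.ndarray:
    """Transition matrix for one photoperiod phase from published statistics.

    The mapping inverts the geometric-run model of the chain:

    * a bout of state ``s`` requires a run of at least ``m`` epochs
      (3 for NREM, 2 for REM), and a geometric run with mean ``D``
      conditioned on length >= m has mean ``m - 1 + D``; the target
      mean bout duration therefore sets ``D = duration_epochs - (m-1)``;
    * the REM occupancy is inferred from the target REM bout count,
      un-conditioning on the >= 2-epoch qualification;
    * NREM occupancy is taken directly from the published percentage;
    * the WAKE dwell is chosen so that the chain's exact expected
      resume-sleep latency (:func:`expected_resume_latency_epochs`)
      equals the published value, floored at the shortest dwell
      compatible with flow balance.
    """
    n_phase = phase_hours * 3600.0 / epoch_length
    ep_min = 60.0 / epoch_length                 # epochs per minute
    D_nrem = targets.nrem_bout_min * ep_min - 2.0
    D_rem = targets.rem_bout_min * ep_min - 1.0
    if D_nrem < 1 or D_rem < 1:
        raise ValueError("bout duration targets shorter than the minimum run")
    if not 0.0 < targets.nrem_fraction < 1.0:
        raise ValueError("nrem_fraction must be in (0, 1)")
    qualify = 1.0 - 1.0 / D_rem                  # P(run >= 2) under geometric
    if qualify <= 0:
        raise ValueError("REM bout duration target implies no qualifying bouts")
    n_runs_rem = targets.rem_bout_count / qualify
    pi_rem = n_runs_rem * D_rem / n_phase
    pi_nrem = targets.nrem_fraction
    pi_wake = 1.0 - pi_nrem - pi_rem
    if pi_wake <= 0:
        raise ValueError("occupancy targets exceed 100% of the phase")
    f_nrem, f_rem = pi_nrem / D_nrem, pi_rem / D_rem
    # flow balance bounds the wake dwell on both sides: no single state
    # may carry more than half of all jump-chain transitions
    d_floor = wake_margin * pi_wake / (f_nrem + f_rem)
    excess = max(f_nrem, f_rem) - min(f_nrem, f_rem)
    d_ceil = (pi_wake / (excess * wake_margin)) if excess > 0 else np.inf

    def build(d_wake):
        return matrix_from_occupancy_dwell(
            [pi_wake, pi_nrem, pi_rem], [d_wake, D_nrem, D_rem])

    target_epochs = targets.resume_latency_min * ep_min
    gap = lambda d: expected_resume_latency_epochs(build(d)) - target_epochs
    d_hi = min(max(10.0 * target_epochs, d_floor + 100.0), d_ceil)
    if gap(d_floor) >= 0.0:
        # latency target unreachable below the flow-balance floor
        d_wake = d_floor
    elif gap(d_hi) <= 0.0:
        d_wake = d_hi
    else:
        from scipy.optimize import brentq

        d_wake = brentq(gap, d_floor, d_hi, xtol=1e-6)
    return build(d_wake)


def calibrate_to_targets(light: PhaseTargets, dark: PhaseTargets,
                         epoch_length: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Calibrate both phase matrices; see :func:`calibrate_phase`."""
    return (calibrate_phase(light, epoch_length), calibrate_phase(dark, epoch_length))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _phase_light_mask(config: GeneratorConfig, start_hour: float | None = None) -> np.ndarray:
    start = config.light_onset if start_hour is None else start_hour
    t = (start + np.arange(config.n_epochs) * config.epoch_length / 3600.0) % 24.0
    rel = (t - config.light_onset) % 24.0
    return rel < config.photoperiod[0]


def simulate_cohort(config: GeneratorConfig, n_animals: int | None = None,
                    seed: int | None = None,
                    initial_state: int | None = None) -> list[Hypnogram]:
    """Simulate ``n_animals`` independent hypnograms (vectorised over animals).

    The recording starts at light onset; each chain is initialised from
    the stationary distribution of the light-phase matrix unless
    ``initial_state`` pins it.  Identical ``(config, seed)`` gives
    bit-identical output.
    """
    config.validate()
    n = config.n_animals if n_animals is None else int(n_animals)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    light = _phase_light_mask(config)
    cum_l = np.cumsum(config.transition_light, axis=1)
    cum_d = np.cumsum(config.transition_dark, axis=1)
    states = np.empty((n, config.n_epochs), dtype=np.int8)
    if initial_state is None:
        init = stationary_distribution(config.transition_light if light[0] else
                                       config.transition_dark)
        s = rng.choice(3, size=n, p=init).astype(np.int8)
    else:
        s = np.full(n, initial_state, dtype=np.int8)
    states[:, 0] = s
    for i in range(1, config.n_epochs):
        cum = cum_l if light[i] else cum_d
        u = rng.random(n)
        s = (u[:, None] > cum[s]).sum(axis=1).astype(np.int8)
        states[:, i] = s
    return [
        Hypnogram(states[a], epoch_length=config.epoch_length,
                  start_hour=config.light_onset, light_onset=config.light_onset,
                  light_hours=config.photoperiod[0])
        for a in range(n)
    ]


def simulate_hypnogram(config: GeneratorConfig, seed: int,
                       initial_state: int | None = None) -> Hypnogram:
    """Single-animal wrapper around :func:`simulate_cohort`."""
    return simulate_cohort(config, n_animals=1, seed=seed,
                           initial_state=initial_state)[0]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _band_limited_noise(rng: np.random.Generator, n_epochs: int, n_samp: int,
                        fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise per epoch with spectral support in ``band``."""
    white = rng.standard_normal((n_epochs, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, 1.0 / fs)
    mask = (f >= band[0] + BAND_GUARD_HZ) & (f <= band[1] - BAND_GUARD_HZ)
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _delta_ramp(h: Hypnogram, decline: float, light_hours: float) -> np.ndarray:
    """Multiplier on NREM delta power: 1 at light onset, 1-decline at light end."""
    mult = np.ones(h.n_epochs)
    if decline == 0:
        return mult
    rel = (h.hour_of_day - h.light_onset) % 24.0
    in_light = rel < light_hours
    mult[in_light] = 1.0 - decline * rel[in_light] / light_hours
    return mult


def synthesize_signals(h: Hypnogram, config: GeneratorConfig, seed: int):
    """Render EEG and EMG (µV) for a scored hypnogram.

    Per epoch the EEG is a sum of three band-limited noise components
    whose variances follow the epoch's state parameters, each modulated
    by an independent log-normal factor of the configured dispersion
    (mean 1).  NREM delta power is additionally scaled by a linear
    homeostatic ramp across the light period (``delta_decline``).  The
    EMG is white noise with state-dependent amplitude.

    Returns a :class:`somnus.sigio.Recording`.
    """
    from .sigio import Recording  # local import to avoid a cycle

    config.validate()
    if not config.band_power:
        raise ValueError("config.band_power is empty; nothing to synthesise")
    fs = config.sampling_rate
    if fs / 2.0 <= BANDS["sigma"][1]:
        raise ValueError(
            f"sampling_rate {fs} Hz cannot represent the sigma band "
            f"(Nyquist must exceed {BANDS['sigma'][1]} Hz)"
        )
    n_samp = int(round(config.epoch_length * fs))
    if abs(config.epoch_length * fs - n_samp) > 1e-9:
        raise ValueError("epoch_length times sampling_rate must be integral")
    n_ep = h.n_epochs
    rng = np.random.default_rng(seed)
    st = h.states
    disp = np.array([config.band_power[s].dispersion for s in (WAKE, NREM, REM)])[st]

    ramp = _delta_ramp(h, config.delta_decline, config.photoperiod[0])
    eeg = np.zeros((n_ep, n_samp))
    for band_name, band in BANDS.items():
        mean_power = np.array(
            [getattr(config.band_power[s], band_name) for s in (WAKE, NREM, REM)]
        )[st]
        if band_name == "delta":
            mean_power = np.where(st == NREM, mean_power * ramp, mean_power)
        lognorm = np.exp(disp * rng.standard_normal(n_ep) - disp**2 / 2.0)
        noise = _band_limited_noise(rng, n_ep, n_samp, fs, band)
        eeg += np.sqrt(mean_power * lognorm)[:, None] * noise

    emg_amp = np.array([config.band_power[s].emg for s in (WAKE, NREM, REM)])[st]
    emg_lognorm = np.exp(disp * rng.standard_normal(n_ep) - disp**2 / 2.0)
    emg = (emg_amp * emg_lognorm)[:, None] * rng.standard_normal((n_ep, n_samp))

    return Recording(
        eeg=eeg.ravel(), emg=emg.ravel(), sampling_rate=fs,
        start_hour=h.start_hour, light_onset=h.light_onset,
        light_hours=h.light_hours, group_label=config.group_label,
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _config_from_dict(doc: dict) -> GeneratorConfig:
    tl = doc["targets"]["light"]
    td = doc["targets"]["dark"]
    light = PhaseTargets(**tl)
    dark = PhaseTargets(**td)
    P_light, P_dark = calibrate_to_targets(light, dark, doc.get("epoch_length", 10.0))
    band_power = {}
    key_to_state = {"wake": WAKE, "nrem": NREM, "rem": REM}
    for key, params in doc.get("band_power", {}).items():
        band_power[key_to_state[key]] = BandPowerParams(**params)
    return GeneratorConfig(
        transition_light=P_light,
        transition_dark=P_dark,
        band_power=band_power,
        epoch_length=doc.get("epoch_length", 10.0),
        sampling_rate=doc.get("sampling_rate", 100.0),
        light_onset=doc.get("light_onset", 7.0),
        photoperiod=tuple(doc.get("photoperiod", (12.0, 12.0))),
        delta_decline=doc.get("delta_decline", 0.0),
        n_animals=doc.get("n_animals", 1),
        duration_hours=doc.get("duration_hours", 48.0),
        seed=doc.get("seed", 0),
        group_label=doc.get("group", "unknown"),
    )


def load_preset(name_or_path: str) -> GeneratorConfig:
    """Load a generator configuration.

    ``name_or_path`` is either the name of a shipped preset
    (``"control"`` or ``"pab"``) or a path to a YAML file of the same
    layout.  Shipped presets store the published group statistics; the
    phase transition matrices are calibrated from them at load time.
    """
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml", ".cfg"} or path.exists():
        text = path.read_text()
    else:
        res = importlib.resources.files("somnus") / "presets" / f"{name_or_path}.yaml"
        if not res.is_file():
            raise FileNotFoundError(
                f"unknown preset {name_or_path!r}; available: {available_presets()}"
            )
        text = res.read_text()
    return _config_from_dict(yaml.safe_load(text))


def available_presets() -> list[str]:
    root = importlib.resources.files("somnus") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                  if p.name.endswith(".yaml"))
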