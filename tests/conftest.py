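from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from somnus import NREM, REM, WAKE, Hypnogram, load_preset
from somnus.hypnogram import CODE_TO_STATE


@pytest.fixture(scope="session")
def control_config():
    return load_preset("control")


@pytest.fixture(scope="session")
def pab_config():
    return load_preset("pab")


def hyp(codes: str, **kwargs) -> Hypnogram:
    """Build a hypnogram from a 'WNR' string, defaulting to 10-s epochs."""
    states = np.array([CODE_TO_STATE[c] for c in codes], dtype=np.int8)
    return Hypnogram(states, **kwargs)


def features_frame(delta, theta, sigma, emg, epoch_length=10.0,
                   start_hour=7.0) -> pd.DataFrame:
    """Hand-built epoch-feature table with consistent metadata."""
    n = len(delta)
    idx = np.arange(n)
    clock = (start_hour + idx * epoch_length / 3600.0) % 24.0
    df = pd.DataFrame({
        "epoch_index": idx,
        "clock_time": clock,
        "light_flag": ((clock - 7.0) % 24.0) < 12.0,
        "delta_power": np.asarray(delta, float),
        "theta_power": np.asarray(theta, float),
        "sigma_power": np.asarray(sigma, float),
        "emg_amp": np.asarray(emg, float),
    })
    df.attrs.update({"epoch_length": epoch_length, "start_hour": start_hour,
                     "light_onset": 7.0, "light_hours": 12.0})
    return df


def features_from_state_params(h: Hypnogram, config, seed: int) -> pd.DataFrame:
    """Draw per-epoch features directly from the generator's band-power
    model (log-normal modulation around the per-state means), bypassing
    signal synthesis; used to test scoring at hypnogram scale."""
    rng = np.random.default_rng(seed)
    st = h.states
    cols = {}
    for name in ("delta", "theta", "sigma", "emg"):
        mean = np.array([getattr(config.band_power[s], name)
                         for s in (WAKE, NREM, REM)])[st]
        disp = np.array([config.band_power[s].dispersion
                         for s in (WAKE, NREM, REM)])[st]
        cols[name] = mean * np.exp(disp * rng.standard_normal(h.n_epochs)
                                   - disp**2 / 2)
    return features_frame(cols["delta"], cols["theta"], cols["sigma"],
                          cols["emg"], epoch_length=h.epoch_length,
                          start_hour=h.start_hour)
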