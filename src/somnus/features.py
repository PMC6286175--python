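"""Per-epoch spectral features: delta/theta/sigma band power and EMG amplitude.

Band power is the integral of the Welch power spectral density over the
band (Hann window, 2-s segments, 50% overlap), so a pure tone of
amplitude A inside a band contributes its variance A²/2 to that band.
The EMG amplitude is the epoch mean of the rectified signal after a
1-s moving average.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .sigio import Recording

__all__ = ["BANDS", "bandpower_epochs"]

#: analysis bands in Hz: slow-wave, theta, and spindle-range activity
BANDS = {"delta": (0.5, 4.0), "theta": (6.0, 9.0), "sigma": (10.0, 14.0)}

_EMG_SMOOTH_SECONDS = 1.0


def _band_integral(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Trapezoidal integral of the PSD over ``band`` (inclusive edges)."""
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if mask.sum() < 2:
        return np.zeros(psd.shape[0])
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def bandpower_epochs(rec: Recording, epoch_length: float = 10.0) -> pd.DataFrame:
    """Per-epoch band powers (µV²) and EMG amplitude (µV).

    The recording is cut into consecutive ``epoch_length``-second
    epochs (trailing partial epoch discarded).  Returns a DataFrame
    with one row per epoch and columns ``epoch_index``, ``clock_time``,
    ``light_flag``, ``delta_power``, ``theta_power``, ``sigma_power``,
    ``emg_amp``; recording metadata is kept in ``DataFrame.attrs``.

    Raises
    ------
    ValueError
        If the Nyquist frequency does not exceed the sigma band, the
        recording is shorter than one epoch, or a NaN sample occurs
        (the error names the offending epoch).
    """
    fs = rec.sampling_rate
    if fs / 2.0 <= BANDS["sigma"][1]:
        raise ValueError(
            f"Nyquist frequency {fs / 2:.1f} Hz must exceed "
            f"{BANDS['sigma'][1]} Hz to resolve the sigma band"
        )
    n_samp = int(round(epoch_length * fs))
    n_ep = rec.n_samples // n_samp
    if n_ep < 1:
        raise ValueError("recording shorter than one epoch")

    eeg = rec.eeg[: n_ep * n_samp].reshape(n_ep, n_samp)
    emg = rec.emg[: n_ep * n_samp].reshape(n_ep, n_samp)
    for name, x in (("eeg", eeg), ("emg", emg)):
        bad = np.flatnonzero(np.isnan(x).any(axis=1))
        if bad.size:
            raise ValueError(f"NaN samples in {name} at epoch {int(bad[0])}")

    nperseg = min(n_samp, int(round(2.0 * fs)))
    freqs, psd = signal.welch(
        eeg, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, axis=1, detrend=False,
    )
    powers = {name: _band_integral(freqs, psd, band) for name, band in BANDS.items()}

    smooth = max(1, int(round(_EMG_SMOOTH_SECONDS * fs)))
    rectified = np.abs(emg)
    smoothed = ndimage.uniform_filter1d(rectified, size=smooth, axis=1, mode="nearest")
    emg_amp = smoothed.mean(axis=1)

    idx = np.arange(n_ep)
    clock = (rec.start_hour + idx * epoch_length / 3600.0) % 24.0
    rel = (clock - rec.light_onset) % 24.0
    df = pd.DataFrame({
        "epoch_index": idx,
        "clock_time": clock,
        "light_flag": rel < rec.light_hours,
        "delta_power": powers["delta"],
        "theta_power": powers["theta"],
        "sigma_power": powers["sigma"],
        "emg_amp": emg_amp,
    })
    df.attrs.update({
        "epoch_length": epoch_length,
        "start_hour": rec.start_hour,
        "light_onset": rec.light_onset,
        "light_hours": rec.light_hours,
        "animal_id": rec.animal_id,
        "group_label": rec.group_label,
    })
    return df
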