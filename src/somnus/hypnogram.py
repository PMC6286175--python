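"""Sleep-state sequences scored on a fixed epoch grid.

States are coded as small integers (WAKE=0, NREM=1, REM=2) so that
hypnograms can live in compact ``int8`` arrays; the single-letter codes
``W``/``N``/``R`` are used in every text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

WAKE: int = 0
NREM: int = 1
REM: int = 2

#: index -> single-letter state code used in CSV files
STATE_CODES = "WNR"
STATE_NAMES = ("WAKE", "NREM", "REM")
CODE_TO_STATE = {c: i for i, c in enumerate(STATE_CODES)}


@dataclass
class Hypnogram:
    """An epoch-resolution Wake/NREM/REM sequence with clock metadata.

    Parameters
    ----------
    states
        Integer array over {WAKE, NREM, REM}, one entry per epoch.
    epoch_length
        Epoch duration in seconds (10 s for standard rodent scoring).
    start_hour
        Clock hour (0-24) at which epoch 0 starts.
    light_onset
        Clock hour at which the light phase begins.
    light_hours
        Duration of the light phase in hours (12 for a 12:12 cycle).
    """

    states: np.ndarray
    epoch_length: float = 10.0
    start_hour: float = 7.0
    light_onset: float = 7.0
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("hypnogram must be a non-empty 1-d sequence")
        if not np.isin(self.states, (WAKE, NREM, REM)).all():
            bad = int(np.flatnonzero(~np.isin(self.states, (WAKE, NREM, REM)))[0])
            raise ValueError(f"unknown state code at epoch {bad}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_length / 3600.0

    @property
    def epochs_per_day(self) -> int:
        return int(round(86400.0 / self.epoch_length))

    @property
    def hour_of_day(self) -> np.ndarray:
        """Clock hour at the *start* of each epoch (epochs are [t, t+len))."""
        t = self.start_hour + np.arange(self.n_epochs) * self.epoch_length / 3600.0
        return t % 24.0

    @property
    def light_mask(self) -> np.ndarray:
        """True for epochs whose start falls in the light phase."""
        rel = (self.hour_of_day - self.light_onset) % 24.0
        return rel < self.light_hours

    @property
    def day_index(self) -> np.ndarray:
        """0-based 24-h block index of each epoch, counted from epoch 0."""
        return (np.arange(self.n_epochs) // self.epochs_per_day).astype(np.int64)

    def slice(self, start: int, stop: int) -> "Hypnogram":
        """Sub-hypnogram over epochs [start, stop) with shifted clock."""
        new_start = (self.start_hour + start * self.epoch_length / 3600.0) % 24.0
        return replace(self, states=self.states[start:stop], start_hour=new_start)

    def to_codes(self) -> list[str]:
        return [STATE_CODES[s] for s in self.states]


def run_length_encode(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximal-run encoding of a state sequence.

    Returns ``(values, starts, lengths)`` for each maximal run of a
    constant state, scanning left to right.
    """
    x = np.asarray(states)
    if x.size == 0:
        return (np.empty(0, x.dtype), np.empty(0, np.int64), np.empty(0, np.int64))
    change = np.flatnonzero(np.diff(x) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [x.size])))
    return x[starts], starts, lengths
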