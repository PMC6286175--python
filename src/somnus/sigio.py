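"""Reading and writing recordings, hypnograms, and epoch-feature tables.

Signals travel as EDF (the open polysomnography interchange format) or
as plain CSV with ``time, eeg, emg`` columns; hypnograms as CSV with
``epoch_index, clock_time, state`` rows using the W/N/R codes.  All
writers and readers are exact inverses up to the documented EDF 16-bit
quantisation of the physical range.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import CODE_TO_STATE, STATE_CODES, Hypnogram

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
]


@dataclass
class Recording:
    """A two-channel EEG + nuchal EMG recording in microvolts."""

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    start_hour: float = 7.0
    light_onset: float = 7.0
    light_hours: float = 12.0
    animal_id: str = ""
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape or self.eeg.ndim != 1:
            raise ValueError("eeg and emg must be 1-d arrays of equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.eeg.size)

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a two-signal EDF file (16-bit, per-channel physical scaling).

    One data record per second; physical range set per channel from the
    data, so the quantisation step is ``(max - min) / 65535`` µV.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        raise ValueError("signal length must be a whole number of seconds")
    channels = [("eeg", rec.eeg), ("emg", rec.emg)]
    ns = len(channels)
    start = _dt.datetime(2000, 1, 1) + _dt.timedelta(hours=rec.start_hour)

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(rec.animal_id or "X", 80),
        _edf_field(
            f"Startdate 01-JAN-2000 group={rec.group_label} "
            f"light_onset={rec.light_onset} light_hours={rec.light_hours} "
            f"start_hour={rec.start_hour}",
            80,
        ),
        _edf_field(start.strftime("%d.%m.%y"), 8),
        _edf_field(start.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field("1", 8),
        _edf_field(ns, 4),
    ])

    digital = []
    phys = []
    for _, x in channels:
        lo = float(np.min(x)) if x.size else -1.0
        hi = float(np.max(x)) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys.append((lo, hi))
        scale = (hi - lo) / 65535.0
        d = np.round((x - lo) / scale - 32768.0).astype("<i2")
        digital.append(d)

    def per_signal(fmt_width, values):
        return b"".join(_edf_field(v, fmt_width) for v in values)

    header += per_signal(16, [name.upper() for name, _ in channels])
    header += per_signal(80, [""] * ns)
    header += per_signal(8, ["uV"] * ns)
    header += per_signal(8, [f"{lo:.7g}"[:8] for lo, _ in phys])
    header += per_signal(8, [f"{hi:.7g}"[:8] for _, hi in phys])
    header += per_signal(8, [-32768] * ns)
    header += per_signal(8, [32767] * ns)
    header += per_signal(80, [""] * ns)
    header += per_signal(8, [spr] * ns)
    header += per_signal(32, [""] * ns)

    records = np.empty((n_rec, ns, spr), dtype="<i2")
    for c, d in enumerate(digital):
        records[:, c, :] = d.reshape(n_rec, spr)
    path.write_bytes(header + records.tobytes())


def _read_edf(path: Path, channel_map: dict[str, str]) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = {n.lower(): n for n in raw.ch_names}
    channels = {}
    for want in ("eeg", "emg"):
        key = channel_map.get(want, want).lower()
        if key not in names:
            raise ValueError(
                f"EDF file {path} is missing required channel {want!r} "
                f"(looked for {key!r}; present: {sorted(names)})"
            )
        channels[want] = raw.get_data(picks=[names[key]], units="uV")[0]
    meta = {"group": "unknown", "light_onset": 7.0, "light_hours": 12.0,
            "start_hour": None}
    # the 80-byte EDF "local recording identification" header field carries
    # our key=value metadata; mne does not expose it, so fetch it directly
    with open(path, "rb") as fh:
        fh.seek(88)
        info_str = fh.read(80).decode("ascii", errors="replace")
    for tok in str(info_str).split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            if k in ("light_onset", "light_hours", "start_hour"):
                meta[k] = float(v)
            elif k == "group":
                meta["group"] = v
    if meta["start_hour"] is None:
        t = raw.info.get("meas_date")
        meta["start_hour"] = (t.hour + t.minute / 60 + t.second / 3600) if t else 7.0
    return Recording(
        eeg=channels["eeg"], emg=channels["emg"],
        sampling_rate=float(raw.info["sfreq"]),
        start_hour=meta["start_hour"], light_onset=meta["light_onset"],
        light_hours=meta["light_hours"], group_label=meta["group"],
        animal_id=path.stem,
    )


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------

def write_csv_recording(rec: Recording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame({"time": t, "eeg": rec.eeg, "emg": rec.emg})
    with open(path, "w") as fh:
        fh.write(
            f"# sampling_rate={rec.sampling_rate} start_hour={rec.start_hour} "
            f"light_onset={rec.light_onset} light_hours={rec.light_hours} "
            f"group={rec.group_label}\n"
        )
        df.to_csv(fh, index=False, float_format="%.6f")


def _read_csv_recording(path: Path) -> Recording:
    meta = {"sampling_rate": None, "start_hour": 7.0, "light_onset": 7.0,
            "light_hours": 12.0, "group": "unknown"}
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first.lstrip("#").split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                if k in meta:
                    meta[k] = v if k == "group" else float(v)
    df = pd.read_csv(path, skiprows=skip)
    for col in ("eeg", "emg"):
        if col not in df.columns:
            raise ValueError(f"CSV recording {path} is missing column {col!r}")
    if meta["sampling_rate"] is None:
        if "time" not in df.columns or len(df) < 2:
            raise ValueError("cannot infer sampling rate: no time column")
        meta["sampling_rate"] = 1.0 / float(np.median(np.diff(df["time"])))
    return Recording(
        eeg=df["eeg"].to_numpy(), emg=df["emg"].to_numpy(),
        sampling_rate=float(meta["sampling_rate"]),
        start_hour=float(meta["start_hour"]),
        light_onset=float(meta["light_onset"]),
        light_hours=float(meta["light_hours"]),
        group_label=str(meta["group"]), animal_id=path.stem,
    )


def read_recording(path: str | Path, format: str | None = None,
                   channel_map: dict[str, str] | None = None) -> Recording:
    """Read an EDF or CSV recording; format inferred from the suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf(path, channel_map or {})
    if fmt == "csv":
        return _read_csv_recording(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "csv":
        write_csv_recording(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# epoch_length={h.epoch_length} start_hour={h.start_hour} "
            f"light_onset={h.light_onset} light_hours={h.light_hours}\n"
        )
        fh.write("epoch_index,clock_time,state\n")
        hours = h.hour_of_day
        for i, (t, s) in enumerate(zip(hours, h.states)):
            fh.write(f"{i},{t:.6f},{STATE_CODES[s]}\n")


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a W/N/R hypnogram CSV; errors cite the offending data row."""
    path = Path(path)
    meta = {"epoch_length": 10.0, "start_hour": 7.0, "light_onset": 7.0,
            "light_hours": 12.0}
    states: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln.lstrip("#").split():
                if "=" in tok:
                    k, _, v = tok.partition("=")
                    if k in meta:
                        meta[k] = float(v)
        elif ln.strip():
            body.append(ln)
    if body and body[0].lower().startswith("epoch_index"):
        body = body[1:]
    if not body:
        raise ValueError(f"hypnogram file {path} contains no epochs")
    for row_no, ln in enumerate(body, start=1):
        code = ln.split(",")[-1].strip().upper()
        if code not in CODE_TO_STATE:
            raise ValueError(
                f"unknown state code {code!r} at row {row_no} of {path}"
            )
        states.append(CODE_TO_STATE[code])
    return Hypnogram(np.array(states, dtype=np.int8), **meta)
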