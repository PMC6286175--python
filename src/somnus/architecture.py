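"""Sleep-architecture metrics computed from a scored hypnogram.

The rule set mirrors standard rodent scoring conventions on 10-s
epochs:

* a NREM bout begins with >= 3 consecutive NREM epochs and ends at the
  first subsequent run of >= 3 wake epochs or >= 2 REM epochs;
* a REM bout begins with >= 2 consecutive REM epochs and ends at the
  first subsequent run of >= 3 wake or >= 3 NREM epochs;
* shorter interruptions remain inside the bout; by default a bout's
  duration spans from its first to its last own-state epoch inclusive
  of interior interruptions (``interruptions="span"``); the stricter
  own-state-epochs-only accounting is available via
  ``interruptions="own"``;
* an arousal is a maximal wake run immediately preceded by >= 3
  consecutive sleep (NREM or REM, in any combination) epochs;
* time to resume sleep runs from the onset of a >= 3-epoch wake run to
  the start of the next 3 consecutive sleep epochs; events unresolved
  at the end of the recording are excluded.

For multi-day recordings every per-period metric is computed per 24-h
day and then averaged within animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import NREM, REM, WAKE, Hypnogram, run_length_encode

__all__ = [
    "Bout",
    "detect_bouts",
    "detect_arousals",
    "resume_latency",
    "resume_latency_events",
    "state_percentages",
    "circadian_profile",
    "delta_density",
    "summarize_hypnogram",
    "summarize_cohort",
]

_MIN_START = {NREM: 3, REM: 2}
# run length of the *other* sleep state that terminates a bout
_MIN_TERM_OTHER = {NREM: 2, REM: 3}
_MIN_TERM_WAKE = 3
_MIN_WAKE_RUN = 3
_SLEEP_RUN = 3


@dataclass
class Bout:
    """A single NREM or REM sleep bout (epoch indices inclusive)."""

    state: int
    start_epoch: int
    end_epoch: int
    own_epochs: int          # epochs of the bout's own state inside the span
    duration_min: float

    @property
    def n_epochs(self) -> int:
        return self.end_epoch - self.start_epoch + 1


def detect_bouts(h: Hypnogram, state: int | None = None,
                 interruptions: str = "span") -> list[Bout]:
    """Scan for sleep bouts of ``state`` (both sleep states if None).

    ``interruptions="span"`` (default) counts a bout's duration from
    its first to its last own-state epoch, interior interruptions
    included; ``"own"`` counts only own-state epochs.
    """
    if interruptions not in ("span", "own"):
        raise ValueError("interruptions must be 'span' or 'own'")
    if state is None:
        both = detect_bouts(h, NREM, interruptions) + detect_bouts(h, REM, interruptions)
        return sorted(both, key=lambda b: b.start_epoch)
    if state not in (_MIN_START):
        raise ValueError("bouts are defined for NREM and REM only")

    other = REM if state == NREM else NREM
    vals, starts, lengths = run_length_encode(h.states)
    bouts: list[Bout] = []
    open_start = None
    last_own_end = None
    own_count = 0
    for v, s, ln in zip(vals, starts, lengths):
        if v == state:
            if open_start is None and ln >= _MIN_START[state]:
                open_start = int(s)
                own_count = 0
            if open_start is not None:
                last_own_end = int(s + ln - 1)
                own_count += int(ln)
        elif open_start is not None:
            terminates = (v == WAKE and ln >= _MIN_TERM_WAKE) or (
                v == other and ln >= _MIN_TERM_OTHER[state]
            )
            if terminates:
                bouts.append(_close(state, open_start, last_own_end, own_count,
                                    interruptions, h.epoch_length))
                open_start = last_own_end = None
                own_count = 0
    if open_start is not None:
        bouts.append(_close(state, open_start, last_own_end, own_count,
                            interruptions, h.epoch_length))
    return bouts


def _close(state, start, end, own, interruptions, epoch_length) -> Bout:
    n = own if interruptions == "own" else (end - start + 1)
    return Bout(state=state, start_epoch=start, end_epoch=end,
                own_epochs=own, duration_min=n * epoch_length / 60.0)


def detect_arousals(h: Hypnogram) -> tuple[int, float]:
    """Arousal count and index (events per hour of sleep).

    An arousal is a maximal wake run whose three immediately preceding
    epochs are all sleep.  The index is count / total sleep hours over
    the hypnogram; with zero sleep time it is reported as NaN.
    """
    onsets = arousal_onsets(h)
    sleep_hours = float(np.sum(h.states != WAKE)) * h.epoch_length / 3600.0
    index = len(onsets) / sleep_hours if sleep_hours > 0 else float("nan")
    return len(onsets), index


def arousal_onsets(h: Hypnogram) -> np.ndarray:
    """Epoch indices at which an arousal (as defined above) begins."""
    x = h.states
    vals, starts, _ = run_length_encode(x)
    out = []
    for v, s in zip(vals, starts):
        if v == WAKE and s >= _SLEEP_RUN and np.all(x[s - _SLEEP_RUN:s] != WAKE):
            out.append(int(s))
    return np.asarray(out, dtype=np.int64)


def resume_latency_events(h: Hypnogram) -> list[tuple[int, int]]:
    """(onset_epoch, latency_epochs) for each resolved resume-sleep event.

    One event per wake run of >= 3 epochs; the latency target is the
    first epoch of the next run of 3 consecutive sleep epochs.  Events
    with no subsequent qualifying sleep are censored and omitted.
    """
    x = h.states
    sleep = (x != WAKE).astype(np.int8)
    if x.size >= _SLEEP_RUN:
        ok = np.convolve(sleep, np.ones(_SLEEP_RUN, dtype=int), mode="valid") == _SLEEP_RUN
        qualifying = np.flatnonzero(ok)          # start indices of sleep triples
    else:
        qualifying = np.empty(0, np.int64)
    vals, starts, lengths = run_length_encode(x)
    events = []
    for v, s, ln in zip(vals, starts, lengths):
        if v == WAKE and ln >= _MIN_WAKE_RUN:
            nxt = qualifying[np.searchsorted(qualifying, s)] if (
                np.searchsorted(qualifying, s) < qualifying.size) else None
            if nxt is not None:
                events.append((int(s), int(nxt - s)))
    return events


def resume_latency(h: Hypnogram) -> float:
    """Mean resume-sleep latency in minutes (NaN if no resolved events)."""
    events = resume_latency_events(h)
    if not events:
        return float("nan")
    return float(np.mean([lat for _, lat in events])) * h.epoch_length / 60.0


# ---------------------------------------------------------------------------
# occupancy and profiles
# ---------------------------------------------------------------------------

def _period_mask(h: Hypnogram, period: str) -> np.ndarray:
    if period == "24h":
        return np.ones(h.n_epochs, dtype=bool)
    if period == "light":
        return h.light_mask
    if period == "dark":
        return ~h.light_mask
    raise ValueError(f"unknown period {period!r}; use 'light', 'dark' or '24h'")


def state_percentages(h: Hypnogram, period: str = "24h") -> tuple[float, float, float]:
    """(pct_wake, pct_nrem, pct_rem) of epochs within the requested period."""
    mask = _period_mask(h, period)
    if not mask.any():
        raise ValueError(f"hypnogram does not cover the {period!r} period")
    x = h.states[mask]
    n = x.size
    return tuple(100.0 * float(np.sum(x == s)) / n for s in (WAKE, NREM, REM))


def circadian_profile(h: Hypnogram, bin_hours: float = 2.0) -> pd.DataFrame:
    """Per-clock-bin state percentages, bins aligned to light onset.

    Requires >= 24 h of data; multi-day recordings pool epochs of the
    same clock bin across days.  Returns one row per bin with
    ``bin_start_hours`` relative to light onset.
    """
    if 24.0 % bin_hours != 0:
        raise ValueError("bin width must divide 24 h")
    if h.duration_hours < 24.0 - 1e-9:
        raise ValueError("circadian profile requires at least 24 h")
    rel = (h.hour_of_day - h.light_onset) % 24.0
    bin_idx = np.floor(rel / bin_hours).astype(int)
    n_bins = int(24.0 / bin_hours)
    rows = []
    for b in range(n_bins):
        x = h.states[bin_idx == b]
        n = x.size
        rows.append({
            "bin_start_hours": b * bin_hours,
            "pct_wake": 100.0 * np.sum(x == WAKE) / n,
            "pct_nrem": 100.0 * np.sum(x == NREM) / n,
            "pct_rem": 100.0 * np.sum(x == REM) / n,
            "n_epochs": n,
        })
    return pd.DataFrame(rows)


def delta_density(features: pd.DataFrame, h: Hypnogram,
                  bin_hours: float = 2.0) -> pd.DataFrame:
    """Normalised NREM delta-power profile on a 2-h clock grid.

    Per bin, the raw value is the mean delta power over NREM-scored
    epochs (multi-day recordings: per-day bin means averaged across
    days first); the normalised value divides by the mean of the raw
    profile over non-missing bins, so the normalised profile averages
    exactly 1.  Bins with no NREM epochs are NaN, never zero.
    """
    if len(features) != h.n_epochs:
        raise ValueError(
            f"features ({len(features)} epochs) and hypnogram "
            f"({h.n_epochs} epochs) are not aligned"
        )
    if 24.0 % bin_hours != 0:
        raise ValueError("bin width must divide 24 h")
    n_bins = int(24.0 / bin_hours)
    rel = (h.hour_of_day - h.light_onset) % 24.0
    bin_idx = np.floor(rel / bin_hours).astype(int)
    day = h.day_index
    delta = features["delta_power"].to_numpy(float)
    nrem = h.states == NREM

    raw = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        day_means = []
        for d in np.unique(day):
            m = nrem & (bin_idx == b) & (day == d)
            counts[b] += int(m.sum())
            if m.any():
                day_means.append(delta[m].mean())
        if day_means:
            raw[b] = float(np.mean(day_means))
    norm = raw / np.nanmean(raw)
    return pd.DataFrame({
        "bin_start_hours": np.arange(n_bins) * bin_hours,
        "raw_delta": raw,
        "normalized_delta": norm,
        "n_nrem_epochs": counts,
    })


# ---------------------------------------------------------------------------
# per-animal summaries
# ---------------------------------------------------------------------------

_SUMMARY_KEYS = (
    "pct_wake", "pct_nrem", "pct_rem", "n_nrem_bouts", "n_rem_bouts",
    "mean_nrem_bout_min", "mean_rem_bout_min", "arousal_index",
    "mean_resume_latency_min",
)


def _day_summary(h: Hypnogram, period: str) -> dict[str, float]:
    mask = _period_mask(h, period)
    if not mask.any():
        # recording does not reach this period (e.g. a light-phase-only clip)
        return {k: float("nan") for k in _SUMMARY_KEYS}
    pw, pn, pr = state_percentages(h, period)
    nrem_bouts = [b for b in detect_bouts(h, NREM) if mask[b.start_epoch]]
    rem_bouts = [b for b in detect_bouts(h, REM) if mask[b.start_epoch]]
    onsets = arousal_onsets(h)
    n_arousals = int(np.sum(mask[onsets])) if onsets.size else 0
    sleep_hours = float(np.sum((h.states != WAKE) & mask)) * h.epoch_length / 3600.0
    events = [(o, lat) for o, lat in resume_latency_events(h) if mask[o]]
    lat_min = (np.mean([lat for _, lat in events]) * h.epoch_length / 60.0
               if events else np.nan)
    return {
        "pct_wake": pw, "pct_nrem": pn, "pct_rem": pr,
        "n_nrem_bouts": float(len(nrem_bouts)),
        "n_rem_bouts": float(len(rem_bouts)),
        "mean_nrem_bout_min": (np.mean([b.duration_min for b in nrem_bouts])
                               if nrem_bouts else np.nan),
        "mean_rem_bout_min": (np.mean([b.duration_min for b in rem_bouts])
                              if rem_bouts else np.nan),
        "arousal_index": (n_arousals / sleep_hours if sleep_hours > 0 else np.nan),
        "mean_resume_latency_min": lat_min,
    }


def summarize_hypnogram(h: Hypnogram, animal_id: str = "",
                        group: str = "unknown") -> pd.DataFrame:
    """One row per period (light, dark, 24h) of architecture metrics.

    Multi-day recordings are summarised per 24-h day and averaged
    within the animal, matching how per-animal values are reported for
    consecutive recording days.
    """
    epd = h.epochs_per_day
    n_days = max(1, h.n_epochs // epd)
    rows = []
    for period in ("light", "dark", "24h"):
        day_rows = [
            _day_summary(h.slice(d * epd, min((d + 1) * epd, h.n_epochs)), period)
            for d in range(n_days)
        ]
        mean_row = {}
        for k in day_rows[0]:
            vals = [r[k] for r in day_rows if not np.isnan(r[k])]
            mean_row[k] = float(np.mean(vals)) if vals else float("nan")
        mean_row.update({"animal_id": animal_id, "group": group, "period": period})
        rows.append(mean_row)
    df = pd.DataFrame(rows)
    front = ["animal_id", "group", "period"]
    return df[front + [c for c in df.columns if c not in front]]


def summarize_cohort(hypnograms: list[Hypnogram], group: str = "unknown",
                     animal_ids: list[str] | None = None) -> pd.DataFrame:
    """Concatenated :func:`summarize_hypnogram` over a cohort."""
    ids = animal_ids or [f"{group}_{i:02d}" for i in range(len(hypnograms))]
    return pd.concat(
        [summarize_hypnogram(h, a, group) for h, a in zip(hypnograms, ids)],
        ignore_index=True,
    )
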