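"""Two-plane threshold scoring of 10-s epochs into Wake/NREM/REM.

An epoch is scored SLEEP when its sigma*theta power lies above a
discriminant line drawn against EMG amplitude; a sleep epoch is NREM
when its delta/theta ratio reaches a scalar threshold, otherwise REM.
Thresholding is done on log-transformed features by default (band
powers are approximately log-normal and the scatter-plot construction
is scale-free); a linear domain is available via ``log_domain=False``.

No temporal smoothing is applied here: classification is purely
per-epoch, and all temporal structure (bouts, arousals) is handled by
the architecture stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .hypnogram import NREM, REM, WAKE, Hypnogram

__all__ = ["ScoringThresholds", "classify_epochs", "fit_thresholds"]

MIN_SLEEP_EPOCHS = 100


@dataclass
class ScoringThresholds:
    """Parameters of the two classification planes.

    ``sw_slope``/``sw_intercept`` define the sleep/wake discriminant
    line in the (emg_amp, sigma*theta) plane; ``dt_threshold`` is the
    NREM-vs-REM cutoff on delta/theta.  With ``log_domain`` both planes
    operate on natural-log features (dt_threshold stays on the raw
    ratio scale).
    """

    sw_slope: float
    sw_intercept: float
    dt_threshold: float
    log_domain: bool = True

    def __post_init__(self) -> None:
        if self.dt_threshold <= 0:
            raise ValueError("dt_threshold must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringThresholds":
        return cls(**json.loads(Path(path).read_text()))


def _plane_coords(features: pd.DataFrame, log_domain: bool):
    emg = features["emg_amp"].to_numpy(float)
    st = (features["sigma_power"] * features["theta_power"]).to_numpy(float)
    if log_domain:
        tiny = np.finfo(float).tiny
        return np.log(np.maximum(emg, tiny)), np.log(np.maximum(st, tiny))
    return emg, st


def classify_epochs(features: pd.DataFrame, thresholds: ScoringThresholds) -> Hypnogram:
    """Score every epoch; pure and order-independent across epochs.

    SLEEP iff sigma*theta lies strictly above the discriminant line
    (ties score WAKE); a sleep epoch is NREM iff delta/theta >=
    dt_threshold (a zero theta power yields an infinite ratio, which is
    scored NREM with a warning rather than raising).
    """
    if len(features) == 0:
        raise ValueError("no epochs to classify")
    x, y = _plane_coords(features, thresholds.log_domain)
    sleep = y > thresholds.sw_slope * x + thresholds.sw_intercept

    delta = features["delta_power"].to_numpy(float)
    theta = features["theta_power"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(theta > 0, delta / np.where(theta > 0, theta, 1.0), np.inf)
    if np.any(sleep & (theta <= 0)):
        warnings.warn(
            f"{int(np.sum(sleep & (theta <= 0)))} sleep epochs had zero theta "
            "power; delta/theta treated as +inf (scored NREM)",
            stacklevel=2,
        )
    states = np.where(sleep, np.where(ratio >= thresholds.dt_threshold, NREM, REM), WAKE)
    return Hypnogram(
        states.astype(np.int8),
        epoch_length=float(features.attrs.get("epoch_length", 10.0)),
        start_hour=float(features.attrs.get("start_hour", 7.0)),
        light_onset=float(features.attrs.get("light_onset", 7.0)),
        light_hours=float(features.attrs.get("light_hours", 12.0)),
    )


def _fixed_bandwidth_kde(x: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    # bandwidth tied to the spread only, so duplicating every observation
    # leaves the density estimate (and hence the antimode) unchanged
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))


def _antimode(x: np.ndarray) -> float | None:
    """Deepest interior density minimum between the two largest modes."""
    sd = float(np.std(x))
    if sd == 0:
        return None
    grid = np.linspace(x.min(), x.max(), 512)
    dens = _fixed_bandwidth_kde(x, grid, bw=0.2 * sd)
    interior = np.arange(1, len(grid) - 1)
    maxima = interior[(dens[interior] > dens[interior - 1])
                      & (dens[interior] >= dens[interior + 1])]
    if len(maxima) < 2:
        return None
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    if hi - lo < 2:
        return None
    between = np.arange(lo + 1, hi)
    return float(grid[between[np.argmin(dens[between])]])


def _quantile_init_gmm(x: np.ndarray) -> GaussianMixture:
    x = x.reshape(-1, 1)
    init = np.percentile(x, [10, 90]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, n_init=1, means_init=init, random_state=0, tol=1e-8
    )
    gm.fit(x)
    return gm


def fit_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Automatic per-recording calibration of both planes.

    A two-component Gaussian mixture on log EMG amplitude locates the
    quiescent (sleep) and active (wake) muscle-tone regimes; the
    sleep/wake line is the perpendicular bisector of the two cluster
    centroids in the (log emg, log sigma*theta) plane.  Among putative
    sleep epochs, the NREM/REM cutoff is the antimode of the
    log(delta/theta) density (fallbacks: two-component mixture
    midpoint, then the median, each with a warning).  Deterministic
    given the features, and invariant to duplicating every row.
    """
    if len(features) * features.attrs.get("epoch_length", 10.0) < 24 * 3600 - 1e-6:
        raise ValueError("threshold calibration requires at least 24 h of features")
    x, y = _plane_coords(features, log_domain=True)

    gm = _quantile_init_gmm(x)
    order = np.argsort(gm.means_.ravel())
    sleep_comp = order[0]                       # low-EMG component
    labels = gm.predict(x.reshape(-1, 1))
    sleep_mask = labels == sleep_comp
    n_sleep = int(sleep_mask.sum())
    if n_sleep < MIN_SLEEP_EPOCHS:
        raise ValueError(
            f"only {n_sleep} putative sleep epochs (< {MIN_SLEEP_EPOCHS}); "
            "cannot calibrate sleep/wake thresholds"
        )

    cs = np.array([x[sleep_mask].mean(), y[sleep_mask].mean()])
    cw = np.array([x[~sleep_mask].mean(), y[~sleep_mask].mean()])
    mid = (cs + cw) / 2.0
    dx, dy = cw - cs
    if abs(dy) < 1e-9 * max(1.0, abs(dx)):
        # clusters separate on EMG only: near-vertical boundary
        slope = -1e9 if dx > 0 else 1e9
    else:
        slope = -dx / dy
    intercept = mid[1] - slope * mid[0]
    if not (cs[1] > slope * cs[0] + intercept):
        # orientation must place the sleep centroid on the "greater" side
        warnings.warn("degenerate cluster geometry; flipping discriminant", stacklevel=2)
        slope, intercept = -slope, -intercept + 2 * cs[1]

    delta = features["delta_power"].to_numpy(float)[sleep_mask]
    theta = features["theta_power"].to_numpy(float)[sleep_mask]
    ok = theta > 0
    log_ratio = np.log(delta[ok] / theta[ok])
    cut = _antimode(log_ratio)
    if cut is None:
        gm2 = _quantile_init_gmm(log_ratio)
        m = np.sort(gm2.means_.ravel())
        sds = np.sqrt(np.sort(gm2.covariances_.ravel()))
        if m[1] - m[0] > max(sds):
            warnings.warn(
                "no antimode in log(delta/theta); using mixture midpoint",
                stacklevel=2,
            )
            cut = float(m.mean())
        else:
            warnings.warn(
                "log(delta/theta) looks unimodal; falling back to the median",
                stacklevel=2,
            )
            cut = float(np.median(log_ratio))
    return ScoringThresholds(
        sw_slope=float(slope), sw_intercept=float(intercept),
        dt_threshold=float(np.exp(cut)), log_domain=True,
    )
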