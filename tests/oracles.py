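"""Independent brute-force oracles used to cross-validate the package.

Everything here re-implements the textual scoring rules and the
classical statistics from scratch, via regex scans over state strings
and explicit design-matrix projections, deliberately sharing no code
with the package implementations they check.
"""

from __future__ import annotations

import re

import numpy as np

_PATTERNS = {
    "N": dict(start=re.compile("NNN"), term=re.compile("WWW|RR")),
    "R": dict(start=re.compile("RR"), term=re.compile("WWW|NNN")),
}


def brute_bouts(s: str, state: str) -> list[tuple[int, int]]:
    """(start, last-own-state-epoch) pairs per the verbatim bout rules."""
    pat = _PATTERNS[state]
    bouts = []
    pos = 0
    n = len(s)
    while True:
        m = pat["start"].search(s, pos)
        if m is None:
            break
        start = m.start()
        t = pat["term"].search(s, start)
        region_end = t.start() if t else n
        last = max(i for i in range(start, region_end) if s[i] == state)
        bouts.append((start, last))
        pos = t.end() if t else n
    return bouts


def brute_arousals(s: str) -> list[int]:
    """Onsets of wake runs preceded by three consecutive sleep epochs."""
    out = []
    for m in re.finditer("W+", s):
        i = m.start()
        if i >= 3 and all(c in "NR" for c in s[i - 3:i]):
            out.append(i)
    return out


def brute_resume_events(s: str) -> list[tuple[int, int]]:
    """(onset, latency) per the verbatim time-to-resume-sleep rule."""
    out = []
    for m in re.finditer("W{3,}", s):
        i = m.start()
        nxt = re.compile("[NR]{3}").search(s, i)
        if nxt is not None:
            out.append((i, nxt.start() - i))
    return out


# ---------------------------------------------------------------------------
# linear-model projection oracle for the split-plot ANOVA
# ---------------------------------------------------------------------------

def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels.tolist()))
    return np.stack([(labels == l).astype(float) for l in levels], axis=1)


def projection_anova(df) -> dict[str, tuple[float, int]]:
    """Sequential sums of squares via nested least-squares fits.

    Returns {effect: (SS, df)} for group, subjects-within, time,
    group:time, and error, from explicit dummy design matrices.
    """
    y = df["value"].to_numpy(float)
    subj = _dummies(df["animal_id"])
    grp = _dummies(df["group"])
    tim = _dummies(df["time_bin"])
    inter = np.einsum("ij,ik->ijk", grp, tim).reshape(len(y), -1)
    one = np.ones((len(y), 1))
    rss_1 = _rss(y, one)
    rss_g = _rss(y, np.hstack([one, grp]))
    rss_s = _rss(y, np.hstack([one, subj]))
    rss_st = _rss(y, np.hstack([one, subj, tim]))
    rss_full = _rss(y, np.hstack([one, subj, tim, inter]))
    a = grp.shape[1]
    k = tim.shape[1]
    n_subj = subj.shape[1]
    return {
        "group": (rss_1 - rss_g, a - 1),
        "subjects_within": (rss_g - rss_s, n_subj - a),
        "time": (rss_s - rss_st, k - 1),
        "group:time": (rss_st - rss_full, (a - 1) * (k - 1)),
        "error": (rss_full, (n_subj - a) * (k - 1)),
    }


def eigen_sphericity(covariances: list[np.ndarray], dfs: list[int]):
    """(W, epsilon) from an explicit orthonormal-contrast eigenproblem.

    ``covariances`` are per-group subject-by-time sample covariances
    with their degrees of freedom; contrasts come from the SVD null
    space of the all-ones row (a different orthonormal basis than the
    implementation uses; both quantities are basis-invariant).
    """
    S = sum(d * c for d, c in zip(dfs, covariances)) / sum(dfs)
    k = S.shape[0]
    ones = np.ones((1, k))
    _, _, vt = np.linalg.svd(ones)
    C = vt[1:]                      # orthonormal complement of the mean
    lam = np.linalg.eigvalsh(C @ S @ C.T)
    W = np.prod(lam) / np.mean(lam) ** (k - 1)
    eps = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
    return float(W), float(eps)
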