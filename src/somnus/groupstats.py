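"""Two-group repeated-measures statistics for sleep time-course data.

The design is a classic split plot: one between-subjects factor
(surgical group) with possibly unequal group sizes, one within-subjects
factor (clock bin) with complete data per animal.  The battery covers
the unpaired pooled-variance t-test, the mixed two-way ANOVA, Mauchly's
sphericity test, the Greenhouse-Geisser epsilon correction, and Fisher
LSD simple effects of group at each time bin.

Reporting policy: both the unadjusted and the epsilon-adjusted p-values
are always computed; the headline p (``p_reported``) applies the
Greenhouse-Geisser correction only when Mauchly's test rejects
sphericity at 0.05, and no multiplicity correction is applied anywhere
(Fisher LSD is by definition unadjusted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "AnovaTable",
    "t_test_unpaired",
    "mixed_rm_anova",
    "mauchly_test",
    "greenhouse_geisser",
    "fisher_lsd",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float


def t_test_unpaired(group_a, group_b) -> TTestResult:
    """Classical pooled-variance two-sample t-test, two-tailed.

    Two identical constant groups give t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, a.mean(), 0.0, b.mean(), 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        float(t), df, float(p),
        float(a.mean()), float(a.std(ddof=1) / np.sqrt(a.size)),
        float(b.mean()), float(b.std(ddof=1) / np.sqrt(b.size)),
    )


# ---------------------------------------------------------------------------
# long-table plumbing
# ---------------------------------------------------------------------------

def _pivot(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list, list]:
    """(subject x time matrix, group index per subject, groups, times)."""
    required = {"animal_id", "group", "time_bin", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"long table is missing columns {sorted(missing)}")
    wide = data.pivot_table(index=["group", "animal_id"], columns="time_bin",
                            values="value", aggfunc="first", sort=True)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every animal needs one value per time bin")
    counts = data.groupby(["group", "animal_id"]).size()
    if (counts != wide.shape[1]).any():
        raise ValueError("duplicate (animal, time_bin) rows in long table")
    groups = list(wide.index.get_level_values("group").unique())
    gidx = np.array([groups.index(g) for g in wide.index.get_level_values("group")])
    return wide.to_numpy(float), gidx, groups, list(wide.columns)


def _contrast_covariance(data: pd.DataFrame) -> tuple[np.ndarray, int, int]:
    """Pooled within-group covariance projected onto orthonormal contrasts.

    Returns (Sigma_contrast, k, pooled_df) with pooled_df = N - a.
    """
    Y, gidx, groups, times = _pivot(data)
    N, k = Y.shape
    a = len(groups)
    if k < 2:
        raise ValueError("need at least 2 time bins")
    pooled = np.zeros((k, k))
    for g in range(a):
        Z = Y[gidx == g]
        if Z.shape[0] < 2:
            raise ValueError("need at least 2 animals per group")
        pooled += (Z.shape[0] - 1) * np.cov(Z, rowvar=False)
    pooled /= N - a
    C = _helmert(k)
    return C @ pooled @ C.T, k, N - a


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

def mauchly_test(data: pd.DataFrame) -> tuple[float, float, int, float]:
    """Mauchly's W with its chi-square approximation.

    Returns ``(W, chi2, df, p)``.  With two time bins sphericity holds
    trivially and ``(1, 0, 0, 1)`` is returned by convention.
    """
    Sc, k, n_pool = _contrast_covariance(data)
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    lam = np.linalg.eigvalsh(Sc)
    if np.min(lam) <= 0:
        raise ValueError(
            "contrast covariance is singular (too few animals for the "
            "number of time bins); Mauchly's W is undefined"
        )
    p_ = k - 1
    W = float(np.prod(lam) / (np.mean(lam) ** p_))
    d = 1.0 - (2 * p_**2 + p_ + 2) / (6.0 * p_ * n_pool)
    chi2 = float(-n_pool * d * np.log(W))
    df = k * (k - 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return W, chi2, df, p


def greenhouse_geisser(data: pd.DataFrame) -> float:
    """Greenhouse-Geisser epsilon from the contrast-space covariance.

    epsilon = (sum lambda)^2 / ((k-1) sum lambda^2), bounded in
    [1/(k-1), 1]; a perfectly spherical covariance gives exactly 1 and
    a rank-1 contrast covariance exactly the lower bound.
    """
    Sc, k, _ = _contrast_covariance(data)
    lam = np.linalg.eigvalsh(Sc)
    eps = float(lam.sum() ** 2 / ((k - 1) * np.sum(lam**2)))
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Split-plot ANOVA results with sphericity diagnostics.

    ``effects`` has one row per effect (group, time, group x time) with
    F, df1, df2, unadjusted p, Greenhouse-Geisser adjusted df/p, and
    the headline ``p_reported`` (adjusted only when Mauchly rejects).
    """

    effects: pd.DataFrame
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float
    sums_of_squares: dict[str, float] = field(default_factory=dict)
    dfs: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> pd.Series:
        return self.effects.set_index("effect").loc[effect]


def mixed_rm_anova(data: pd.DataFrame) -> AnovaTable:
    """Two-way mixed (split-plot) ANOVA on a balanced long table.

    The between-subjects effect (group) is tested against
    subjects-within-groups; the within-subjects effects (time and
    group x time) against the subject x time error.  Group sizes may
    differ; each animal must have exactly one value per time bin
    (no imputation — incomplete tables raise).
    """
    Y, gidx, groups, times = _pivot(data)
    N, k = Y.shape
    a = len(groups)
    for g in range(a):
        if np.sum(gidx == g) < 2:
            raise ValueError("need at least 2 animals per group")
    n_g = np.array([np.sum(gidx == g) for g in range(a)])
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = np.array([Y[gidx == g].mean() for g in range(a)])

    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = k * np.sum(n_g * (group_means - grand) ** 2)
    ss_subj_within = ss_between_subj - ss_group

    Z = Y - subj_means[:, None]                 # subject-centred data
    ss_within_total = np.sum(Z**2)
    time_eff = Z.mean(axis=0)                   # observation-weighted
    ss_time = N * np.sum(time_eff**2)
    cell = np.stack([Z[gidx == g].mean(axis=0) for g in range(a)])
    ss_cells = np.sum(n_g[:, None] * cell**2)
    ss_inter = ss_cells - ss_time
    ss_error = ss_within_total - ss_cells

    df_group, df_sw = a - 1, N - a
    df_time = k - 1
    df_inter = (a - 1) * (k - 1)
    df_err = (N - a) * (k - 1)

    if k >= 3:
        try:
            mauchly_w, _, _, mauchly_p = mauchly_test(data)
            eps = greenhouse_geisser(data)
        except ValueError:
            mauchly_w, mauchly_p, eps = np.nan, np.nan, 1.0
    else:
        mauchly_w, mauchly_p, eps = 1.0, 1.0, 1.0

    def f_row(name, ss, df1, ss_err_, df2, within):
        if ss_err_ <= 0 or df2 <= 0 or df1 <= 0:
            return dict(effect=name, F=np.nan, df1=df1, df2=df2, p=np.nan,
                        df1_gg=np.nan, df2_gg=np.nan, p_gg=np.nan,
                        p_reported=np.nan)
        F = (ss / df1) / (ss_err_ / df2)
        p = float(stats.f.sf(F, df1, df2))
        if within:
            d1, d2 = eps * df1, eps * df2
            p_gg = float(stats.f.sf(F, d1, d2))
        else:
            d1, d2, p_gg = df1, df2, p
        reported = p_gg if (within and not np.isnan(mauchly_p)
                            and mauchly_p < 0.05) else p
        return dict(effect=name, F=float(F), df1=df1, df2=df2, p=p,
                    df1_gg=d1, df2_gg=d2, p_gg=p_gg, p_reported=reported)

    rows = [
        f_row("group", ss_group, df_group, ss_subj_within, df_sw, within=False),
        f_row("time", ss_time, df_time, ss_error, df_err, within=True),
        f_row("group:time", ss_inter, df_inter, ss_error, df_err, within=True),
    ]
    if (np.var(Y) == 0):
        for r in rows:
            r.update(F=np.nan, p=np.nan, p_gg=np.nan, p_reported=np.nan)
    return AnovaTable(
        effects=pd.DataFrame(rows),
        epsilon_gg=eps, mauchly_w=mauchly_w, mauchly_p=mauchly_p,
        sums_of_squares={
            "group": float(ss_group), "subjects_within": float(ss_subj_within),
            "time": float(ss_time), "group:time": float(ss_inter),
            "error": float(ss_error),
        },
        dfs={"group": df_group, "subjects_within": df_sw, "time": df_time,
             "group:time": df_inter, "error": df_err},
    )


def fisher_lsd(data: pd.DataFrame) -> pd.DataFrame:
    """Group comparison at each time bin using the pooled ANOVA error.

    The error term pools the between-subject and within-subject error
    sums of squares (the usual simple-effects variance for a mixed
    design); p-values are unadjusted, per Fisher's LSD.  With a single
    time bin this reduces exactly to the pooled-variance t-test.
    """
    table = mixed_rm_anova(data) if len(set(data["time_bin"])) > 1 else None
    Y, gidx, groups, times = _pivot(data)
    if len(groups) != 2:
        raise ValueError("Fisher LSD simple effects expect exactly 2 groups")
    n_a, n_b = np.sum(gidx == 0), np.sum(gidx == 1)
    if table is not None:
        ss = table.sums_of_squares
        dfs = table.dfs
        ms_pool = (ss["subjects_within"] + ss["error"]) / (
            dfs["subjects_within"] + dfs["error"])
        df = dfs["subjects_within"] + dfs["error"]
    else:
        v = np.concatenate([Y[gidx == 0, 0], Y[gidx == 1, 0]])
        g = np.concatenate([np.zeros(n_a), np.ones(n_b)])
        ms_pool = (np.sum((v[g == 0] - v[g == 0].mean()) ** 2)
                   + np.sum((v[g == 1] - v[g == 1].mean()) ** 2)) / (n_a + n_b - 2)
        df = n_a + n_b - 2
    rows = []
    se = np.sqrt(ms_pool * (1.0 / n_a + 1.0 / n_b))
    for j, t in enumerate(times):
        diff = Y[gidx == 0, j].mean() - Y[gidx == 1, j].mean()
        if se == 0:
            tval, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
        else:
            tval = diff / se
            p = float(2 * stats.t.sf(abs(tval), df))
        rows.append({"time_bin": t, "mean_diff": float(diff), "t": float(tval),
                     "df": df, "p": p})
    return pd.DataFrame(rows)
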