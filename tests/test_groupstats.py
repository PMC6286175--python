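import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import eigen_sphericity, projection_anova
from somnus import (
    fisher_lsd,
    greenhouse_geisser,
    mauchly_test,
    mixed_rm_anova,
    t_test_unpaired,
)


def long_table(Y, groups, times=None):
    """Long table from a (subjects x times) matrix and group labels."""
    n, k = Y.shape
    times = times if times is not None else list(range(k))
    rows = [(f"s{i}", groups[i], times[t], Y[i, t])
            for i in range(n) for t in range(k)]
    return pd.DataFrame(rows, columns=["animal_id", "group", "time_bin", "value"])


def random_table(seed, n_a=4, n_b=5, k=5, effect=0.0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    Y = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
    Y[n_a:] += effect * np.arange(k)
    return long_table(Y, ["a"] * n_a + ["b"] * n_b)


class TestTTest:
    def test_identical_groups(self):
        r = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_textbook_closed_form(self):
        """(1,2,3) vs (4,5,6): pooled-variance t = -3/(sqrt(1)*sqrt(2/3))."""
        r = t_test_unpaired([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.6742346, abs=1e-6)
        assert r.df == 4
        assert r.sem_a == pytest.approx(1.0 / np.sqrt(3))

    def test_scale_invariance_of_t_and_p(self):
        a, b = np.array([1.0, 2.5, 3.1]), np.array([2.0, 4.0, 5.5, 6.0])
        r1 = t_test_unpaired(a, b)
        r2 = t_test_unpaired(7.3 * a, 7.3 * b)
        assert r2.t == pytest.approx(r1.t) and r2.p == pytest.approx(r1.p)

    def test_constant_equal_groups_give_p_one(self):
        r = t_test_unpaired([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            t_test_unpaired([1.0], [1.0, 2.0])


class TestMixedAnova:
    def test_matches_projection_oracle(self):
        data = random_table(1)
        tab = mixed_rm_anova(data)
        oracle = projection_anova(data)
        for eff in ("group", "time", "group:time"):
            ss, df1 = oracle[eff]
            err = "subjects_within" if eff == "group" else "error"
            ss_e, df2 = oracle[err]
            F = (ss / df1) / (ss_e / df2)
            assert tab[eff]["F"] == pytest.approx(F, abs=1e-8)
            assert tab.sums_of_squares[eff] == pytest.approx(ss, abs=1e-8)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        data = random_table(2, n_a=5, n_b=5, k=4, effect=0.3)
        tab = mixed_rm_anova(data)
        ref = pg.mixed_anova(data=data, dv="value", within="time_bin",
                             subject="animal_id", between="group")
        ref = ref.set_index("Source")
        assert tab["group"]["F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert tab["time"]["F"] == pytest.approx(ref.loc["time_bin", "F"], rel=1e-9)
        assert tab["group:time"]["F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)

    def test_constant_data_reports_missing(self):
        data = long_table(np.full((4, 3), 5.0), ["a", "a", "b", "b"])
        tab = mixed_rm_anova(data)
        assert np.isnan(tab["group:time"]["F"])

    def test_shift_invariance(self):
        data = random_table(3)
        shifted = data.assign(value=data["value"] + 1234.5)
        t1, t2 = mixed_rm_anova(data), mixed_rm_anova(shifted)
        for eff in ("group", "time", "group:time"):
            assert t1[eff]["F"] == pytest.approx(t2[eff]["F"], rel=1e-9)

    def test_scale_invariance_of_f(self):
        data = random_table(4)
        scaled = data.assign(value=data["value"] * 3.7)
        t1, t2 = mixed_rm_anova(data), mixed_rm_anova(scaled)
        for eff in ("group", "time", "group:time"):
            assert t1[eff]["F"] == pytest.approx(t2[eff]["F"], rel=1e-9)

    def test_two_bin_time_effect_equals_paired_t_squared(self):
        """Single group, two time bins: F(time) is the square of the
        paired-difference t statistic."""
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (8, 2))
        data = long_table(Y, ["a"] * 8)
        tab = mixed_rm_anova(data)
        t, p = stats.ttest_rel(Y[:, 0], Y[:, 1])
        assert tab["time"]["F"] == pytest.approx(t**2, rel=1e-9)
        assert tab["time"]["p"] == pytest.approx(p, rel=1e-9)

    def test_unbalanced_within_rejected(self):
        data = random_table(6).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_rm_anova(data)

    def test_single_animal_group_rejected(self):
        data = random_table(7, n_a=1, n_b=4)
        with pytest.raises(ValueError, match="2 animals"):
            mixed_rm_anova(data)


def spherical_table(n=9, k=4, seed=8):
    """Subject data whose contrast-space sample covariance is exactly
    the identity, built from orthonormalised noise."""
    rng = np.random.default_rng(seed)
    from somnus.groupstats import _helmert

    X = rng.normal(0, 1, (n, k - 1))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    X = Q[:, : k - 1] * np.sqrt(n - 1)
    Y = X @ _helmert(k)
    return long_table(Y, ["a"] * n)


class TestSphericity:
    def test_spherical_covariance_gives_w_one(self):
        data = spherical_table()
        W, chi2, df, p = mauchly_test(data)
        assert W == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_two_bins_is_trivially_spherical(self):
        data = random_table(9, k=2)
        assert mauchly_test(data) == (1.0, 0.0, 0, 1.0)

    def test_w_matches_eigen_oracle(self):
        data = random_table(10, n_a=6, n_b=6, k=4)
        W, *_ = mauchly_test(data)
        Ya = data[data.group == "a"].pivot(index="animal_id", columns="time_bin",
                                           values="value").to_numpy()
        Yb = data[data.group == "b"].pivot(index="animal_id", columns="time_bin",
                                           values="value").to_numpy()
        W_o, _ = eigen_sphericity(
            [np.cov(Ya, rowvar=False), np.cov(Yb, rowvar=False)], [5, 5])
        assert W == pytest.approx(W_o, abs=1e-8)

    def test_singular_covariance_rejected(self):
        data = random_table(11, n_a=2, n_b=2, k=6)  # n too small for k
        with pytest.raises(ValueError, match="singular"):
            mauchly_test(data)


class TestGreenhouseGeisser:
    def test_spherical_gives_epsilon_one(self):
        assert greenhouse_geisser(spherical_table()) == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_hits_lower_bound_exactly(self):
        k = 5
        u = np.linspace(-1, 1, 7)
        c = np.arange(k, dtype=float) - (k - 1) / 2
        data = long_table(np.outer(u, c), ["a"] * 7)
        assert greenhouse_geisser(data) == 1.0 / (k - 1)

    def test_matches_eigen_oracle(self):
        data = random_table(12, n_a=6, n_b=6, k=4)
        eps = greenhouse_geisser(data)
        Ya = data[data.group == "a"].pivot(index="animal_id", columns="time_bin",
                                           values="value").to_numpy()
        Yb = data[data.group == "b"].pivot(index="animal_id", columns="time_bin",
                                           values="value").to_numpy()
        _, eps_o = eigen_sphericity(
            [np.cov(Ya, rowvar=False), np.cov(Yb, rowvar=False)], [5, 5])
        assert eps == pytest.approx(eps_o, abs=1e-10)

    def test_matches_r_car_reference_value(self):
        """Frozen cross-check: epsilon and Mauchly W for a fixed toy
        dataset agree with car::Anova (R) to printed precision."""
        rng = np.random.default_rng(5)
        rows = []
        for i in range(6):
            g = "a" if i < 3 else "b"
            base = rng.normal(0, 1)
            for t in range(4):
                rows.append((f"s{i}", g, t,
                             base + rng.normal(0, 1) + (0.5 * t if g == "b" else 0)))
        data = pd.DataFrame(rows, columns=["animal_id", "group", "time_bin", "value"])
        assert greenhouse_geisser(data) == pytest.approx(0.7147793, abs=1e-7)
        W, *_ = mauchly_test(data)
        assert W == pytest.approx(0.27857, abs=1e-5)


class TestFisherLSD:
    def test_identical_groups_give_p_one_at_that_bin(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0], [1.0, 5.0], [3.0, 1.0]])
        data = long_table(Y, ["a", "a", "b", "b"])
        res = fisher_lsd(data)
        assert res.loc[res.time_bin == 0, "p"].iloc[0] == pytest.approx(1.0)

    def test_single_bin_reduces_to_pooled_t(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        data = long_table(np.concatenate([a, b])[:, None], ["a"] * 5 + ["b"] * 6)
        res = fisher_lsd(data)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert res["t"].iloc[0] == pytest.approx(t_ref, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-9)

    def test_injected_separation_found_at_right_bin(self):
        """A group difference planted at one bin should produce its
        smallest p there in nearly every replicate."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            Y = rng.normal(0, 1, (12, 5))
            Y[6:, 2] += 2.5
            res = fisher_lsd(long_table(Y, ["a"] * 6 + ["b"] * 6))
            hits += int(res["p"].idxmin() == 2)
        assert hits >= 0.9 * n_rep
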