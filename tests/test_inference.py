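import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cordmaskvar.errors import DesignError, UndefinedMetricError
from cordmaskvar.inference import (fisher_z, fisher_z_inv, maxt_permutation,
                                   maxt_permutation_arrays, spearman, two_way_anova)


def anova_ss_oracle(table: np.ndarray):
    """First-principles balanced two-way SS decomposition (independent of
    the implementation under test)."""
    grand = table.mean()
    R, D = table.shape
    ss_rater = D * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_dataset = R * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_resid = ss_total - ss_rater - ss_dataset
    f_rater = (ss_rater / (R - 1)) / (ss_resid / ((R - 1) * (D - 1)))
    f_dataset = (ss_dataset / (D - 1)) / (ss_resid / ((R - 1) * (D - 1)))
    return ss_rater, ss_dataset, ss_resid, ss_total, f_rater, f_dataset


def cells_from_array(table: np.ndarray) -> pd.DataFrame:
    R, D = table.shape
    return pd.DataFrame([
        {"rater": f"r{r}", "dataset": f"d{d}", "y": table[r, d]}
        for r in range(R) for d in range(D)
    ])


class TestTwoWayAnova:
    @pytest.mark.parametrize("R,D,df_effect,df_resid", [(8, 21, 7, 140), (9, 21, 8, 160)])
    def test_design_degrees_of_freedom(self, R, D, df_effect, df_resid):
        rng = np.random.default_rng(0)
        res = two_way_anova(cells_from_array(rng.normal(size=(R, D))), "y")
        assert res.factors.loc["rater", "df_effect"] == df_effect
        assert res.factors.loc["dataset", "df_effect"] == D - 1
        assert res.df_resid == df_resid

    def test_constant_response_degenerate(self):
        res = two_way_anova(cells_from_array(np.full((3, 4), 2.5)), "y")
        assert res.degenerate
        assert (res.factors["eta_sq"] == 0.0).all()
        assert res.ss_total == 0.0

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(11)
        table = rng.normal(size=(3, 4))
        res = two_way_anova(cells_from_array(table), "y")
        ss_r, ss_d, ss_e, ss_t, f_r, f_d = anova_ss_oracle(table)
        assert res.factors.loc["rater", "F"] == pytest.approx(f_r)
        assert res.factors.loc["dataset", "F"] == pytest.approx(f_d)
        assert res.factors.loc["rater", "eta_sq"] == pytest.approx(ss_r / ss_t)
        assert res.factors.loc["dataset", "eta_sq"] == pytest.approx(ss_d / ss_t)

    def test_ss_decomposition_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            R = int(rng.integers(2, 6))
            D = int(rng.integers(2, 7))
            table = rng.normal(size=(R, D))
            res = two_way_anova(cells_from_array(table), "y")
            ss_sum = res.factors["ss"].sum() + res.ss_resid
            assert ss_sum == pytest.approx(res.ss_total, rel=1e-9)
            # eta² of both factors plus residual share sums to one
            etas = res.factors["eta_sq"].sum() + res.ss_resid / res.ss_total
            assert etas == pytest.approx(1.0, abs=1e-10)

    def test_incomplete_design_raises(self):
        cells = cells_from_array(np.zeros((3, 3))).iloc[:-1]
        with pytest.raises(DesignError):
            two_way_anova(cells, "y")


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 70]) == 1.0

    def test_enumerated_triple(self):
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_agrees_with_scipy_including_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 5, size=15).astype(float)  # ties guaranteed
            y = rng.normal(size=15)
            assert spearman(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_independent_permutations_average_near_zero(self):
        rng = np.random.default_rng(8)
        x = np.arange(23, dtype=float)
        vals = [spearman(x, rng.permutation(x)) for _ in range(2000)]
        assert abs(np.mean(vals)) < 0.02

    def test_degenerate_inputs_raise(self):
        with pytest.raises(UndefinedMetricError):
            spearman([1, 2], [3, 4])
        with pytest.raises(UndefinedMetricError):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])


class TestFisherZ:
    def test_fixed_point_and_closed_form(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))

    def test_round_trip(self):
        for r in np.arange(-0.9, 0.95, 0.1):
            assert fisher_z_inv(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_boundary_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))


def naive_maxt(dsc, outcome, n_perm, rng):
    """Slow, independent max-T implementation: python loops and
    scipy.stats.spearmanr, permuting within each rater-dataset block."""
    n_r, n_d, n_s = dsc.shape

    def pooled(x):
        z = np.empty(n_r)
        for r in range(n_r):
            zs = []
            for d in range(n_d):
                rho = stats.spearmanr(x[r, d], outcome[r, d]).statistic
                zs.append(0.0 if np.isnan(rho) else np.arctanh(np.clip(rho, -1 + 1e-7, 1 - 1e-7)))
            z[r] = np.mean(zs)
        return z

    z_obs = pooled(dsc)
    null = np.empty(n_perm)
    for k in range(n_perm):
        xp = np.stack([[rng.permutation(dsc[r, d]) for d in range(n_d)]
                       for r in range(n_r)])
        null[k] = np.abs(pooled(xp)).max()
    p = (1.0 + (null[None, :] >= np.abs(z_obs)[:, None]).sum(axis=1)) / (n_perm + 1.0)
    return z_obs, p


class TestMaxtPermutation:
    def test_single_pair_reduces_to_exhaustive_permutation_p(self):
        # 1 rater × 1 dataset, 5 slices: exhaustive two-tailed p over all
        # 120 permutations vs the sampled max-T p (max over one item)
        x = np.array([[[1.0, 2.0, 3.0, 4.0, 5.0]]])
        y = np.array([[[2.0, 1.0, 4.0, 3.0, 5.0]]])
        rho_obs = stats.spearmanr(x[0, 0], y[0, 0]).statistic
        count = sum(
            abs(stats.spearmanr(np.array(p), y[0, 0]).statistic) >= abs(rho_obs) - 1e-12
            for p in itertools.permutations(x[0, 0]))
        p_exact = count / 120
        z, p, null, _ = maxt_permutation_arrays(x, y, n_perm=4000,
                                                rng=np.random.default_rng(0))
        assert z[0] == pytest.approx(np.arctanh(rho_obs))
        assert p[0] == pytest.approx(p_exact, abs=0.05)

    def test_observed_above_all_null_gives_minimum_p(self):
        n_s = 30
        x = np.arange(n_s, dtype=float)[None, None, :]
        y = x.copy()
        _, p, null, _ = maxt_permutation_arrays(x, y, n_perm=200,
                                                rng=np.random.default_rng(1))
        assert p[0] == pytest.approx(1.0 / 201.0)

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(17)
        n_r, n_d, n_s = 3, 4, 10
        x = rng.normal(size=(n_r, n_d, n_s))
        y = 0.6 * x + 0.8 * rng.normal(size=(n_r, n_d, n_s))
        z_fast, p_fast, _, _ = maxt_permutation_arrays(
            x, y, n_perm=600, rng=np.random.default_rng(2))
        z_slow, p_slow = naive_maxt(x, y, 600, np.random.default_rng(3))
        assert z_fast == pytest.approx(z_slow, abs=1e-10)
        # different permutation draws: agreement within Monte-Carlo error
        assert p_fast == pytest.approx(p_slow, abs=0.08)

    def test_adjusted_p_monotone_in_observed_statistic(self):
        rng = np.random.default_rng(4)
        n_r, n_d, n_s = 5, 6, 12
        x = rng.normal(size=(n_r, n_d, n_s))
        y = rng.normal(size=(n_r, n_d, n_s))
        for r in range(n_r):  # increasing signal strength by rater
            w = r / (n_r - 1)
            y[r] = w * x[r] + np.sqrt(1 - w**2) * y[r]
        z, p, _, _ = maxt_permutation_arrays(x, y, n_perm=500,
                                             rng=np.random.default_rng(5))
        order = np.argsort(-np.abs(z))
        assert np.all(np.diff(p[order]) >= 0)

    def test_degenerate_pair_contributes_zero(self):
        x = np.stack([np.tile(np.arange(8.0), (3, 1)),
                      np.tile(np.arange(8.0), (3, 1))])[..., :]
        y = x.copy()
        y[1] = 1.0  # constant outcome: all rater-2 pairs degenerate
        z, p, _, n_deg = maxt_permutation_arrays(x, y, n_perm=100,
                                                 rng=np.random.default_rng(6))
        assert n_deg == 3
        assert z[1] == 0.0 and z[0] > 0.0

    def test_table_api_matches_array_api(self):
        rng = np.random.default_rng(9)
        rows = []
        vals = rng.normal(size=(2, 3, 6, 2))
        for r in range(2):
            for d in range(3):
                for s in range(6):
                    rows.append({"rater": f"r{r}", "dataset": f"d{d}", "slice": s,
                                 "dsc": vals[r, d, s, 0], "cv_adjacent": vals[r, d, s, 1]})
        res = maxt_permutation(pd.DataFrame(rows), "cv_adjacent", n_perm=300, seed=12)
        z, p, _, _ = maxt_permutation_arrays(vals[..., 0], vals[..., 1], n_perm=300,
                                             rng=np.random.default_rng(12))
        assert res.mean_fisher_z == pytest.approx(z)
        assert res.p_adjusted == pytest.approx(p)
        # per-pair Spearman values round-trip through the result table
        for _, row in res.rho_by_dataset.iterrows():
            r = int(row["rater"][1:]); d = int(row["dataset"][1:])
            assert row["rho"] == pytest.approx(
                stats.spearmanr(vals[r, d, :, 0], vals[r, d, :, 1]).statistic)

    def test_incomplete_table_raises(self):
        rows = [{"rater": "a", "dataset": "d0", "slice": s, "dsc": s, "cv_adjacent": s}
                for s in range(5)]
        rows += [{"rater": "a", "dataset": "d1", "slice": s, "dsc": s, "cv_adjacent": s}
                 for s in range(3)]  # unbalanced slice counts break completeness
        with pytest.raises(DesignError):
            maxt_permutation(pd.DataFrame(rows), "cv_adjacent", n_perm=10, seed=0)
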