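"""Spearman screens, permutation inference, BH control, partial
correlation, and CCA with Wilks' lambda."""

from itertools import permutations
from math import factorial, log

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microcohort.association import (
    association_grid,
    bh_adjust,
    cca,
    partial_spearman,
    permutation_pvalue,
    spearman,
    wilks_test,
)
from microcohort.core_tables import ClinicalMetadata, to_relative

from conftest import make_table


class TestSpearman:
    def test_monotone(self):
        assert spearman([1, 2, 3, 5], [2, 4, 9, 10]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 5], [10, 9, 4, 2]) == pytest.approx(-1.0)

    def test_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3) == pytest.approx(base, abs=1e-12)


class TestPermutationP:
    def test_monotone_pair_exhaustive(self):
        x = np.arange(7.0)
        y = np.arange(7.0) * 2 + 1
        p = permutation_pvalue(x, y)
        # only the identity and the full reversal reach |rho| = 1
        assert p == pytest.approx(2 / factorial(7), abs=1e-15)

    def test_exhaustive_matches_full_enumeration_oracle(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        p = permutation_pvalue(x, y)
        rho_obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, y[list(perm)]).statistic) >= rho_obs - 1e-12
            for perm in permutations(range(6))
        )
        assert p == pytest.approx(count / factorial(6), abs=1e-12)

    def test_null_p_roughly_uniform(self, rng):
        hits = 0
        n_pairs = 300
        for _ in range(n_pairs):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            hits += permutation_pvalue(x, y, b=400, seed=int(rng.integers(2**31))) <= 0.05
        assert 0.02 <= hits / n_pairs <= 0.08

    def test_seed_reproducibility(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        assert permutation_pvalue(x, y, b=500, seed=11) == permutation_pvalue(
            x, y, b=500, seed=11
        )

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3], [3, 2, 1], b=0)


class TestBH:
    def test_step_up_example(self):
        q, reject = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert reject.sum() == 3
        assert not reject[3]

    def test_all_ones(self):
        q, reject = bh_adjust([1.0, 1.0, 1.0])
        assert reject.sum() == 0

    def test_single_p(self):
        q, reject = bh_adjust([0.04])
        assert q[0] == pytest.approx(0.04)
        assert reject[0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_never_fewer_than_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=25)
            _, bh = bh_adjust(p, fdr=0.05)
            bonf = p <= 0.05 / len(p)
            assert bh.sum() >= bonf.sum()
            assert (bh | ~bonf).all()  # everything Bonferroni rejects, BH rejects


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        rho, _ = partial_spearman(x, y, None)
        assert rho == pytest.approx(spearman(x, y), abs=1e-12)

    def test_constant_covariate_rejected(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        with pytest.raises(ValueError):
            partial_spearman(x, y, np.ones((20, 1)))

    def test_y_equal_to_covariate_vanishes(self, rng):
        c = rng.standard_normal(200)
        x = c + rng.standard_normal(200)
        y = c.copy()
        # y is fully explained by the covariate up to rank noise
        rho, _ = partial_spearman(x, y + 1e-8 * rng.standard_normal(200), c)
        assert abs(rho) < 0.1

    def test_confounded_pair_attenuated(self, rng):
        attenuated = 0
        for _ in range(40):
            c = rng.standard_normal(120)
            x = c + rng.standard_normal(120)
            y = c + rng.standard_normal(120)
            plain = spearman(x, y)
            partial, _ = partial_spearman(x, y, c)
            attenuated += abs(partial) < abs(plain)
        assert attenuated >= 38

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 60
        c = rng.standard_normal((n, 2))
        x = c[:, 0] + rng.standard_normal(n)
        y = c[:, 1] + 0.5 * x + rng.standard_normal(n)
        rho, p = partial_spearman(x, y, c)
        df = pd.DataFrame({"x": x, "y": y, "c1": c[:, 0], "c2": c[:, 1]})
        ref = pingouin.partial_corr(
            df, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )
        assert rho == pytest.approx(ref["r"].iloc[0], abs=1e-10)
        assert p == pytest.approx(ref["p_val"].iloc[0], abs=1e-10)


class TestAssociationGrid:
    def _grid_inputs(self, rng, n=80, n_taxa=5, planted=None):
        counts = rng.integers(1, 200, size=(n, n_taxa))
        table = to_relative(make_table(counts))
        meta = pd.DataFrame(
            {
                "v1": rng.standard_normal(n),
                "v2": rng.standard_normal(n),
            },
            index=table.sample_ids,
        )
        if planted:
            taxon, var, rho = planted
            z = stats.zscore(stats.rankdata(table.data[taxon]))
            meta[var] = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return table, ClinicalMetadata(data=meta)

    def test_planted_cell_found(self, rng):
        table, meta = self._grid_inputs(rng, n=164, planted=("g2", "v2", 0.45))
        grid = association_grid(table, meta, ["v1", "v2"], b=1000, seed=5)
        assert grid.significant.at["g2", "v2"]
        nulls = grid.significant.to_numpy().sum() - 1
        assert nulls <= 1
        assert grid.rho.at["g2", "v2"] > 0

    def test_missing_values_pairwise_deleted(self, rng):
        table, meta = self._grid_inputs(rng, n=40)
        meta.data.loc[meta.data.index[:5], "v1"] = np.nan
        grid = association_grid(table, meta, ["v1", "v2"], b=200, seed=1)
        assert (grid.n_pairs["v1"] == 35).all()
        assert (grid.n_pairs["v2"] == 40).all()

    def test_sparse_cells_excluded(self, rng):
        table, meta = self._grid_inputs(rng, n=30)
        meta.data.loc[meta.data.index[:25], "v1"] = np.nan  # 5 complete pairs
        grid = association_grid(table, meta, ["v1", "v2"], b=200, seed=1)
        assert grid.p["v1"].isna().all()
        assert grid.q["v1"].isna().all()
        assert not grid.significant["v1"].any()

    def test_adjusted_grid_runs(self, rng):
        table, meta = self._grid_inputs(rng, n=60)
        meta.data["age"] = rng.uniform(7, 15, 60)
        grid = association_grid(
            table, meta, ["v1", "v2"], adjust_for=["age"], seed=3
        )
        assert grid.adjusted_for == ["age"]
        assert np.isfinite(grid.p.to_numpy()).all()


class TestCca:
    def test_single_pair_equals_pearson(self, rng):
        x = rng.standard_normal((50, 1))
        y = 0.6 * x + rng.standard_normal((50, 1))
        res = cca(x, y)
        assert res.correlations[0] == pytest.approx(
            abs(np.corrcoef(x[:, 0], y[:, 0])[0, 1]), abs=1e-10
        )

    def test_invertible_transform_all_ones(self, rng):
        x = rng.standard_normal((50, 3))
        a = np.array([[1.0, 2, 0], [0, 1, 1], [1, 0, 3]])
        res = cca(x, x @ a)
        np.testing.assert_allclose(res.correlations, 1.0, atol=1e-8)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((60, 3))
        y = rng.standard_normal((60, 2)) + 0.4 * x[:, :2]
        base = cca(x, y).correlations
        ax = np.array([[2.0, 1, 0], [0, 1, 0.5], [1, 0, 1]])
        ay = np.array([[1.0, 3], [0, 2]])
        moved = cca(x @ ax + 5, y @ ay - 2).correlations
        np.testing.assert_allclose(base, moved, atol=1e-8)

    def test_matches_sklearn_first_correlation(self, rng):
        sklearn_cd = pytest.importorskip("sklearn.cross_decomposition")
        x = rng.standard_normal((80, 4))
        y = rng.standard_normal((80, 3)) + 0.5 * x[:, :3]
        ours = cca(x, y)
        model = sklearn_cd.CCA(n_components=1, max_iter=2000).fit(x, y)
        u, v = model.transform(x, y)
        r_sklearn = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert ours.correlations[0] == pytest.approx(r_sklearn, abs=1e-6)

    def test_errors(self, rng):
        x = rng.standard_normal((10, 5))
        y = rng.standard_normal((10, 5))
        with pytest.raises(ValueError):
            cca(x, y)  # n too small
        x2 = rng.standard_normal((50, 2))
        x2[:, 1] = 3.0
        with pytest.raises(ValueError, match="constant"):
            cca(x2, rng.standard_normal((50, 2)))


class TestWilks:
    def test_all_zero_correlations(self):
        out = wilks_test([0.0, 0.0], 40, 2, 2)
        assert out["wilks_lambda"].iloc[0] == pytest.approx(1.0)
        assert out["chi2"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_worked_example(self):
        out = wilks_test([0.5], 50, 1, 1)
        assert out["wilks_lambda"].iloc[0] == pytest.approx(0.75, abs=1e-12)
        assert out["chi2"].iloc[0] == pytest.approx(-47.5 * log(0.75), abs=1e-9)
        assert out["df"].iloc[0] == 1

    def test_lambda_non_decreasing(self, rng):
        r = np.sort(rng.uniform(0, 0.9, 4))[::-1]
        out = wilks_test(r, 100, 4, 4)
        lam = out["wilks_lambda"].to_numpy()
        assert (np.diff(lam) >= -1e-12).all()

    def test_degenerate_correlation_flagged(self):
        out = wilks_test([1.0, 0.3], 50, 2, 2)
        assert out["degenerate"].iloc[0]
        assert out["p"].iloc[0] == 0.0
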