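import numpy as np
import pandas as pd
import pytest

import segstab as ss


def brute_force_scaled_ranks(values):
    """Independent average-rank computation by pairwise comparison."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = np.empty(n)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return (ranks - 1) / (n - 1)


def make_feature_table(rng, n, with_f=True, valid=None):
    cols = {
        "lambda_": rng.random(n),
        "sigma2": rng.random(n) * 3,
        "mu": rng.random(n) * 8,
        "omega": rng.random(n),
    }
    cols["omega_star"] = cols["omega"] * (cols["mu"] / cols["mu"].max())
    if with_f:
        cols["f_stat"] = rng.random(n) * 10
    ft = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
    ft["valid"] = True if valid is None else valid
    return ft


class TestScaledRank:
    @pytest.mark.parametrize(
        "v,expected",
        [
            ([10, 30, 20], [0, 1, 0.5]),
            ([5, 5], [0.5, 0.5]),
            ([1, 2, 2, 4], [0, 0.5, 0.5, 1]),
        ],
    )
    def test_examples(self, v, expected):
        np.testing.assert_allclose(ss.scaled_rank(v), expected)

    def test_missing_excluded(self):
        out = ss.scaled_rank([1.0, np.nan, 3.0])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0, 1])

    def test_all_missing_is_error(self):
        with pytest.raises(ValueError):
            ss.scaled_rank([np.nan, np.nan])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 20, size=50).astype(float)  # ties likely
        np.testing.assert_allclose(ss.scaled_rank(v), brute_force_scaled_ranks(v))


class TestStabilityIndex:
    def test_best_gene_has_index_one(self):
        rng = np.random.default_rng(1)
        ft = make_feature_table(rng, 20)
        for c in ("lambda_", "sigma2", "omega_star", "f_stat"):
            ft.loc["g0", c] = ft[c].min() - 1e-3
        res = ss.stability_index(ft)
        assert res.index["g0"] == pytest.approx(1.0)

    def test_worst_gene_has_index_zero(self):
        rng = np.random.default_rng(2)
        ft = make_feature_table(rng, 20)
        for c in ("lambda_", "sigma2", "omega_star", "f_stat"):
            ft.loc["g0", c] = ft[c].max() + 1e-3
        assert ss.stability_index(ft).index["g0"] == pytest.approx(0.0)

    def test_matches_independent_recomputation(self):
        """10 hand-assigned genes: index equals a from-scratch average of
        1 - scaled rank computed by pairwise counting."""
        rng = np.random.default_rng(3)
        ft = make_feature_table(rng, 10)
        res = ss.stability_index(ft)
        expected = np.zeros(10)
        for c in ("lambda_", "sigma2", "omega_star", "f_stat"):
            expected += 1.0 - brute_force_scaled_ranks(ft[c].to_numpy())
        expected /= 4.0
        np.testing.assert_allclose(res.index.to_numpy(), expected)

    def test_mean_index_is_half_without_ties(self):
        rng = np.random.default_rng(4)
        ft = make_feature_table(rng, 101)
        assert ss.stability_index(ft).index.mean() == pytest.approx(0.5)

    def test_three_feature_mode_without_labels(self):
        rng = np.random.default_rng(5)
        ft = make_feature_table(rng, 30, with_f=False)
        res = ss.stability_index(ft)
        assert res.features_used == ["lambda_", "sigma2", "omega_star"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        ft = make_feature_table(rng, 40)
        base = ss.stability_index(ft).index
        ft2 = ft.copy()
        ft2["sigma2"] = np.exp(ft2["sigma2"])      # strictly monotone
        ft2["lambda_"] = ft2["lambda_"] ** 3 + 1.0
        pd.testing.assert_series_equal(base, ss.stability_index(ft2).index)

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        ft = make_feature_table(rng, 25)
        perm = rng.permutation(len(ft))
        res_a = ss.stability_index(ft).index
        res_b = ss.stability_index(ft.iloc[perm]).index
        pd.testing.assert_series_equal(res_a.sort_index(), res_b.sort_index())

    def test_invalid_gene_gets_missing_index(self):
        rng = np.random.default_rng(8)
        ft = make_feature_table(rng, 10)
        ft.loc["g3", ["lambda_", "sigma2", "omega_star", "f_stat"]] = np.nan
        ft.loc["g3", "valid"] = False
        res = ss.stability_index(ft)
        assert np.isnan(res.index["g3"])

    def test_too_few_valid_genes(self):
        rng = np.random.default_rng(9)
        ft = make_feature_table(rng, 3, valid=[True, False, False])
        ft.loc[~ft["valid"], ["lambda_", "sigma2", "omega_star", "f_stat"]] = np.nan
        with pytest.raises(ValueError):
            ss.stability_index(ft)


def brute_force_select(ft, res, index_pct=80.0, feature_pct=60.0):
    """Rule enumeration from raw values, independent of select_segs."""
    genes = list(ft.index)
    idx = res.index.to_numpy()
    selected = []
    G = len(genes)
    idx_rank = brute_force_scaled_ranks(idx) * (G - 1) + 1
    for i, g in enumerate(genes):
        pct = 100 * (idx_rank[i] - 1) / (G - 1)
        ok = pct > index_pct
        for c in res.features_used:
            v = ft[c].to_numpy()
            desc_rank = brute_force_scaled_ranks(-v) * (G - 1) + 1
            rev_pct = 100 * (desc_rank[i] - 1) / (G - 1)
            ok = ok and rev_pct > feature_pct
        if ok:
            selected.append(g)
    return selected


class TestSelectSegs:
    def test_best_gene_selected(self):
        rng = np.random.default_rng(10)
        ft = make_feature_table(rng, 100)
        for c in ("lambda_", "sigma2", "omega_star", "f_stat"):
            ft.loc["g0", c] = ft[c].min() - 1e-3
        res = ss.stability_index(ft)
        assert "g0" in ss.select_segs(res)

    def test_matches_rule_enumeration(self):
        rng = np.random.default_rng(11)
        ft = make_feature_table(rng, 20)
        res = ss.stability_index(ft)
        assert ss.select_segs(res) == brute_force_select(ft, res)

    def test_low_index_percentile_excluded(self):
        rng = np.random.default_rng(12)
        ft = make_feature_table(rng, 100)
        res = ss.stability_index(ft)
        order = res.index.rank()  # 1..100 ascending
        # a gene at percentile ~75 must be excluded regardless of features
        gene = order[(order - 1) / 99 * 100 <= 76].idxmax()
        assert gene not in ss.select_segs(res)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(13)
        ft = make_feature_table(rng, 150)
        res = ss.stability_index(ft)
        loose = set(ss.select_segs(res, 70, 50))
        tight = set(ss.select_segs(res, 85, 70))
        assert tight <= loose

    def test_empty_selection_warns(self):
        rng = np.random.default_rng(14)
        ft = make_feature_table(rng, 10)
        res = ss.stability_index(ft)
        with pytest.warns(UserWarning):
            assert ss.select_segs(res, 99.9, 99.9) == []


class TestUnion:
    def test_union_preserves_order(self):
        assert ss.union_gene_lists(["A", "B"], ["B", "C"]) == ["A", "B", "C"]

    def test_union_with_empty(self):
        assert ss.union_gene_lists(["A", "B"], []) == ["A", "B"]

    def test_disjoint_concatenates(self):
        assert ss.union_gene_lists(["A"], ["B"], ["C"]) == ["A", "B", "C"]


class TestSubsampleReproducibility:
    def test_identical_subsamples_correlate_perfectly(self, small_dataset):
        from segstab.index import _pipeline_index
        from segstab.mixture import EMConfig

        m = small_dataset.matrix
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        cells_a = np.sort(rng_a.choice(m.n_cells, 240, replace=False))
        cells_b = np.sort(rng_b.choice(m.n_cells, 240, replace=False))
        ia = _pipeline_index(m.subset_cells(cells_a), None, 0.8, EMConfig())
        ib = _pipeline_index(m.subset_cells(cells_b), None, 0.8, EMConfig())
        assert np.corrcoef(ia, ib)[0, 1] == pytest.approx(1.0)

    def test_fraction_bounds(self, small_dataset):
        with pytest.raises(ValueError):
            ss.subsample_reproducibility(small_dataset.matrix, fraction=1.0)

    def test_deterministic_given_seed(self, small_dataset):
        kw = dict(fraction=0.8, reps=3, seed=42)
        a = ss.subsample_reproducibility(small_dataset.matrix,
                                         small_dataset.annotation, **kw)
        b = ss.subsample_reproducibility(small_dataset.matrix,
                                         small_dataset.annotation, **kw)
        np.testing.assert_array_equal(a.correlations, b.correlations)
        assert a.correlations.size == 3
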