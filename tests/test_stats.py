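"""Mantel tests, correlograms, Moran's I and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from coralsym import stats as S
from coralsym.phylo import cophenetic_distances
from coralsym.simulate import simulate_richness_trait, simulate_tree


def random_distance(n, rng):
    return squareform(rng.random(n * (n - 1) // 2))


class TestMantel:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        d = random_distance(6, rng)
        res = S.mantel(d, d.copy(), n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        d = random_distance(6, rng)
        d2 = 3.0 * d + 0.2
        np.fill_diagonal(d2, 0.0)
        res = S.mantel(d, d2, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_r_matches_independent_implementation(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(9)]
        da = DistanceMatrix(random_distance(9, rng), ids)
        db = DistanceMatrix(random_distance(9, rng), ids)
        r_ref, _, _ = skbio_mantel(da, db, permutations=0)
        assert S.mantel(da, db, n_perm=9, seed=0).r \
            == pytest.approx(r_ref, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 5])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        A = random_distance(n, rng)
        B = random_distance(n, rng)
        res = S.mantel(A, B, exact=True)

        va = squareform(A)

        def pearson(a, b):
            a, b = a - a.mean(), b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        r_obs = pearson(va, squareform(B))
        rs = [pearson(va, squareform(B[np.ix_(p, p)]))
              for p in itertools.permutations(range(n))]
        p_oracle = np.mean(np.asarray(rs) >= r_obs - 1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        d = np.ones((5, 5)) - np.eye(5)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            S.mantel(d, random_distance(5, rng), n_perm=9, seed=0)


class TestDistanceClasses:
    def test_singletons_plus_equal_width(self):
        rng = np.random.default_rng(0)
        D = squareform(rng.uniform(0.01, 0.29, 45))
        for (i, j), v in zip([(0, 1), (2, 3), (4, 5), (6, 7)],
                             [0.35, 0.5, 0.6, 0.7]):
            D[i, j] = D[j, i] = v
        part = S.build_distance_classes(D, n_classes=11,
                                        singleton_threshold=0.3)
        assert part.n_classes == 11
        assert part.bounds[-4:] == [(0.35, 0.35), (0.5, 0.5),
                                    (0.6, 0.6), (0.7, 0.7)]
        assert all(part.n_pairs(k) == 1 for k in range(7, 11))

    def test_manual_breaks_half_open(self):
        D = np.array([[0, 0.05, 0.15], [0.05, 0, 0.25], [0.15, 0.25, 0]])
        part = S.build_distance_classes(D, manual_breaks=[0, 0.1, 0.2])
        assert part.n_classes == 3
        assert [part.n_pairs(k) for k in range(3)] == [1, 1, 1]

    def test_partition_covers_every_pair_once(self):
        tree = simulate_tree(16, seed=2)
        dm = cophenetic_distances(tree)
        part = S.build_distance_classes(dm, n_classes=8)
        stack = np.sum([ind.astype(int) for ind in part.indicators], axis=0)
        off = stack[np.triu_indices(16, 1)]
        assert (off == 1).all()

    def test_too_many_classes_errors(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            S.build_distance_classes(D, n_classes=5)

    def test_sturges(self):
        assert S.sturges_classes(32) == 6
        assert S.sturges_classes(496) == 10


class TestMantelCorrelogram:
    def test_identical_structure_first_class_significant(self):
        tree = simulate_tree(20, seed=5)
        dm = cophenetic_distances(tree)
        part = S.build_distance_classes(dm, n_classes=6)
        res = S.mantel_correlogram(dm, part, n_perm=999, seed=0)
        assert res.statistic.iloc[0] > 0
        assert res.p.iloc[0] <= 0.05

    def test_indicators_symmetric_zero_diagonal(self):
        tree = simulate_tree(10, seed=6)
        part = S.build_distance_classes(cophenetic_distances(tree),
                                        n_classes=4)
        for ind in part.indicators:
            assert (ind == ind.T).all()
            assert not ind.diagonal().any()

    def test_progressive_holm_never_below_raw(self):
        tree = simulate_tree(16, seed=7)
        dm = cophenetic_distances(tree)
        part = S.build_distance_classes(dm, n_classes=6)
        rng = np.random.default_rng(8)
        noise = DistanceMatrix(random_distance(16, rng),
                               list(part.labels))
        res = S.mantel_correlogram(noise, part, n_perm=99, seed=1)
        ok = res.dropna(subset=["p"])
        assert (ok.p_corrected >= ok.p - 1e-12).all()


class TestMoransI:
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_permutation_null_mean_exact(self, n):
        rng = np.random.default_rng(n)
        z = rng.standard_normal(n)
        W = random_distance(n, rng)
        vals = [S.morans_i(z[list(p)], W)
                for p in itertools.permutations(range(n))]
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=1e-10)

    def test_two_cluster_direct_formula(self):
        z = np.array([1.0, 1, 1, -1, -1, -1])
        W = np.zeros((6, 6))
        for i, j in itertools.combinations(range(3), 2):
            W[i, j] = W[j, i] = 1
            W[i + 3, j + 3] = W[j + 3, i + 3] = 1
        got = S.morans_i(z, W)
        n, s0 = 6, W.sum()
        zc = z - z.mean()
        expected = n / s0 * (zc @ W @ zc) / (zc @ zc)
        assert got == pytest.approx(expected)
        assert got > 0

    def test_constant_trait_errors(self):
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            S.morans_i(np.ones(4), W)
        with pytest.raises(ValueError):
            S.morans_i(np.arange(4.0), np.zeros((4, 4)))


class TestPhyloCorrelogram:
    def test_brownian_trait_first_class_positive(self, host_tree_32):
        dm = cophenetic_distances(host_tree_32)
        part = S.build_distance_classes(dm, n_classes=6)
        trait = simulate_richness_trait(host_tree_32, 1.0, 0.1, seed=5)
        res = S.phylo_correlogram(trait, part, n_perm=199, seed=0)
        assert res.significant_positive.iloc[0]

    def test_iid_trait_calibration(self, host_tree_32):
        dm = cophenetic_distances(host_tree_32)
        part = S.build_distance_classes(dm, n_classes=6)
        rng = np.random.default_rng(0)
        hits = np.zeros(part.n_classes)
        reps = 200
        for i in range(reps):
            trait = pd.Series(rng.standard_normal(32),
                              index=list(part.labels))
            res = S.phylo_correlogram(trait, part, n_perm=99, seed=i)
            hits += (res.significant_positive | res.significant_negative
                     ).to_numpy()
        rate = hits.mean() / reps
        assert 0.01 < rate < 0.11  # ~5% two-sided, binomial tolerance

    def test_averaging_replicates_leaves_one_value_per_tip(self):
        values = pd.Series([1.0, 3.0, 5.0], index=["a1", "a2", "b1"])
        host_of = pd.Series(["hA", "hA", "hB"], index=values.index)
        avg = S.average_by_host(values, host_of)
        assert avg.to_dict() == {"hA": 2.0, "hB": 5.0}


class TestPermanova:
    def test_single_group_errors(self):
        rng = np.random.default_rng(0)
        D = random_distance(6, rng)
        with pytest.raises(ValueError):
            S.permanova(D, pd.Series(["x"] * 6), n_perm=9, seed=0)

    def test_f_matches_independent_implementation(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(12)]
        D = DistanceMatrix(random_distance(12, rng), ids)
        grp = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ref = skbio_permanova(D, grp, permutations=0)
        mine = S.permanova(D, pd.Series(grp, index=ids), n_perm=9, seed=0,
                           factor_name="g")
        assert mine.pseudo_f == pytest.approx(ref["test statistic"],
                                              rel=1e-10)

    def test_exact_p_and_f_match_enumeration(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((6, 2))
        D = squareform(pdist(pts))
        grp = pd.Series(["a"] * 3 + ["b"] * 3)
        res = S.permanova(D, grp, exact=True, factor_name="g")

        # brute-force SS decomposition oracle on raw distances
        def ss_within(perm):
            idx = {"a": [perm[0], perm[1], perm[2]],
                   "b": [perm[3], perm[4], perm[5]]}
            ss = 0.0
            for members in idx.values():
                sub = D[np.ix_(members, members)]
                ss += (sub ** 2).sum() / (2 * len(members))
            return ss

        n = 6
        ss_tot = (D ** 2).sum() / (2 * n)
        sw = ss_within(list(range(6)))
        f_oracle = ((ss_tot - sw) / 1) / (sw / 4)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-10)
        fs = []
        for p in itertools.permutations(range(6)):
            sw_p = ss_within(list(p))
            fs.append(((ss_tot - sw_p) / 1) / (sw_p / 4))
        p_oracle = np.mean(np.asarray(fs) >= res.pseudo_f - 1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_separated_clusters_high_r2(self):
        n = 10
        D = np.full((n, n), 1.0)
        D[:5, :5] = 0.01
        D[5:, 5:] = 0.01
        np.fill_diagonal(D, 0.0)
        grp = pd.Series(["a"] * 5 + ["b"] * 5)
        res = S.permanova(D, grp, n_perm=99, seed=0, factor_name="g")
        assert res.r2 > 0.9

    def test_unknown_values_dropped(self):
        rng = np.random.default_rng(3)
        D = random_distance(8, rng)
        grp = pd.Series(["a", "a", "a", "b", "b", "b", "Unknown",
                         "Unknown"])
        res = S.permanova(D, grp, n_perm=9, seed=0, factor_name="g")
        assert res.n_samples == 6

    def test_continuous_covariate_single_df(self):
        rng = np.random.default_rng(4)
        D = random_distance(10, rng)
        cov = pd.Series(rng.standard_normal(10))
        res = S.permanova(D, cov, n_perm=9, seed=0, factor_name="lat")
        assert res.df == 1


class TestSmallHelpers:
    def test_adjusted_r2(self):
        assert S.adjusted_r2(0.5, 10, 3) == pytest.approx(0.25)
        assert S.adjusted_r2(1.0, 10, 3) == pytest.approx(1.0)
        assert S.adjusted_r2(0.3, 100_000, 1) == pytest.approx(0.3,
                                                               abs=1e-4)
        with pytest.raises(ValueError):
            S.adjusted_r2(0.5, 10, 9)

    def test_zscore_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            z = S.zscore_columns(m)
        assert z["a"].tolist() == [-1.0, 0.0, 1.0]
        assert z["b"].tolist() == [0.0, 0.0, 0.0]
        assert z["a"].mean() == pytest.approx(0.0)
        assert z["a"].std(ddof=1) == pytest.approx(1.0)

    def test_bonferroni(self):
        np.testing.assert_allclose(S.bonferroni_adjust([0.01], 60), [0.6])
        np.testing.assert_allclose(S.bonferroni_adjust([0.5, 0.3], 3),
                                   [1.0, 0.9])
        np.testing.assert_allclose(S.bonferroni_adjust([0.2], 1), [0.2])

    def test_expand_host_distance(self):
        tree = simulate_tree(4, seed=1, prefix="h")
        dm = cophenetic_distances(tree)
        host_of = pd.Series(["h01", "h01", "h02"],
                            index=["s1", "s2", "s3"])
        ds = S.expand_host_distance(dm, host_of)
        assert ds["s1", "s2"] == 0.0
        assert ds["s1", "s3"] == pytest.approx(dm["h01", "h02"])
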