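import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionflora.community_stats import (
    DistanceMatrix, bray_curtis, dispersion_homogeneity, filter_min_records,
    host_hca, kruskal_dunn, permanova, permanova_pairwise, _ss_total, _ss_within,
)
from lesionflora.core_data import CommunityMatrix


def matrix_from(counts):
    return CommunityMatrix(counts=pd.DataFrame(
        counts, index=[f"s{i}" for i in range(len(counts))]), rank="motu")


def random_distance(n, seed):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 6))
    from scipy.spatial.distance import pdist, squareform
    return DistanceMatrix(labels=[f"s{i}" for i in range(n)],
                          D=squareform(pdist(X)), metric="euclidean")


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        m = matrix_from([[3, 1, 0], [3, 1, 0]])
        assert bray_curtis(m).D[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        m = matrix_from([[3, 0], [0, 5]])
        assert bray_curtis(m).D[0, 1] == pytest.approx(1.0)

    def test_hand_formula_untransformed(self):
        m = matrix_from([[1, 1, 0], [0, 1, 1]])
        assert bray_curtis(m, transform="none").D[0, 1] == pytest.approx(0.5)

    def test_sqrt_transform_applied(self):
        m = matrix_from([[4, 0], [1, 0]])
        # sqrt rows: (2,0) vs (1,0) -> 1/3
        assert bray_curtis(m).D[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_named(self):
        m = matrix_from([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="s1"):
            bray_curtis(m)


class TestPermanova:
    def _groups(self, labels, sizes):
        g = []
        for i, n in enumerate(sizes):
            g += [f"g{i}"] * n
        return pd.Series(g, index=labels)

    def test_distance_decomposition_identity(self):
        D = random_distance(15, 0)
        g = self._groups(D.labels, [5, 5, 5])
        codes = np.repeat(np.arange(3), 5)
        D2 = D.D ** 2
        ss_t = _ss_total(D2)
        ss_w = _ss_within(D2, codes, 3)
        # SS_total decomposes exactly; cross-check against PCoA coordinates
        from lesionflora.community_stats import _pcoa_coords
        real, imag = _pcoa_coords(D.D)
        centred = real - real.mean(axis=0)
        assert ss_t == pytest.approx((centred ** 2).sum(), abs=1e-9)
        assert 0 < ss_w < ss_t

    def test_ss_total_invariant_under_label_permutation(self):
        D = random_distance(12, 1)
        D2 = D.D ** 2
        rng = np.random.default_rng(0)
        base = _ss_total(D2)
        for _ in range(5):
            perm = rng.permutation(12)
            sub = DistanceMatrix([D.labels[i] for i in perm],
                                 D.D[np.ix_(perm, perm)], "euclidean")
            assert _ss_total(sub.D ** 2) == pytest.approx(base)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (10, 4))
        b = rng.normal(4, 1, (10, 4))
        counts = np.abs(np.vstack([a, b])) + 1
        m = matrix_from(counts.round().astype(int))
        D = bray_curtis(m)
        g = self._groups(D.labels, [10, 10])
        res = permanova(D, g, n_perm=999, seed=0)
        assert res.p <= 0.005
        assert 0 <= res.R2 <= 1

    def test_pseudo_f_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        D = random_distance(14, 5)
        g = self._groups(D.labels, [7, 7])
        res = permanova(D, g, n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.D, ids=D.labels), g.to_numpy(), permutations=0)
        assert res.pseudo_F == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_exhaustive_enumeration_matches_sampled_p(self):
        D = random_distance(7, 2)
        g = self._groups(D.labels, [3, 4])
        exact = permanova(D, g, exhaustive=True)
        sampled = permanova(D, g, n_perm=4999, seed=1)
        assert exact.p == pytest.approx(sampled.p, abs=0.03)
        # exact p identical under relabelled group names
        g2 = g.map({"g0": "B", "g1": "A"})
        assert permanova(D, g2, exhaustive=True).p == exact.p

    def test_singleton_group_rejected(self):
        D = random_distance(5, 3)
        g = pd.Series(["a", "a", "a", "a", "b"], index=D.labels)
        with pytest.raises(ValueError, match="singleton"):
            permanova(D, g)

    def test_pairwise_table_bonferroni(self):
        D = random_distance(18, 4)
        g = self._groups(D.labels, [6, 6, 6])
        table = permanova_pairwise(D, g, n_perm=99, seed=0)
        assert len(table) == 3
        assert (table["p_bonferroni"] >= table["p"] - 1e-12).all()
        assert (table["p_bonferroni"] <= 1.0).all()


class TestDispersion:
    def test_unequal_dispersion_detected(self):
        rng = np.random.default_rng(0)
        tight = np.abs(rng.normal(5, 0.05, (10, 4)))
        loose = np.abs(rng.normal(5, 3.0, (10, 4)))
        m = matrix_from(np.vstack([tight, loose]).round(2) * 100)
        D = bray_curtis(m)
        g = pd.Series(["t"] * 10 + ["l"] * 10, index=D.labels)
        F, p = dispersion_homogeneity(D, g, n_perm=499, seed=0)
        assert p <= 0.01

    def test_equal_dispersion_not_flagged(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(5, 1.0, (24, 5)))
        m = matrix_from((X * 10).round().astype(int))
        D = bray_curtis(m)
        g = pd.Series(["a"] * 12 + ["b"] * 12, index=D.labels)
        _, p = dispersion_homogeneity(D, g, n_perm=499, seed=0)
        assert p > 0.05

    def test_f_statistic_matches_skbio_permdisp(self):
        skbio = pytest.importorskip("skbio")
        D = random_distance(16, 9)
        g = pd.Series(["a"] * 8 + ["b"] * 8, index=D.labels)
        F, _ = dispersion_homogeneity(D, g, n_perm=99, seed=0)
        sk = skbio.stats.distance.permdisp(
            skbio.DistanceMatrix(D.D, ids=D.labels), g.to_numpy(),
            permutations=0, test="centroid")
        assert F == pytest.approx(sk["test statistic"], rel=1e-6)

    def test_degenerate_identical_samples_error(self):
        D = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)), "bray_curtis")
        g = pd.Series(["x", "x", "y", "y"], index=D.labels)
        with pytest.raises(ValueError):
            dispersion_homogeneity(D, g)


class TestKruskalDunn:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        v = pd.Series(np.r_[rng.normal(0, 1, 15), rng.normal(3, 1, 15)],
                      index=[f"s{i}" for i in range(30)])
        g = pd.Series(["a"] * 15 + ["b"] * 15, index=v.index)
        H, p, dunn = kruskal_dunn(v, g)
        assert p < 1e-3
        assert dunn["p_bonferroni"].iloc[0] < 0.01

    def test_two_groups_match_mann_whitney_normal_approx(self):
        rng = np.random.default_rng(2)
        v = pd.Series(rng.integers(0, 8, size=26).astype(float),
                      index=[f"s{i}" for i in range(26)])
        g = pd.Series(["a"] * 13 + ["b"] * 13, index=v.index)
        H, p, _ = kruskal_dunn(v, g)
        mwu = stats.mannwhitneyu(v[g == "a"], v[g == "b"],
                                 alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        assert p == pytest.approx(mwu.pvalue, rel=1e-6)

    def test_all_tied_values_error(self):
        v = pd.Series([2.0] * 8, index=[f"s{i}" for i in range(8)])
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=v.index)
        with pytest.raises(ValueError, match="tied"):
            kruskal_dunn(v, g)

    def test_dunn_z_symmetry(self):
        rng = np.random.default_rng(4)
        v = pd.Series(rng.normal(size=18), index=[f"s{i}" for i in range(18)])
        g = pd.Series(np.repeat(["a", "b", "c"], 6), index=v.index)
        _, _, dunn = kruskal_dunn(v, g)
        assert len(dunn) == 3


class TestHostHCA:
    def test_two_cluster_profiles_recovered(self):
        profiles = pd.DataFrame(
            [[10, 0, 0], [11, 1, 0], [0, 10, 10], [1, 11, 9], [0, 9, 11]],
            index=["h1", "h2", "h3", "h4", "h5"])
        dend, c = host_hca(profiles)
        assert c > 0.9
        from lesionflora.fingerprint import cut_clusters
        # cut between the two merge scales: h1+h2 vs h3+h4+h5
        heights = np.sort(dend.merges[:, 2])    # root merge is the smallest
        mid = (heights[0] + heights[1]) / 2
        parts = cut_clusters(dend, mid)
        assert parts["h1"] == parts["h2"]
        assert parts["h3"] == parts["h4"] == parts["h5"]
        assert parts["h1"] != parts["h3"]

    def test_duplicate_profiles_merge_at_zero_distance(self):
        profiles = pd.DataFrame([[1, 2], [1, 2], [8, 9]], index=["a", "b", "c"])
        dend, c = host_hca(profiles)
        assert dend.merges[0, 2] == pytest.approx(100.0)   # distance 0

    def test_ultrametric_input_has_unit_cophenetic_correlation(self):
        # profiles engineered so Euclidean distances are already ultrametric
        profiles = pd.DataFrame([[0, 0, 0], [1, 0, 0], [0.5, 5, 0]],
                                index=["a", "b", "c"])
        # d(ab)=1, d(ac)=d(bc)~5.02 -> nearly ultrametric
        _, c = host_hca(profiles)
        assert c > 0.99

    def test_needs_three_hosts(self):
        with pytest.raises(ValueError):
            host_hca(pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"]))


class TestFilter:
    def test_sparse_samples_dropped(self):
        m = matrix_from([[3, 3], [1, 0], [5, 5]])
        f = filter_min_records(m, 5)
        assert f.n_samples == 2
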