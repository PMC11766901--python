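import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from lesionflora.fingerprint import (
    Dendrogram, FingerprintProfile, SimilarityMatrix, assign_taxonomy,
    consensus_similarity, cut_clusters, irc, irc_percent, pearson_similarity,
    read_fingerprints, reproducibility_cutoff, upgma, write_fingerprints,
)


def profile(rid, x, primer="csM13", dup=None):
    return FingerprintProfile(rid, primer, np.asarray(x, float), dup)


class TestPearsonSimilarity:
    def test_identical_profiles_score_100(self):
        sim = pearson_similarity([profile("a", [1, 2, 3]), profile("b", [1, 2, 3])])
        assert sim.value("a", "b") == pytest.approx(100.0)

    def test_mirrored_profiles_score_minus_100(self):
        sim = pearson_similarity([profile("a", [0, 1, 2]), profile("b", [2, 1, 0])])
        assert sim.value("a", "b") == pytest.approx(-100.0)

    def test_matches_direct_pearson_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 5])
        r = (np.sum((x - x.mean()) * (y - y.mean()))
             / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        sim = pearson_similarity([profile("a", x), profile("b", y)])
        assert sim.value("a", "b") == pytest.approx(100 * r)

    def test_zero_variance_profile_is_named(self):
        with pytest.raises(ValueError, match="flat"):
            pearson_similarity([profile("flat", [2, 2, 2]), profile("b", [1, 2, 3])])

    def test_mixed_primers_rejected(self):
        with pytest.raises(ValueError, match="primers"):
            pearson_similarity([profile("a", [1, 2, 3]),
                                profile("b", [1, 2, 3], primer="GTG5")])


class TestConsensus:
    def test_identical_matrices_unchanged(self):
        S = np.array([[100.0, 80], [80, 100]])
        sim = SimilarityMatrix(["a", "b"], S)
        out = consensus_similarity(sim, sim)
        np.testing.assert_allclose(out.S_pct, S)

    def test_entries_are_averaged(self):
        a = SimilarityMatrix(["a", "b"], np.array([[100.0, 80], [80, 100]]))
        b = SimilarityMatrix(["a", "b"], np.array([[100.0, 90], [90, 100]]))
        assert consensus_similarity(a, b).value("a", "b") == pytest.approx(85.0)

    def test_random_pair_stays_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(0)
        X1, X2 = rng.random(size=(2, 6, 40))
        s1 = pearson_similarity([profile(f"r{i}", X1[i]) for i in range(6)])
        s2 = pearson_similarity([profile(f"r{i}", X2[i]) for i in range(6)])
        out = consensus_similarity(s1, s2)
        np.testing.assert_allclose(out.S_pct, out.S_pct.T)
        np.testing.assert_allclose(np.diag(out.S_pct), 100.0)

    def test_label_mismatch_rejected(self):
        a = SimilarityMatrix(["a", "b"], np.eye(2) * 100)
        c = SimilarityMatrix(["a", "c"], np.eye(2) * 100)
        with pytest.raises(ValueError):
            consensus_similarity(a, c)


def brute_force_upgma(S_pct, labels):
    """Independent average-linkage oracle: cluster distances recomputed as
    means over the ORIGINAL dissimilarity matrix at every step."""
    D = 100.0 - S_pct
    clusters = {i: [i] for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, 100.0 - d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)


class TestUPGMA:
    def test_three_leaf_hand_example(self):
        # S(A,B)=90, S(A,C)=S(B,C)=50: merge (A,B) at 90, then C at 50
        S = np.array([[100.0, 90, 50], [90, 100, 50], [50, 50, 100]])
        dend = upgma(SimilarityMatrix(["A", "B", "C"], S))
        assert dend.merges[0, 2] == pytest.approx(90)
        assert dend.merges[1, 2] == pytest.approx(50)
        parts = cut_clusters(dend, 75)
        assert parts["A"] == parts["B"] != parts["C"]

    def test_equal_similarities_merge_at_single_height(self):
        S = np.full((4, 4), 70.0)
        np.fill_diagonal(S, 100.0)
        dend = upgma(SimilarityMatrix(list("abcd"), S))
        np.testing.assert_allclose(dend.merges[:, 2], 70.0)
        # lexicographic tie-break: first merge joins a and b
        assert sorted(dend.merges[0, :2]) == [0, 1]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_agrees_with_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            X = rng.normal(size=(n, 25))
            S = 100 * np.corrcoef(X)
            labels = [f"r{i}" for i in range(n)]
            dend = upgma(SimilarityMatrix(labels, S.copy()))
            oracle = brute_force_upgma(S, labels)
            np.testing.assert_allclose(dend.merges[:, 2], oracle[:, 2], atol=1e-8)

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 30))
        S = 100 * np.corrcoef(X)
        dend = upgma(SimilarityMatrix([f"r{i}" for i in range(12)], S.copy()))
        D = 100.0 - S
        np.fill_diagonal(D, 0.0)
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(D, checks=False), method="average")
        np.testing.assert_allclose(np.sort(dend.linkage()[:, 2]),
                                   np.sort(Z[:, 2]), atol=1e-8)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma(SimilarityMatrix(["a"], np.array([[100.0]])))

    def test_heights_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 40))
        dend = upgma(SimilarityMatrix([f"r{i}" for i in range(10)],
                                      100 * np.corrcoef(X)))
        heights = dend.merges[:, 2]
        assert (np.diff(heights) <= 1e-9).all()


class TestCutClusters:
    def _dend(self):
        S = np.array([[100.0, 90, 50], [90, 100, 50], [50, 50, 100]])
        return upgma(SimilarityMatrix(["A", "B", "C"], S))

    def test_threshold_100_gives_singletons(self):
        parts = cut_clusters(self._dend(), 100)
        assert len(set(parts.values())) == 3

    def test_threshold_below_min_height_gives_one_cluster(self):
        parts = cut_clusters(self._dend(), 10)
        assert len(set(parts.values())) == 1

    def test_partitions_nest_across_cutoffs(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 50))
        dend = upgma(SimilarityMatrix([f"r{i}" for i in range(20)],
                                      100 * np.corrcoef(X)))
        tax = assign_taxonomy(dend, 30, 50, 70)
        for a in tax.gt:
            for b in tax.gt:
                if tax.gt[a] == tax.gt[b]:
                    assert tax.motu[a] == tax.motu[b]
                if tax.motu[a] == tax.motu[b]:
                    assert tax.genus_cluster[a] == tax.genus_cluster[b]

    def test_cophenetic_consistent_with_cut(self):
        dend = self._dend()
        coph = dend.cophenetic_similarity()
        parts = cut_clusters(dend, 75)
        for a in "ABC":
            for b in "ABC":
                same = parts[a] == parts[b]
                assert same == (coph.value(a, b) >= 75)


class TestReproducibility:
    def test_paper_style_means_average_to_overall(self):
        # engineered duplicate pairs whose per-primer mean similarities are
        # exact; overall = mean of per-primer values, conservative floor 95
        x = np.array([1.0, 2, 3, 4, 5, 4, 3, 2, 1, 2])
        pairs = {
            "csM13": [(profile("a", x), profile("a2", x))],
            "GTG5": [(profile("b", x, "GTG5"), profile("b2", x, "GTG5"))],
        }
        out = reproducibility_cutoff(pairs)
        assert out["csM13"] == pytest.approx(100.0)
        assert out["overall"] == pytest.approx(100.0)
        assert out["conservative"] == 95.0

    def test_synthetic_duplicates_match_generator_target(self, default_dataset):
        from lesionflora.synthetic import simulate_fingerprints
        sub = default_dataset["records"].head(150).reset_index(drop=True)
        prof = simulate_fingerprints(sub, default_dataset["config"])
        dups = {pr: [(next(q for q in ps if q.record_id == p.is_duplicate_of), p)
                     for p in ps if p.is_duplicate_of]
                for pr, ps in prof.items()}
        out = reproducibility_cutoff(dups)
        assert 94.0 <= out["overall"] <= 97.0

    def test_no_duplicates_is_error(self):
        with pytest.raises(ValueError):
            reproducibility_cutoff({"csM13": []})


class TestIRC:
    def test_worked_totals(self):
        assert irc_percent(135, 2064) == pytest.approx(6.54, abs=0.005)

    def test_no_linked_pairs_gives_zero(self):
        records = pd.DataFrame({
            "record_id": ["R1", "R2"], "sample_id": ["S1", "S1"],
            "genus": ["g", "g"],
        })
        sim = SimilarityMatrix(["R1", "R2"], np.array([[100.0, 50], [50, 100]]))
        pct, red = irc(records, sim)
        assert pct == 0 and red == []

    def test_connected_component_counted_once(self):
        # 3 mutually linked same-genus records in one lesion: 2 redundant
        records = pd.DataFrame({
            "record_id": ["R1", "R2", "R3"], "sample_id": ["S1"] * 3,
            "genus": ["g"] * 3,
        })
        S = np.full((3, 3), 97.0)
        np.fill_diagonal(S, 100.0)
        pct, red = irc(records, SimilarityMatrix(["R1", "R2", "R3"], S))
        assert len(red) == 2
        assert pct == pytest.approx(100 * 2 / 3)

    def test_transitive_chain_not_double_counted(self):
        # R1-R2 and R2-R3 linked, R1-R3 not: still one component, 2 redundant
        records = pd.DataFrame({
            "record_id": ["R1", "R2", "R3"], "sample_id": ["S1"] * 3,
            "genus": ["g"] * 3,
        })
        S = np.array([[100.0, 96, 80], [96, 100, 96], [80, 96, 100]])
        pct, red = irc(records, SimilarityMatrix(["R1", "R2", "R3"], S))
        assert len(red) == 2

    def test_different_lesions_never_redundant(self):
        records = pd.DataFrame({
            "record_id": ["R1", "R2"], "sample_id": ["S1", "S2"],
            "genus": ["g", "g"],
        })
        S = np.full((2, 2), 99.0)
        np.fill_diagonal(S, 100.0)
        pct, _ = irc(records, SimilarityMatrix(["R1", "R2"], S))
        assert pct == 0


class TestIO:
    def test_fingerprint_tsv_round_trip(self, tmp_path):
        profiles = [profile("a", [1, 2, 3]), profile("b", [3, 2, 1]),
                    profile("a-dup", [1, 2, 3.1], dup="a")]
        write_fingerprints(profiles, tmp_path / "fp.tsv")
        back = read_fingerprints(tmp_path / "fp.tsv")
        assert len(back["csM13"]) == 3
        dup = [p for p in back["csM13"] if p.is_duplicate_of][0]
        assert dup.is_duplicate_of == "a"
        np.testing.assert_allclose(back["csM13"][0].intensities, [1, 2, 3])

    def test_newick_export_parses(self):
        S = np.array([[100.0, 90, 50], [90, 100, 50], [50, 50, 100]])
        nwk = upgma(SimilarityMatrix(["A", "B", "C"], S)).to_newick()
        assert nwk.endswith(";") and "A" in nwk and "(" in nwk
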