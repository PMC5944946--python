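import numpy as np
import pandas as pd
import pytest

from ribophase.community import (
    bray_curtis,
    cluster_samples,
    dataset_overlap,
    ks_compare_groups,
    pair_coupling,
    percent_of_union,
    season_agreement,
    simprof_test,
    venn_partition,
)
from ribophase.io_tables import OtuTable
from ribophase.synthetic_data import simulate_null


def brute_bray_curtis(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_worked_example(self):
        assert bray_curtis([1, 2], [2, 0]) == pytest.approx(0.6)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            n = rng.integers(2, 20)
            x = rng.integers(0, 10, n)
            y = rng.integers(0, 10, n)
            if (x + y).sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(brute_bray_curtis(x, y), abs=1e-9)


class TestSimprof:
    def test_identical_samples_no_structure(self):
        x = np.tile([5, 3, 2, 1], (4, 1))
        res = simprof_test(x, n_expected=50, n_test=49, seed=0)
        assert res.pi == 0.0
        assert res.p == 1.0

    def test_planted_groups_detected(self):
        rng = np.random.default_rng(0)
        a = rng.multinomial(1000, [0.7, 0.1, 0.1, 0.1], size=6)
        b = rng.multinomial(1000, [0.1, 0.1, 0.1, 0.7], size=6)
        res = simprof_test(np.vstack([a, b]), n_expected=200, n_test=199, seed=1)
        assert res.p <= 0.05

    def test_null_rarely_rejected(self):
        rejections = 0
        for i in range(40):
            t = simulate_null(12, 60, 800, seed=i)
            res = simprof_test(t.counts.to_numpy(), n_expected=150, n_test=149, seed=i)
            rejections += res.significant
        assert rejections <= 6  # alpha=0.05: expect ~2 of 40

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            simprof_test(np.array([[1, 2, 3]]))


def _dated_table(counts, molecule=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = [f"S{i + 1}" for i in range(n)]
    dates = pd.Series(pd.date_range("2013-01-01", periods=n, freq="7D"), index=ids)
    mol = pd.Series(molecule or ["rDNA"] * n, index=ids)
    return OtuTable(
        pd.DataFrame(counts, index=pd.Index(ids), columns=[f"OTU{j + 1}" for j in range(counts.shape[1])]),
        dates=dates,
        molecule=mol,
    )


class TestClusterSamples:
    def test_identical_samples_single_cluster_everywhere(self):
        t = _dated_table(np.tile([5, 3, 2], (3, 1)))
        res = cluster_samples(t, n_expected=50, n_test=49, seed=0)
        for sim in (25, 40, 90):
            assert res.n_clusters_at(sim) == 1

    def test_duplicates_merge_at_full_similarity(self):
        t = _dated_table([[5, 3, 2], [5, 3, 2], [50, 1, 1]])
        res = cluster_samples(t, run_simprof=False)
        labels = res.labels_at(99.9)
        assert labels["S1"] == labels["S2"] != labels["S3"]

    def test_cut_monotonicity(self):
        rng = np.random.default_rng(2)
        t = _dated_table(rng.integers(0, 40, size=(8, 15)))
        res = cluster_samples(t, run_simprof=False)
        coarse = res.labels_at(10)
        fine = res.labels_at(60)
        # samples split at low similarity stay split at high similarity
        for i in range(8):
            for j in range(i):
                a, b = f"S{i + 1}", f"S{j + 1}"
                if coarse[a] != coarse[b]:
                    assert fine[a] != fine[b]

    def test_planted_two_group_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.multinomial(2000, np.r_[np.full(5, 0.19), np.full(15, 0.05 / 15)], size=5)
        b = rng.multinomial(2000, np.r_[np.full(15, 0.05 / 15), np.full(5, 0.19)], size=5)
        t = _dated_table(np.vstack([a, b]))
        res = cluster_samples(t, n_expected=200, n_test=199, seed=4)
        labels = res.labels_at(25)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        assert res.homogeneous_groups().nunique() >= 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(_dated_table([[1, 2], [2, 1]]))


class TestPairCoupling:
    def test_paired_duplicates_all_adjacent_and_coclustered(self):
        counts = [[50, 5, 1], [50, 5, 1], [1, 40, 9], [1, 40, 9]]
        t = _dated_table(counts, molecule=["rDNA", "rRNA", "rDNA", "rRNA"])
        res = cluster_samples(t, run_simprof=False)
        pairs = [("S1", "S2"), ("S3", "S4")]
        n_adj, n_same = pair_coupling(res, pairs)
        assert (n_adj, n_same) == (2, 2)

    def test_pairs_in_different_planted_groups(self):
        counts = [[100, 0, 0], [0, 100, 0], [100, 1, 0], [0, 99, 1]]
        t = _dated_table(counts, molecule=["rDNA", "rRNA", "rDNA", "rRNA"])
        res = cluster_samples(t, run_simprof=False)
        n_adj, n_same = pair_coupling(res, [("S1", "S2"), ("S3", "S4")])
        assert n_same == 0

    def test_adjacency_never_exceeds_coclustering(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            base = rng.multinomial(3000, np.full(25, 0.04), size=6).repeat(2, axis=0)
            noisy = base + rng.integers(0, 30, size=base.shape)
            mol = ["rDNA", "rRNA"] * 6
            ids = [f"S{i + 1}" for i in range(12)]
            t = OtuTable(
                pd.DataFrame(noisy, index=pd.Index(ids), columns=[f"OTU{j}" for j in range(25)]),
                dates=pd.Series(
                    pd.date_range("2013-01-01", periods=6, freq="7D").repeat(2), index=ids
                ),
                molecule=pd.Series(mol, index=ids),
            )
            res = cluster_samples(t, run_simprof=False)
            pairs = [(f"S{i + 1}", f"S{i + 2}") for i in range(0, 12, 2)]
            n_adj, n_same = pair_coupling(res, pairs, similarity_pct=40)
            assert n_adj <= n_same


class TestSeasonAgreement:
    def test_perfect_agreement(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        seasons = pd.Series(["w", "w", "s", "s"], index=list("abcd"))
        assert season_agreement(labels, seasons) == 1.0

    def test_one_mislabeled_of_ten(self):
        idx = [f"x{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=idx)
        seasons = pd.Series(["w"] * 5 + ["s"] * 4 + ["w"], index=idx)
        assert season_agreement(labels, seasons) == pytest.approx(0.9)

    def test_random_labels_near_majority_baseline(self):
        # Monte-Carlo oracle for the majority-vote baseline
        rng = np.random.default_rng(11)
        n, k = 300, 3
        fracs, oracle = [], []
        for rep in range(30):
            labels = pd.Series(rng.integers(0, k, n), index=range(n))
            seasons = pd.Series(rng.integers(0, k, n), index=range(n))
            fracs.append(season_agreement(labels, seasons))
            # oracle: per cluster, expected majority share of a random split
            tot = 0
            for c in range(k):
                members = seasons[labels == c]
                if len(members):
                    tot += members.value_counts().iloc[0]
            oracle.append(tot / n)
        assert np.mean(fracs) == pytest.approx(np.mean(oracle), abs=1e-12)
        assert 1 / k < np.mean(fracs) < 0.5


class TestVennPartition:
    def _three_cluster_table(self, counts):
        t = _dated_table(counts)
        labels = pd.Series([1, 2, 3], index=t.sample_ids)
        return t, labels

    def test_disjoint_clusters_empty_center(self):
        t, labels = self._three_cluster_table(
            [[1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 0, 0], [0, 0, 0, 0, 1, 1]]
        )
        v = venn_partition(labels, t)
        assert v.center_count == 0
        assert v.n_union == 6

    def test_everything_shared(self):
        t, labels = self._three_cluster_table([[1, 1, 1], [2, 1, 1], [1, 3, 1]])
        v = venn_partition(labels, t)
        assert v.center_count == v.n_union == 3

    def test_region_counts_sum_to_union_on_random_tables(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 3, size=(3, rng.integers(4, 30)))
            counts[:, counts.sum(axis=0) == 0] += 1
            t, labels = self._three_cluster_table(counts)
            v = venn_partition(labels, t)
            assert sum(v.region_counts.values()) == v.n_union

    def test_rounded_percentage_convention(self):
        assert percent_of_union(199, 868) == 23

    def test_empty_cluster_rejected(self):
        t = _dated_table([[1, 1], [1, 1], [1, 1]])
        labels = pd.Series([1, 1, 2], index=t.sample_ids)
        with pytest.raises(ValueError):
            venn_partition(labels, t, clusters=[1, 2, 3])


class TestKsCompare:
    def test_identical_vectors(self):
        d, p = ks_compare_groups([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_ecdf_scan_oracle(self):
        a, b = [1, 2, 3], [1, 2, 3, 100]
        grid = sorted(set(a) | set(b))
        brute = max(
            abs(sum(x <= g for x in a) / len(a) - sum(x <= g for x in b) / len(b))
            for g in grid
        )
        d, _ = ks_compare_groups(a, b)
        assert d == pytest.approx(brute, abs=1e-9)

    def test_disjoint_supports(self):
        d, _ = ks_compare_groups([1, 2], [10, 11])
        assert d == 1.0


class TestDatasetOverlap:
    def test_survey_counts_arithmetic(self):
        dna = {f"OTU{i}" for i in range(696)}                      # 168 unique
        rna = {f"OTU{i}" for i in range(168, 868)}                 # 700, 172 unique
        res = dataset_overlap(dna, rna)
        assert res.n_shared == 528
        assert res.n_union == 868
        assert res.pct_shared == pytest.approx(60.83, abs=0.01)
        assert res.pct_shared > 60

    def test_identical_and_disjoint_sets(self):
        assert dataset_overlap({"a", "b"}, {"a", "b"}).pct_shared == 100.0
        assert dataset_overlap({"a"}, {"b"}).pct_shared == 0.0

    def test_union_decomposition_on_random_sets(self, rng):
        for _ in range(50):
            a = {int(x) for x in rng.integers(0, 40, rng.integers(1, 30))}
            b = {int(x) for x in rng.integers(0, 40, rng.integers(1, 30))}
            r = dataset_overlap(a, b)
            assert r.n_union == r.n_shared + r.n_dna_only + r.n_rna_only
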