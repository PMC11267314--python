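import itertools

import numpy as np
import pytest

import pansv.io as pio
from pansv.models import ValidationError
from pansv.pangene import (
    CATEGORIES,
    PresenceMatrix,
    classify_clusters,
    new_cluster_increments,
    per_assembly_composition,
    saturation_curve,
)


def matrix_from_presence(presence_counts, n_haps, rng=None):
    """Matrix whose cluster i is present in presence_counts[i] haplotypes."""
    rng = rng or np.random.default_rng(0)
    counts = np.zeros((len(presence_counts), n_haps), dtype=int)
    for i, k in enumerate(presence_counts):
        cols = rng.choice(n_haps, size=k, replace=False)
        counts[i, cols] = rng.integers(1, 4, size=k)
    clusters = [f"c{i}" for i in range(len(presence_counts))]
    haps = [f"h{j}" for j in range(n_haps)]
    return PresenceMatrix(clusters, haps, counts)


def brute_force_labels(matrix, softcore_fraction=0.80):
    """Independent re-derivation of category labels from presence counts."""
    n = len(matrix.haplotypes)
    labels = {}
    for i, cluster in enumerate(matrix.clusters):
        k = sum(1 for x in matrix.gene_counts[i] if x > 0)
        if k == n:
            labels[cluster] = "core"
        elif k == 1:
            labels[cluster] = "cloud"
        elif k / n > softcore_fraction:
            labels[cluster] = "softcore"
        else:
            labels[cluster] = "shell"
    return labels


class TestClassify:
    def test_definitions_n14(self):
        m = matrix_from_presence([14, 1, 12, 11], 14)
        labels = classify_clusters(m).labels
        assert labels["c0"] == "core"
        assert labels["c1"] == "cloud"
        assert labels["c2"] == "softcore"  # 12/14 = 0.857 > 0.80
        assert labels["c3"] == "shell"  # 11/14 = 0.786 <= 0.80

    def test_random_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 15, size=200)
        m = matrix_from_presence(counts, 14, rng)
        cl = classify_clusters(m)
        assert cl.labels == brute_force_labels(m)

    def test_zero_presence_cluster_rejected(self):
        with pytest.raises(ValidationError):
            PresenceMatrix(["c0"], ["h0", "h1"], np.zeros((1, 2), dtype=int))

    def test_counts_invariant_to_order(self):
        rng = np.random.default_rng(3)
        m = matrix_from_presence(rng.integers(1, 6, size=50), 5, rng)
        base = classify_clusters(m).counts
        perm_r = rng.permutation(len(m.clusters))
        perm_c = rng.permutation(len(m.haplotypes))
        m2 = PresenceMatrix(
            [m.clusters[i] for i in perm_r],
            [m.haplotypes[j] for j in perm_c],
            m.gene_counts[np.ix_(perm_r, perm_c)],
        )
        assert classify_clusters(m2).counts == base

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        m = matrix_from_presence(rng.integers(1, 15, size=120), 14, rng)
        cl = classify_clusters(m)
        assert sum(cl.counts.values()) == 120
        assert sum(cl.cluster_fractions.values()) == pytest.approx(1.0)
        assert sum(cl.gene_fractions.values()) == pytest.approx(1.0)


class TestPerAssembly:
    def test_all_core(self):
        m = matrix_from_presence([3, 3, 3], 3)
        comp = per_assembly_composition(m, classify_clusters(m))
        assert np.allclose(comp["core"], 1.0)
        assert np.allclose(comp[["softcore", "shell", "cloud"]], 0.0)

    def test_toy_hand_arithmetic(self):
        counts = np.array([[2, 1, 1], [0, 3, 0], [1, 1, 0]])
        m = PresenceMatrix(["a", "b", "c"], ["h0", "h1", "h2"], counts)
        cl = classify_clusters(m)
        assert cl.labels == {"a": "core", "b": "cloud", "c": "shell"}
        comp = per_assembly_composition(m, cl)
        # h1 has 1 core + 3 cloud + 1 shell genes
        assert comp.loc["h1", "core"] == pytest.approx(1 / 5)
        assert comp.loc["h1", "cloud"] == pytest.approx(3 / 5)
        assert comp.loc["h1", "shell"] == pytest.approx(1 / 5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        m = matrix_from_presence(rng.integers(1, 15, size=80), 14, rng)
        comp = per_assembly_composition(m, classify_clusters(m))
        assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-9)


class TestSaturation:
    def test_prefix_one_and_full(self):
        rng = np.random.default_rng(9)
        m = matrix_from_presence(rng.integers(1, 6, size=40), 5, rng)
        curve = saturation_curve(m)
        per_hap = m.present.sum(axis=0)
        assert curve.pan_mean[0] == pytest.approx(per_hap.mean())
        assert curve.core_mean[0] == pytest.approx(per_hap.mean())
        assert curve.pan_mean[-1] == 40
        core_count = classify_clusters(m).counts["core"]
        assert curve.core_mean[-1] == core_count
        assert curve.pan_sd[-1] == 0.0
        assert curve.core_sd[-1] == 0.0

    def test_monotone(self):
        rng = np.random.default_rng(13)
        m = matrix_from_presence(rng.integers(1, 7, size=60), 6, rng)
        curve = saturation_curve(m)
        assert (np.diff(curve.pan_mean) >= -1e-12).all()
        assert (np.diff(curve.core_mean) <= 1e-12).all()

    def test_exhaustive_matches_enumeration_n4(self):
        rng = np.random.default_rng(21)
        m = matrix_from_presence(rng.integers(1, 5, size=30), 4, rng)
        curve = saturation_curve(m)  # auto-exhaustive for N <= 8
        assert curve.exhaustive and curve.n_orderings == 24
        # independent enumeration of all 24 orderings
        present = m.present
        pans = np.zeros((24, 4))
        cores = np.zeros((24, 4))
        for oi, order in enumerate(itertools.permutations(range(4))):
            seen_any = np.zeros(30, dtype=bool)
            seen_all = np.ones(30, dtype=bool)
            for k, h in enumerate(order):
                seen_any |= present[:, h]
                seen_all &= present[:, h]
                pans[oi, k] = seen_any.sum()
                cores[oi, k] = seen_all.sum()
        assert np.allclose(curve.pan_mean, pans.mean(axis=0))
        assert np.allclose(curve.core_mean, cores.mean(axis=0))

    def test_sampled_close_to_exhaustive(self):
        rng = np.random.default_rng(23)
        m = matrix_from_presence(rng.integers(1, 5, size=30), 4, rng)
        exact = saturation_curve(m, exhaustive=True)
        sampled = saturation_curve(m, n_permutations=500, seed=0, exhaustive=False)
        se = sampled.pan_sd / np.sqrt(sampled.n_orderings)
        assert (np.abs(sampled.pan_mean - exact.pan_mean) <= 3 * se + 1e-9).all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(31)
        m = matrix_from_presence(rng.integers(1, 10, size=50), 9, rng)
        a = saturation_curve(m, 50, seed=4, exhaustive=False)
        b = saturation_curve(m, 50, seed=4, exhaustive=False)
        assert np.array_equal(a.pan_mean, b.pan_mean)
        assert np.array_equal(a.core_sd, b.core_sd)


class TestIncrements:
    def test_single_haplotype(self):
        m = PresenceMatrix(["a", "b"], ["h0"], np.array([[1], [2]]))
        assert new_cluster_increments(m, ["h0"]) == [2]

    def test_unique_to_last(self):
        counts = np.array([[1, 1], [0, 1]])
        m = PresenceMatrix(["a", "b"], ["h0", "h1"], counts)
        assert new_cluster_increments(m, ["h0", "h1"])[-1] >= 1

    def test_random_matches_set_oracle(self):
        rng = np.random.default_rng(17)
        m = matrix_from_presence(rng.integers(1, 6, size=50), 5, rng)
        order = [m.haplotypes[i] for i in rng.permutation(5)]
        incs = new_cluster_increments(m, order)
        # set-algebra oracle
        idx = {h: j for j, h in enumerate(m.haplotypes)}
        seen: set[int] = set()
        expected = []
        for h in order:
            col = {i for i in range(50) if m.present[i, idx[h]]}
            expected.append(len(col - seen))
            seen |= col
        assert incs == expected
        assert sum(incs) == 50

    def test_not_a_permutation(self):
        m = matrix_from_presence([2, 1], 2)
        with pytest.raises(ValidationError):
            new_cluster_increments(m, ["h0", "h0"])


class TestOnSyntheticCohort:
    def test_truth_categories_recovered_exactly(self, bundle, cohort, truth):
        og = pio.read_orthogroups(bundle.orthogroups, cohort)
        m = PresenceMatrix.from_orthogroups(og, cohort.haplotype_ids)
        cl = classify_clusters(m)
        expected = truth[truth.entity_type == "cluster"].set_index("id")["planted_label"]
        mismatches = [c for c in m.clusters if cl.labels[c] != expected[c]]
        assert mismatches == []

    def test_mean_core_gene_fraction_near_reported(self, bundle, cohort):
        og = pio.read_orthogroups(bundle.orthogroups, cohort)
        m = PresenceMatrix.from_orthogroups(og, cohort.haplotype_ids)
        comp = per_assembly_composition(m, classify_clusters(m))
        assert abs(comp["core"].mean() * 100 - 64.3) <= 5.0

    def test_category_partition(self, bundle, cohort):
        og = pio.read_orthogroups(bundle.orthogroups, cohort)
        m = PresenceMatrix.from_orthogroups(og, cohort.haplotype_ids)
        cl = classify_clusters(m)
        assert set(cl.labels.values()) <= set(CATEGORIES)
        assert sum(cl.counts.values()) == len(m.clusters)
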