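"""Clustering machinery: dissimilarities, trees, AC, FANNY, silhouettes."""

import itertools

import numpy as np
import pytest

from hydrocode.clusterkit import (
    SECOND_BASE_GROUPS,
    agglomerative_coefficient,
    agnes,
    amino_acid_clustering,
    avg_silhouette,
    cophenetic_correlation,
    cut_tree,
    dissimilarity,
    fanny,
)

rng = np.random.default_rng(1234)


class TestDissimilarity:
    def test_identical_rows_zero(self):
        d = dissimilarity(np.array([[1.0, 2.0], [1.0, 2.0]]), "manhattan")
        assert d.matrix[0, 1] == 0.0

    def test_manhattan_example(self):
        d = dissimilarity(np.array([[0.0, 0.0], [1.0, 1.0]]), "manhattan")
        assert d.matrix[0, 1] == 2.0

    def test_matches_brute_force_double_loop(self):
        X = rng.normal(size=(6, 2))
        d = dissimilarity(X, "manhattan").matrix
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(np.abs(X[i] - X[j]).sum())

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            dissimilarity(np.array([[np.nan, 0.0], [1.0, 1.0]]))


class TestAgnes:
    def test_two_points_single_merge(self):
        d = dissimilarity(np.array([[0.0], [3.0]]), "manhattan")
        dend = agnes(d, "upgma")
        assert dend.linkage.shape == (1, 4)
        assert dend.linkage[0, 2] == pytest.approx(3.0)

    @pytest.mark.parametrize("method", ["ward", "upgma"])
    def test_top_split_separates_two_far_pairs(self, method):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        dend = agnes(dissimilarity(X), method)
        labels = cut_tree(dend, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[0] != labels[2]

    def test_upgma_heights_match_sequential_averaging_oracle(self):
        """UPGMA on 5 points vs a textbook re-implementation (nearest pair,
        size-weighted average of distances)."""
        X = rng.normal(size=(5, 2))
        d = dissimilarity(X, "euclidean")
        dend = agnes(d, "upgma")

        # oracle: independent naive UPGMA
        D = {frozenset([i]): None for i in range(5)}
        clusters = [frozenset([i]) for i in range(5)]
        dist = {frozenset([a, b]): d.matrix[a, b] for a, b in itertools.combinations(range(5), 2)}

        def cdist(c1, c2):
            return np.mean([d.matrix[i, j] for i in c1 for j in c2])

        heights = []
        while len(clusters) > 1:
            pair = min(itertools.combinations(clusters, 2), key=lambda p: cdist(*p))
            heights.append(cdist(*pair))
            clusters = [c for c in clusters if c not in pair] + [pair[0] | pair[1]]
        np.testing.assert_allclose(sorted(dend.linkage[:, 2]), sorted(heights), rtol=1e-12)

    def test_upgma_heights_monotone(self):
        X = rng.normal(size=(12, 3))
        dend = agnes(dissimilarity(X, "euclidean"), "upgma")
        assert np.all(np.diff(dend.linkage[:, 2]) >= -1e-12)

    def test_newick_export_parses(self):
        import io

        from Bio import Phylo

        dend = agnes(dissimilarity(rng.normal(size=(5, 2)), labels=list("ABCDE")), "upgma")
        tree = Phylo.read(io.StringIO(dend.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("ABCDE")


class TestAgglomerativeCoefficient:
    def test_two_leaves_zero(self):
        dend = agnes(dissimilarity(np.array([[0.0], [1.0]])), "upgma")
        assert agglomerative_coefficient(dend) == 0.0

    def test_matches_direct_formula_on_six_leaves(self):
        X = rng.normal(size=(6, 2))
        dend = agnes(dissimilarity(X), "upgma")
        Z = dend.linkage
        # direct formula: walk the merge list per leaf
        first = {}
        members = {i: [i] for i in range(6)}
        for k, (i, j, h, _) in enumerate(Z):
            merged = members[int(i)] + members[int(j)]
            for leaf in merged:
                first.setdefault(leaf, h)
            members[6 + k] = merged
        expected = np.mean([1 - first[leaf] / Z[-1, 2] for leaf in range(6)])
        assert agglomerative_coefficient(dend) == pytest.approx(expected)

    def test_in_unit_interval_and_monotone_in_separation(self):
        acs = []
        for gap in (1.0, 5.0, 25.0):
            X = np.concatenate([rng.normal(size=10), gap + rng.normal(size=10)])[:, None]
            ac = agglomerative_coefficient(agnes(dissimilarity(X), "upgma"))
            assert 0.0 <= ac <= 1.0
            acs.append(ac)
        assert acs == sorted(acs)


class TestFanny:
    def test_identical_points_uniform_membership(self):
        d = dissimilarity(np.zeros((5, 2)))
        fz = fanny(d, k=2)
        np.testing.assert_allclose(fz.membership, 1.0 / 2.0)

    def test_three_tight_triplets_recovered(self):
        X = np.concatenate([c + 0.01 * rng.normal(size=(3, 2)) for c in ([0, 0], [10, 0], [0, 10])])
        fz = fanny(dissimilarity(X), k=3)
        labels = fz.crisp_labels
        assert len({tuple(labels[i : i + 3]) for i in range(0, 9, 3)}) == 3
        for i in range(0, 9, 3):
            assert len(set(labels[i : i + 3])) == 1

    def test_membership_rows_sum_to_one(self):
        fz = fanny(dissimilarity(rng.normal(size=(8, 2))), k=3)
        np.testing.assert_allclose(fz.membership.sum(axis=1), 1.0, atol=1e-9)
        assert (fz.membership >= 0).all()

    def test_objective_matches_exhaustive_grid_search(self):
        """On 4 points / k=2 the converged objective matches (to 2 d.p.) the
        best value over an exhaustive membership grid, and never exceeds it."""
        X = np.array([[0.0], [0.7], [8.0], [8.9]])
        d = dissimilarity(X)
        fz = fanny(d, k=2)

        def grid_min(axes):
            combos = np.array(np.meshgrid(*axes)).reshape(4, -1).T  # (B, 4)
            costs = np.zeros(len(combos))
            for t in (combos**2, (1.0 - combos) ** 2):
                num = np.einsum("bi,ij,bj->b", t, d.matrix, t)
                den = 2.0 * t.sum(axis=1)
                costs += np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
            i = int(np.argmin(costs))
            return float(costs[i]), combos[i]

        # exhaustive coarse grid over u[:, 0], then refined around its basin
        coarse, at = grid_min([np.linspace(0, 1, 21)] * 4)
        fine, _ = grid_min([np.clip(np.linspace(c - 0.05, c + 0.05, 21), 0, 1) for c in at])
        best = min(coarse, fine)
        assert fz.objective <= best + 1e-9
        assert fz.objective == pytest.approx(best, abs=0.01)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            fanny(dissimilarity(rng.normal(size=(4, 2))), k=4)


class TestSilhouette:
    def test_two_far_tight_clusters_near_one(self):
        X = np.concatenate([0.001 * rng.normal(size=(5, 1)), 1000 + 0.001 * rng.normal(size=(5, 1))])
        d = dissimilarity(X)
        labels = np.array([0] * 5 + [1] * 5)
        assert avg_silhouette(labels, d) > 0.99

    def test_five_point_hand_computation(self):
        # points on a line: {0, 1} cluster 0, {10, 11, 12} cluster 1
        X = np.array([[0.0], [1.0], [10.0], [11.0], [12.0]])
        d = dissimilarity(X)
        labels = np.array([0, 0, 1, 1, 1])
        s = []
        for i in range(5):
            same = [j for j in range(5) if labels[j] == labels[i] and j != i]
            other = [j for j in range(5) if labels[j] != labels[i]]
            a = np.mean([d.matrix[i, j] for j in same])
            b = np.mean([d.matrix[i, j] for j in other])
            s.append((b - a) / max(a, b))
        assert avg_silhouette(labels, d) == pytest.approx(np.mean(s))

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            avg_silhouette(np.zeros(4, dtype=int), dissimilarity(rng.normal(size=(4, 1))))


class TestCophenetic:
    def test_ultrametric_input_gives_one(self):
        # two tight pairs; UPGMA cophenetic distances reproduce such data well
        X = np.array([[0.0], [0.0], [4.0], [4.0]])
        d = dissimilarity(X)
        dend = agnes(d, "upgma")
        assert cophenetic_correlation(dend, d) == pytest.approx(1.0)

    def test_matches_brute_force_extraction(self):
        X = rng.normal(size=(6, 2))
        d = dissimilarity(X, "euclidean")
        dend = agnes(d, "upgma")
        Z = dend.linkage
        # brute force: cophenetic distance = height of the lowest common merge
        members = {i: {i} for i in range(6)}
        coph = np.zeros((6, 6))
        for k, (i, j, h, _) in enumerate(Z):
            a, b = members[int(i)], members[int(j)]
            for p in a:
                for q in b:
                    coph[p, q] = coph[q, p] = h
            members[6 + k] = a | b
        iu = np.triu_indices(6, 1)
        expected = np.corrcoef(d.matrix[iu], coph[iu])[0, 1]
        assert cophenetic_correlation(dend, d) == pytest.approx(expected)


@pytest.fixture(scope="module")
def results():
    return {t: amino_acid_clustering(t) for t in (25, 100)}


class TestAminoAcidClustering:
    @pytest.mark.parametrize("temperature", [25, 100])
    def test_recovers_second_base_groups(self, results, temperature):
        assert set(results[temperature].groups) == set(SECOND_BASE_GROUPS)

    def test_partition_temperature_independent(self, results):
        assert set(results[25].groups) == set(results[100].groups)

    def test_fanny_crisp_agrees_with_ward_cut(self, results):
        for res in results.values():
            fz_groups = {
                frozenset(
                    aa
                    for aa, lab in zip(res.dendrogram.leaf_labels, res.fuzzy.crisp_labels)
                    if lab == g
                )
                for g in set(res.fuzzy.crisp_labels)
            }
            assert fz_groups == set(res.groups)

    def test_permutation_invariance(self):
        """Permuting the row order of the input yields the same partition."""
        from hydrocode.codebook import AMINO_ACIDS
        from hydrocode.scales import get_scale, standardize

        hydro, davis = get_scale("logkwc_25"), get_scale("davis")
        perm = rng.permutation(20)
        order = [AMINO_ACIDS[i] for i in perm]
        X = np.column_stack(
            [standardize(hydro.vector(order)), standardize(davis.vector(order))]
        )
        dend = agnes(dissimilarity(X, "manhattan", labels=order), "ward")
        labels = cut_tree(dend, 3)
        groups = {
            frozenset(aa for aa, lab in zip(order, labels) if lab == g) for g in set(labels)
        }
        assert groups == set(SECOND_BASE_GROUPS)
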