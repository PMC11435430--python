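import numpy as np
import pytest

from pearsnp import (
    MISSING,
    DistanceMatrix,
    SimulationConfig,
    euclidean_distances,
    pca_genotypes,
    simulate_genotypes,
    upgma,
)
from pearsnp.clustering import ClusteringError
from _oracles import upgma_cophenetic_reference


class TestPca:
    def test_rank_one_structure_loads_on_pc1(self, make_matrix):
        rows = np.array([[0, 2, 0, 2, 1]] * 2 + [[2, 0, 2, 0, 1]] * 2, dtype=np.int8)
        matrix = make_matrix(rows)
        _, explained = pca_genotypes(matrix)
        assert explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_preserve_centered_geometry(self, make_matrix):
        """Distances between score rows equal distances between rows of the
        centered genotype matrix (the decomposition loses nothing)."""
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        matrix = make_matrix(calls)
        scores, explained = pca_genotypes(matrix)
        centered = calls - calls.mean(axis=0, keepdims=True)
        d_orig = np.linalg.norm(
            centered[:, None, :] - centered[None, :, :], axis=-1
        )
        d_scores = np.linalg.norm(scores[:, None, :] - scores[None, :, :], axis=-1)
        np.testing.assert_allclose(d_scores, d_orig, atol=1e-8)
        assert explained.sum() == pytest.approx(1.0)
        assert (np.diff(explained) <= 1e-12).all()

    def test_explained_fractions_invariant_to_accession_order(self, make_matrix):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(15, 40)).astype(np.int8)
        matrix = make_matrix(calls)
        perm = rng.permutation(15)
        shuffled = matrix.subset_accessions([matrix.accessions[i] for i in perm])
        _, e1 = pca_genotypes(matrix)
        _, e2 = pca_genotypes(shuffled)
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_separates_divergent_populations(self):
        config = SimulationConfig(
            n_populations=2,
            sizes=(30, 30),
            labels=("A", "B"),
            divergence_F=(0.3, 0.3),
            n_loci=300,
            missing_rate=0.0,
            n_clone_pairs=0,
            clone_mutation_loci=0,
            mean_depth=None,
            seed=4,
        )
        matrix, pops, _ = simulate_genotypes(config)
        scores, _ = pca_genotypes(matrix)
        from sklearn.metrics import silhouette_score

        labels = [pops.label_of(a) for a in matrix.accessions]
        assert silhouette_score(scores[:, :1], labels) > 0.5

    def test_all_missing_locus_dropped_with_warning(self, make_matrix):
        calls = np.array([[0, MISSING], [2, MISSING], [1, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning, match="all-missing"):
            scores, _ = pca_genotypes(make_matrix(calls))
        assert scores.shape[0] == 3


class TestEuclideanDistances:
    def test_closed_forms(self, make_matrix):
        matrix = make_matrix([[0, 0, 0], [0, 0, 0], [2, 2, 2]])
        dist = euclidean_distances(matrix)
        assert dist.values[0, 1] == 0.0
        assert dist.values[0, 2] == pytest.approx(np.sqrt(12))

    def test_missing_pair_rescaling(self, make_matrix):
        """Loci missing in either member are excluded and the squared sum is
        rescaled by L / L_shared: here one disagreement over 2 of 3 loci."""
        matrix = make_matrix([[0, 1, MISSING], [0, 2, 2]])
        dist = euclidean_distances(matrix)
        assert dist.values[0, 1] == pytest.approx(np.sqrt(1 * 3 / 2))

    def test_metric_axioms_on_complete_data(self, make_matrix):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(12, 60)).astype(np.int8)
        d = euclidean_distances(make_matrix(calls)).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_insufficient_shared_loci_is_an_error_naming_the_pair(self, make_matrix):
        calls = np.array(
            [[0, 1, MISSING, MISSING], [MISSING, MISSING, 1, 2], [0, 1, 1, 2]],
            dtype=np.int8,
        )
        with pytest.raises(ClusteringError, match="acc00.*acc01"):
            euclidean_distances(make_matrix(calls))


class TestUpgma:
    def test_three_leaf_hand_case(self):
        dist = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float),
        )
        tree = upgma(dist)
        # A,B merge at height 1; C joins at height 3
        assert tree.root.height == pytest.approx(3.0)
        first = [c for c in tree.root.children if not c.is_leaf][0]
        assert first.height == pytest.approx(1.0)
        assert sorted(first.leaves()) == ["A", "B"]
        coph = tree.cophenetic().to_frame()
        assert coph.loc["A", "B"] == pytest.approx(2.0)
        assert coph.loc["A", "C"] == pytest.approx(6.0)

    def test_reproduces_ultrametric_input_exactly(self):
        reference = upgma(
            DistanceMatrix(
                labels=list("ABCD"),
                values=np.array(
                    [
                        [0, 2, 8, 8],
                        [2, 0, 8, 8],
                        [8, 8, 0, 4],
                        [8, 8, 4, 0],
                    ],
                    dtype=float,
                ),
            )
        )
        np.testing.assert_allclose(
            reference.cophenetic().values,
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            atol=1e-12,
        )

    def test_matches_reference_implementation_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 8
            raw = rng.uniform(1, 10, size=(n, n))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            dist = DistanceMatrix(labels=[f"L{i}" for i in range(n)], values=values)
            coph = upgma(dist).cophenetic().values
            np.testing.assert_allclose(
                coph, upgma_cophenetic_reference(values), atol=1e-10
            )

    def test_merge_heights_non_decreasing_and_ultrametric(self, small_collection):
        matrix, _, _ = small_collection
        sub = matrix.subset_accessions(matrix.accessions[:40])
        tree = upgma(euclidean_distances(sub))
        heights = tree.linkage[:, 2]
        assert (np.diff(heights) >= -1e-9).all()
        coph = tree.cophenetic().values
        # ultrametric three-point condition
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.choice(40, size=3, replace=False)
            a, b, c = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert b == pytest.approx(c, rel=1e-9)

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        raw = rng.uniform(1, 5, size=(6, 6))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        labels = [f"acc{i}" for i in range(6)]
        tree = upgma(DistanceMatrix(labels=labels, values=values))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {t.label for t in parsed.taxon_namespace}
        assert taxa == set(labels)
        # every leaf sits at the same root-path depth (ultrametric)
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-6

    def test_deterministic_tie_break(self):
        values = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], dtype=float
        )
        t1 = upgma(DistanceMatrix(labels=list("ABCD"), values=values))
        t2 = upgma(DistanceMatrix(labels=list("ABCD"), values=values))
        assert t1.to_newick() == t2.to_newick()
        # lexicographically smallest pair (A,B) merges first
        np.testing.assert_array_equal(t1.linkage[0, :2], [0.0, 1.0])
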