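import numpy as np
import pytest

from pearsnp import (
    MISSING,
    SimulationConfig,
    add_clonal_mutants,
    inject_missing,
    pairwise_fst,
    simulate_genotypes,
)
from pearsnp.marker_stats import locus_stats_frame
from pearsnp.synthetic_data import SimulationError


def test_fixed_seed_reproduces_dataset_exactly():
    config = SimulationConfig(sizes=(20, 10, 10, 10, 10), n_loci=100, seed=42)
    m1, p1, t1 = simulate_genotypes(config)
    m2, p2, t2 = simulate_genotypes(config)
    np.testing.assert_array_equal(m1.calls, m2.calls)
    np.testing.assert_array_equal(m1.depth, m2.depth)
    assert m1.accessions == m2.accessions
    assert [l.marker_id for l in m1.loci] == [l.marker_id for l in m2.loci]
    assert p1.mapping == p2.mapping
    np.testing.assert_array_equal(t1.pop_alt_freq, t2.pop_alt_freq)


def test_no_divergence_limit_gives_near_zero_fst():
    """With all drift parameters at zero the populations share one frequency
    vector, so the estimated differentiation collapses to ~0."""
    config = SimulationConfig(
        n_populations=2,
        sizes=(60, 60),
        labels=("A", "B"),
        divergence_F=(0.0, 0.0),
        n_loci=500,
        missing_rate=0.0,
        n_clone_pairs=0,
        clone_mutation_loci=0,
        mean_depth=None,
        seed=3,
    )
    matrix, pops, _ = simulate_genotypes(config)
    theta = pairwise_fst(matrix, pops, ("A", "B"))
    assert abs(theta) < 0.02


def test_balding_nichols_frequency_variance():
    """Across populations with equal drift F, the cross-population variance
    of allele frequencies matches p(1-p)F within Monte-Carlo error."""
    F = 0.05
    config = SimulationConfig(
        n_populations=4,
        sizes=(5, 5, 5, 5),
        labels=("A", "B", "C", "D"),
        divergence_F=(F, F, F, F),
        n_loci=3000,
        missing_rate=0.0,
        n_clone_pairs=0,
        clone_mutation_loci=0,
        mean_depth=None,
        seed=5,
    )
    _, _, params = simulate_genotypes(config)
    p = params.ancestral_alt_freq
    sample_var = params.pop_alt_freq.var(axis=0, ddof=1)
    ratio = sample_var.mean() / (p * (1.0 - p)).mean()
    assert ratio == pytest.approx(F, rel=0.15)


def test_true_parameters_predict_observed_heterozygosity():
    """He computed from genotypes tracks the closed form mean 2q(1-q)."""
    config = SimulationConfig(
        n_populations=1,
        sizes=(200,),
        labels=("A",),
        divergence_F=(0.1,),
        n_loci=400,
        missing_rate=0.0,
        n_clone_pairs=0,
        clone_mutation_loci=0,
        mean_depth=None,
        seed=9,
    )
    matrix, pops, params = simulate_genotypes(config)
    observed = locus_stats_frame(matrix)["he_unbiased"].mean()
    assert observed == pytest.approx(params.expected_he("A"), abs=0.02)


def test_hybrid_population_averages_parent_frequencies():
    config = SimulationConfig(
        n_populations=3,
        sizes=(10, 10, 10),
        labels=("A", "B", "AxB"),
        divergence_F=(0.2, 0.2, 0.2),
        n_loci=50,
        missing_rate=0.0,
        n_clone_pairs=0,
        clone_mutation_loci=0,
        mean_depth=None,
        hybrid_parents={2: (0, 1)},
        seed=1,
    )
    _, _, params = simulate_genotypes(config)
    np.testing.assert_allclose(
        params.pop_alt_freq[2],
        0.5 * (params.pop_alt_freq[0] + params.pop_alt_freq[1]),
    )


class TestClonalMutants:
    def test_zero_mutation_clone_is_exact_duplicate(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(0).integers(0, 3, (10, 30)))
        out = add_clonal_mutants(matrix, n_pairs=1, mutated_loci=0, seed=4)
        assert out.n_accessions == 11
        clone = out.accessions[-1]
        assert clone.endswith("_mut")
        src = out.accession_index(clone.replace("_mut", ""))
        np.testing.assert_array_equal(out.calls[-1], out.calls[src])

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_clone_differs_at_exactly_k_loci(self, make_matrix, k):
        matrix = make_matrix(np.random.default_rng(1).integers(0, 3, (10, 30)))
        out = add_clonal_mutants(matrix, n_pairs=1, mutated_loci=k, seed=7)
        clone = out.accessions[-1]
        src = out.accession_index(clone.replace("_mut", ""))
        hamming = int((out.calls[-1] != out.calls[src]).sum())
        assert hamming == k
        assert not (out.calls[-1] == MISSING).any()

    def test_counts_and_errors(self, make_matrix):
        matrix = make_matrix(np.zeros((10, 5), dtype=np.int8))
        assert add_clonal_mutants(matrix, 3, 0, seed=0).n_accessions == 13
        with pytest.raises(SimulationError):
            add_clonal_mutants(matrix, 1, mutated_loci=6, seed=0)
        with pytest.raises(SimulationError):
            add_clonal_mutants(matrix, 11, 0, seed=0)


class TestInjectMissing:
    def test_zero_rate_is_identity(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(2).integers(0, 3, (20, 20)))
        out = inject_missing(matrix, 0.0, seed=1)
        np.testing.assert_array_equal(out.calls, matrix.calls)

    def test_realized_fraction_near_rate(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(3).integers(0, 3, (100, 200)))
        out = inject_missing(matrix, 0.1, seed=2)
        realized = (out.calls == MISSING).mean()
        assert 0.08 <= realized <= 0.12

    def test_mask_reproducible_under_seed(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(4).integers(0, 3, (30, 30)))
        a = inject_missing(matrix, 0.2, seed=9)
        b = inject_missing(matrix, 0.2, seed=9)
        np.testing.assert_array_equal(a.calls, b.calls)


def test_config_validation_catches_bad_inputs():
    with pytest.raises(SimulationError):
        SimulationConfig(sizes=(10, 10)).validate()  # wrong length for 5 pops
    with pytest.raises(SimulationError):
        SimulationConfig(divergence_F=(0.1, 0.2, 0.3, 1.0, 0.1)).validate()
    with pytest.raises(SimulationError):
        SimulationConfig(ancestral_maf_range=(0.0, 0.5)).validate()
    with pytest.raises(SimulationError):
        SimulationConfig(missing_rate=1.0).validate()
    with pytest.raises(SimulationError):
        SimulationConfig(n_loci=5, clone_mutation_loci=(0, 10)).validate()


def test_loci_are_sorted_unique_and_on_17_chromosomes():
    matrix, _, _ = simulate_genotypes(
        SimulationConfig(sizes=(10, 5, 5, 5, 5), n_loci=300, seed=6)
    )
    seen = set()
    last = None
    for locus in matrix.loci:
        key = (locus.chromosome, locus.position_bp)
        assert key not in seen
        seen.add(key)
        if last is not None:
            assert key >= last
        last = key
    assert {l.chromosome for l in matrix.loci} <= set(range(1, 18))
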