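import numpy as np
import pytest

from pearsnp import (
    GenotypeMatrix,
    LocusInfo,
    PopulationAssignment,
    SimulationConfig,
    simulate_genotypes,
)


@pytest.fixture
def make_matrix():
    """Factory for small hand-built genotype matrices.

    ``calls`` is a nested list/array in the 0/1/2/-1 coding; loci are placed
    1 Mb apart on chromosome 1 unless positions/chromosomes are given.
    """

    def _make(
        calls,
        accessions=None,
        depth=None,
        chromosomes=None,
        positions=None,
        ref="A",
        alt="G",
    ) -> GenotypeMatrix:
        calls = np.asarray(calls, dtype=np.int8)
        n, L = calls.shape
        if accessions is None:
            accessions = [f"acc{i:02d}" for i in range(n)]
        if chromosomes is None:
            chromosomes = [1] * L
        if positions is None:
            positions = [1_000_000 * (k + 1) for k in range(L)]
        loci = [
            LocusInfo(
                marker_id=f"m{k:03d}",
                chromosome=chromosomes[k],
                position_bp=positions[k],
                ref=ref,
                alt=alt,
            )
            for k in range(L)
        ]
        return GenotypeMatrix(
            accessions=list(accessions), loci=loci, calls=calls, depth=depth
        )

    return _make


@pytest.fixture
def two_pop_assignment():
    """Population assignment for matrices built by make_matrix: the first
    half of the accessions is population X, the second half population Y."""

    def _assign(matrix: GenotypeMatrix, split: int | None = None):
        if split is None:
            split = matrix.n_accessions // 2
        mapping = {
            a: ("X" if i < split else "Y") for i, a in enumerate(matrix.accessions)
        }
        return PopulationAssignment(mapping=mapping)

    return _assign


@pytest.fixture(scope="session")
def small_collection():
    """A reduced five-population collection shared by read-only tests."""
    config = SimulationConfig(
        sizes=(30, 20, 15, 15, 15),
        n_loci=250,
        n_clone_pairs=4,
        missing_rate=0.02,
        seed=11,
    )
    return simulate_genotypes(config)
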