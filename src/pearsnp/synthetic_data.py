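"""Synthetic multi-population genotype generator.

The generator emulates the statistical structure of a cultivated-pear
germplasm collection genotyped at a few hundred biallelic SNPs: five
predefined populations (four *Pyrus* species plus interspecific hybrids)
with unequal sample sizes, population divergence spanning weak to strong
differentiation, within-population diversity spanning narrow (European pear)
to broad (*P. pyrifolia*), a small missing-data fraction, and near-duplicate
accessions standing in for clones and bud mutants.

The divergence model is Balding–Nichols: each locus draws an ancestral
allele frequency ``p``; population ``k`` with drift parameter ``F_k`` draws
its own frequency from ``Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``, and each
diploid genotype is two binomial draws from that frequency.  The model gives
every population pair a known target differentiation (for the Hudson-style
estimand, approximately the mean of the two drift parameters), so estimator
recovery can be tested quantitatively against recorded true frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    LocusInfo,
    PopulationAssignment,
)

#: Approximate chromosome spans (bp) of the 17 pear chromosomes, used to
#: place simulated loci; proportions follow the physical coverage of a
#: pear reference assembly (~480 Mb total).
PEAR_CHROMOSOME_LENGTHS_BP: tuple[int, ...] = (
    23_120_000, 31_750_000, 31_600_000, 19_460_000, 35_230_000, 22_020_000,
    36_070_000, 26_490_000, 24_990_000, 20_990_000, 35_070_000, 24_610_000,
    29_540_000, 22_550_000, 39_620_000, 25_450_000, 31_980_000,
)

DEFAULT_POPULATION_LABELS: tuple[str, ...] = (
    "P. pyrifolia",
    "P. ussuriensis",
    "P. bretschneideri",
    "P. communis",
    "interspecific hybrid",
)

_POP_CODES = {
    "P. pyrifolia": "PYR",
    "P. ussuriensis": "USS",
    "P. bretschneideri": "BRE",
    "P. communis": "COM",
    "interspecific hybrid": "HYB",
}


class SimulationError(ValueError):
    """Invalid simulation configuration or request."""


@dataclass
class SimulationConfig:
    """Study conditions for the genotype simulator.

    Defaults emulate the structure of the pear collection the pipeline is
    designed for: five populations with sample sizes (86, 27, 19, 26, 26)
    totalling 184 accessions, plus 8 clone pairs (192 accessions in all);
    900 loci spread over 17 chromosomes; drift parameters spanning weak
    (0.02) to strong (0.75) divergence; 3% missing calls; a mean read depth
    of 20x.

    ``clone_mutation_loci`` is either an exact integer (every clone differs
    from its source at exactly that many loci) or an inclusive ``(lo, hi)``
    range from which each clone's count is drawn uniformly — the default
    ``(0, 2)`` emulates somatic/bud mutants differing at 0–2 assayed loci.
    """

    n_populations: int = 5
    sizes: tuple[int, ...] = (86, 27, 19, 26, 26)
    labels: tuple[str, ...] = DEFAULT_POPULATION_LABELS
    n_loci: int = 900
    chromosomes: tuple[int, ...] = PEAR_CHROMOSOME_LENGTHS_BP
    divergence_F: tuple[float, ...] = (0.02, 0.20, 0.25, 0.75, 0.05)
    ancestral_maf_range: tuple[float, float] = (0.10, 0.50)
    missing_rate: float = 0.03
    n_clone_pairs: int = 8
    clone_mutation_loci: int | tuple[int, int] = (0, 2)
    mean_depth: float | None = 20.0
    hybrid_parents: Mapping[int, tuple[int, int]] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1:
            raise SimulationError("n_populations must be >= 1")
        if len(self.sizes) != self.n_populations:
            raise SimulationError("sizes length must equal n_populations")
        if len(self.labels) != self.n_populations:
            raise SimulationError("labels length must equal n_populations")
        if len(self.divergence_F) != self.n_populations:
            raise SimulationError("divergence_F length must equal n_populations")
        if any(s < 1 for s in self.sizes):
            raise SimulationError("population sizes must be >= 1")
        if any(not (0.0 <= f < 1.0) for f in self.divergence_F):
            raise SimulationError("divergence_F entries must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimulationError("ancestral_maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must lie in [0, 1)")
        if self.n_clone_pairs < 0:
            raise SimulationError("n_clone_pairs must be >= 0")
        if self.n_loci < 1:
            raise SimulationError("n_loci must be >= 1")
        if len(self.chromosomes) < 1 or any(c < 2 for c in self.chromosomes):
            raise SimulationError("chromosome lengths must be positive")
        lohi = self._mutation_range()
        if lohi[0] < 0 or lohi[1] < lohi[0]:
            raise SimulationError("clone_mutation_loci range is invalid")
        if lohi[1] > self.n_loci:
            raise SimulationError("clone_mutation_loci exceeds n_loci")
        if self.hybrid_parents:
            for k, (i, j) in self.hybrid_parents.items():
                if not (0 <= k < self.n_populations):
                    raise SimulationError(f"hybrid population index {k} out of range")
                if not (0 <= i < self.n_populations and 0 <= j < self.n_populations):
                    raise SimulationError(f"hybrid parent indices {(i, j)} out of range")

    def _mutation_range(self) -> tuple[int, int]:
        if isinstance(self.clone_mutation_loci, (tuple, list)):
            lo, hi = self.clone_mutation_loci
            return int(lo), int(hi)
        return int(self.clone_mutation_loci), int(self.clone_mutation_loci)


@dataclass
class TrueParameters:
    """Generative ground truth recorded by :func:`simulate_genotypes`.

    ``pop_alt_freq[k, l]`` is the realized ALT-allele frequency of population
    ``k`` at locus ``l``; these suffice to recompute any population's
    expected heterozygosity in closed form and to evaluate the Hudson-style
    differentiation between any pair, giving parameter-recovery oracles for
    the estimator implementations.
    """

    labels: tuple[str, ...]
    divergence_F: tuple[float, ...]
    ancestral_alt_freq: np.ndarray
    pop_alt_freq: np.ndarray

    def expected_he(self, population: int | str) -> float:
        """Closed-form expected heterozygosity: mean over loci of 2q(1-q)."""
        k = self._index(population)
        q = self.pop_alt_freq[k]
        return float(np.mean(2.0 * q * (1.0 - q)))

    def true_fst(self, pop_a: int | str, pop_b: int | str) -> float:
        """Hudson-style multi-locus differentiation from true frequencies.

        Ratio of sums over loci of ``(p1-p2)^2`` to ``p1(1-p2)+p2(1-p1)``;
        under Balding–Nichols its expectation is close to the mean of the two
        drift parameters.
        """
        p1 = self.pop_alt_freq[self._index(pop_a)]
        p2 = self.pop_alt_freq[self._index(pop_b)]
        num = np.sum((p1 - p2) ** 2)
        den = np.sum(p1 * (1.0 - p2) + p2 * (1.0 - p1))
        return float(num / den) if den > 0 else 0.0

    def _index(self, population: int | str) -> int:
        if isinstance(population, str):
            return self.labels.index(population)
        return int(population)


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> list[LocusInfo]:
    """Place loci uniformly on the genome (chromosomes weighted by length)."""
    lengths = np.asarray(config.chromosomes, dtype=np.float64)
    weights = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=config.n_loci, p=weights)
    placements: set[tuple[int, int]] = set()
    for c in chrom_idx:
        while True:
            pos = int(rng.integers(1, config.chromosomes[c] + 1))
            if (c, pos) not in placements:
                placements.add((int(c), pos))
                break
    ordered = sorted(placements)
    nucs = np.array(list("ACGT"))
    loci = []
    for i, (c, pos) in enumerate(ordered):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            LocusInfo(
                marker_id=f"snp{i + 1:04d}",
                chromosome=c + 1,
                position_bp=pos,
                ref=str(nucs[ref]),
                alt=str(nucs[alt]),
            )
        )
    return loci


def _accession_ids(config: SimulationConfig) -> list[str]:
    codes: list[str] = []
    for k, label in enumerate(config.labels):
        code = _POP_CODES.get(
            label, "".join(ch for ch in label.upper() if ch.isalnum())[:3] or "POP"
        )
        if code in codes:
            code = f"{code}{k}"
        codes.append(code)
    ids = []
    for code, size in zip(codes, config.sizes):
        ids.extend(f"{code}{i + 1:03d}" for i in range(size))
    return ids


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationAssignment, TrueParameters]:
    """Simulate a structured diploid SNP dataset under Balding–Nichols.

    Returns the genotype matrix (clones appended and missing data injected
    according to the config), the population assignment (clones inherit
    their source's label), and the recorded ground truth (for the base
    accessions, before clone/missing post-processing).
    """
    config.validate()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    rng = np.random.default_rng(seeds[0])

    L = config.n_loci
    K = config.n_populations
    lo, hi = config.ancestral_maf_range
    maf = rng.uniform(lo, hi, size=L)
    mirror = rng.random(L) < 0.5
    p_anc = np.where(mirror, 1.0 - maf, maf)  # ancestral ALT frequency

    pop_freq = np.empty((K, L))
    for k, F in enumerate(config.divergence_F):
        if F <= 0.0:
            pop_freq[k] = p_anc
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            pop_freq[k] = rng.beta(a, b)
    if config.hybrid_parents:
        for k, (i, j) in config.hybrid_parents.items():
            pop_freq[k] = 0.5 * (pop_freq[i] + pop_freq[j])

    loci = _place_loci(config, rng)
    accessions = _accession_ids(config)
    n_total = int(sum(config.sizes))
    calls = np.empty((n_total, L), dtype=np.int8)
    row = 0
    mapping: dict[str, str] = {}
    for k, (label, size) in enumerate(zip(config.labels, config.sizes)):
        calls[row : row + size] = rng.binomial(2, pop_freq[k], size=(size, L)).astype(
            np.int8
        )
        for a in accessions[row : row + size]:
            mapping[a] = label
        row += size

    depth = None
    if config.mean_depth is not None:
        depth = rng.poisson(config.mean_depth, size=calls.shape).astype(np.int32)

    matrix = GenotypeMatrix(
        accessions=accessions, loci=loci, calls=calls, depth=depth
    )

    if config.n_clone_pairs > 0:
        lo_m, hi_m = config._mutation_range()
        clone_rng = np.random.default_rng(seeds[1])
        counts = clone_rng.integers(lo_m, hi_m + 1, size=config.n_clone_pairs)
        sources = clone_rng.choice(
            matrix.n_accessions, size=config.n_clone_pairs, replace=False
        )
        for s, m in zip(sources, counts):
            matrix = _append_clone(
                matrix, int(s), int(m), np.random.default_rng(clone_rng.integers(2**31))
            )
            clone_id = matrix.accessions[-1]
            mapping[clone_id] = mapping[matrix.accessions[int(s)]]

    if config.missing_rate > 0:
        matrix = inject_missing(
            matrix, config.missing_rate, int(np.random.default_rng(seeds[2]).integers(2**31))
        )

    populations = PopulationAssignment(mapping=mapping)
    params = TrueParameters(
        labels=tuple(config.labels),
        divergence_F=tuple(config.divergence_F),
        ancestral_alt_freq=p_anc,
        pop_alt_freq=pop_freq,
    )
    return matrix, populations, params


def _append_clone(
    matrix: GenotypeMatrix, source: int, mutated_loci: int, rng: np.random.Generator
) -> GenotypeMatrix:
    new_calls = matrix.calls[source].copy()
    if mutated_loci > 0:
        targets = rng.choice(matrix.n_loci, size=mutated_loci, replace=False)
        for t in targets:
            states = [s for s in (0, 1, 2) if s != new_calls[t]]
            new_calls[t] = states[int(rng.integers(len(states)))]
    base = matrix.accessions[source]
    name = f"{base}_mut"
    k = 2
    while name in matrix.accessions:
        name = f"{base}_mut{k}"
        k += 1
    depth = matrix.depth
    if depth is not None:
        depth = np.vstack([depth, depth[source][None, :]])
    return GenotypeMatrix(
        accessions=matrix.accessions + [name],
        loci=matrix.loci,
        calls=np.vstack([matrix.calls, new_calls[None, :]]),
        depth=depth,
    )


def add_clonal_mutants(
    matrix: GenotypeMatrix, n_pairs: int, mutated_loci: int, seed: int
) -> GenotypeMatrix:
    """Append ``n_pairs`` near-duplicate accessions (clones / bud mutants).

    Each clone copies a randomly chosen source accession and is altered at
    exactly ``mutated_loci`` randomly chosen loci; an altered call becomes a
    uniformly random *different* non-missing state.  Clone names take the
    source id with a ``_mut`` suffix.
    """
    if n_pairs > matrix.n_accessions:
        raise SimulationError("n_pairs exceeds the number of source accessions")
    if mutated_loci > matrix.n_loci:
        raise SimulationError("mutated_loci exceeds the locus count")
    rng = np.random.default_rng(seed)
    sources = rng.choice(matrix.n_accessions, size=n_pairs, replace=False)
    out = matrix
    for s in sources:
        out = _append_clone(out, int(s), mutated_loci, rng)
    return out


def inject_missing(matrix: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each non-missing call to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise SimulationError("rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    mask = (rng.random(matrix.calls.shape) < rate) & (matrix.calls != MISSING)
    calls = matrix.calls.copy()
    calls[mask] = MISSING
    return GenotypeMatrix(
        accessions=list(matrix.accessions),
        loci=list(matrix.loci),
        calls=calls,
        depth=None if matrix.depth is None else matrix.depth.copy(),
    )
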