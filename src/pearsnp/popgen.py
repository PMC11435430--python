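"""Between-population differentiation: Weir–Cockerham Fst, Nei's unbiased
standard genetic distance, and permutation-based significance.

The Fst estimator is Weir & Cockerham's (1984) theta for two populations,
combined over loci as a ratio of sums of the variance components
(``theta = sum_l a_l / sum_l (a_l + b_l + c_l)``).  Negative multi-locus
theta is reported as computed; Nei's distance is clipped at zero.  P-values
come from permuting whole multilocus genotypes (accessions) between the two
populations, with the add-one estimator ``(1 + #{theta_perm >= theta_obs})
/ (1 + n_perm)`` so that no p-value is exactly zero, and a Bonferroni
factor equal to the number of population pairs tested.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationAssignment


@dataclass(frozen=True)
class PairwiseResult:
    """One population pair: differentiation, distance, and significance."""

    pop_a: str
    pop_b: str
    fst: float
    nei_d: float
    p_raw: float
    p_bonferroni: float
    n_permutations: int


class PopgenError(ValueError):
    """Invalid population comparison request."""


# ---------------------------------------------------------------------------
# per-group allele summaries
# ---------------------------------------------------------------------------

def _group_summaries(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n, p_alt, h_obs) per locus for one group of diploid calls."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def _wc_theta_sums(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) variance-component sums for two populations.

    Operates elementwise on arrays whose last axis indexes loci; loci where
    either sample has no called genotype (or the pooled sample fewer than 3)
    are excluded.  Returns ``(sum_a, sum_abc)`` along the last axis.
    """
    r = 2.0
    valid = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 3)
    n1 = np.where(valid, n1, np.nan)
    n2 = np.where(valid, n2, np.nan)
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0

    a = np.where(valid, a, 0.0)
    abc = np.where(valid, a + np.where(valid, b, 0.0) + np.where(valid, c, 0.0), 0.0)
    return np.nansum(a, axis=-1), np.nansum(abc, axis=-1)


def _pair_calls(
    matrix: GenotypeMatrix, populations: PopulationAssignment, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    calls_by_pop = []
    for label in pair:
        idx = populations.indices_for(matrix, label)
        if idx.size == 0:
            raise PopgenError(f"population {label!r} has no accessions in the matrix")
        calls_by_pop.append(matrix.calls[idx, :])
    return calls_by_pop[0], calls_by_pop[1]


def pairwise_fst(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    pair: tuple[str, str],
) -> float:
    """Multi-locus Weir–Cockerham theta between two populations."""
    calls_a, calls_b = _pair_calls(matrix, populations, pair)
    n1, p1, h1 = _group_summaries(calls_a)
    n2, p2, h2 = _group_summaries(calls_b)
    if not ((n1 >= 2) & (n2 >= 2)).any():
        raise PopgenError(
            f"populations {pair} share no locus with >= 2 called diploids each"
        )
    sum_a, sum_abc = _wc_theta_sums(n1, p1, h1, n2, p2, h2)
    if sum_abc == 0:
        return 0.0
    return float(sum_a / sum_abc)


def nei_distance(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    pair: tuple[str, str],
) -> float:
    """Nei's (1978) unbiased standard genetic distance between two populations.

    Within-population gene identities use the sample-size-corrected form
    ``J_X = mean_l (2 n_X sum_i x_i^2 - 1) / (2 n_X - 1)``; the between
    identity is ``J_XY = mean_l sum_i x_i y_i``; the distance is
    ``D = -ln(J_XY / sqrt(J_X J_Y))``, clipped at 0, with ``+inf`` when the
    populations share no alleles at any usable locus.  Loci with fewer than
    2 called diploids in either population are skipped.
    """
    calls_a, calls_b = _pair_calls(matrix, populations, pair)
    n1, p1, _ = _group_summaries(calls_a)
    n2, p2, _ = _group_summaries(calls_b)
    valid = (n1 >= 2) & (n2 >= 2)
    if not valid.any():
        raise PopgenError(
            f"populations {pair} share no locus with >= 2 called diploids each"
        )
    n1, p1 = n1[valid], p1[valid]
    n2, p2 = n2[valid], p2[valid]

    def unbiased_identity(n: np.ndarray, p: np.ndarray) -> float:
        plug_in = p**2 + (1.0 - p) ** 2
        return float(np.mean((2.0 * n * plug_in - 1.0) / (2.0 * n - 1.0)))

    j_x = unbiased_identity(n1, p1)
    j_y = unbiased_identity(n2, p2)
    j_xy = float(np.mean(p1 * p2 + (1.0 - p1) * (1.0 - p2)))
    if j_xy == 0.0:
        return float("inf")
    if j_x <= 0.0 or j_y <= 0.0:
        raise PopgenError(
            f"unbiased within-population identity is non-positive for {pair}; "
            "sample sizes are too small for the corrected estimator"
        )
    d = -math.log(j_xy / math.sqrt(j_x * j_y))
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _theta_for_assignments(
    member: np.ndarray,
    called: np.ndarray,
    dosage0: np.ndarray,
    het: np.ndarray,
) -> np.ndarray:
    """Theta for many group assignments at once.

    ``member`` is a (n_assignments, m) boolean matrix marking group-1
    membership among the m pooled accessions; the complementary accessions
    form group 2.  Per-locus summaries are obtained by matrix products, so
    the permutation null costs one matmul per summary.
    """
    member = member.astype(np.float64)
    tot_n = called.sum(axis=0)
    tot_alt = dosage0.sum(axis=0)
    tot_het = het.sum(axis=0)

    n1 = member @ called
    alt1 = member @ dosage0
    het1 = member @ het
    n2 = tot_n[None, :] - n1
    alt2 = tot_alt[None, :] - alt1
    het2 = tot_het[None, :] - het1
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / (2.0 * n1)
        p2 = alt2 / (2.0 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        sum_a, sum_abc = _wc_theta_sums(n1, p1, h1, n2, p2, h2)
        theta = sum_a / sum_abc
    return np.where(sum_abc == 0, 0.0, theta)


def fst_permutation_test(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    pair: tuple[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    n_tests: int | None = None,
) -> PairwiseResult:
    """Permutation significance of the pairwise theta.

    The null reassigns the pooled accessions of the pair at random to two
    groups of the original sizes (whole multilocus genotypes are permuted),
    recomputing theta each time.  ``n_tests`` is the Bonferroni factor —
    the number of population pairs in the full analysis (defaults to
    C(K, 2) over the assignment's labels; 10 for five populations).
    """
    if n_perm < 1:
        raise PopgenError("n_perm must be >= 1")
    idx_a = populations.indices_for(matrix, pair[0])
    idx_b = populations.indices_for(matrix, pair[1])
    if idx_a.size == 0 or idx_b.size == 0:
        raise PopgenError(f"empty population in pair {pair}")
    pooled = np.concatenate([idx_a, idx_b])
    m, n_a = pooled.size, idx_a.size

    calls = matrix.calls[pooled, :]
    called = (calls != MISSING).astype(np.float64)
    dosage0 = np.where(calls != MISSING, calls, 0).astype(np.float64)
    het = (calls == 1).astype(np.float64)

    rng = np.random.default_rng(seed)
    member = np.zeros((n_perm + 1, m), dtype=bool)
    member[0, :n_a] = True  # observed split
    for i in range(1, n_perm + 1):
        member[i, rng.permutation(m)[:n_a]] = True

    # evaluate in blocks to bound the (block x loci) temporaries
    block = 2048
    theta = np.concatenate(
        [
            _theta_for_assignments(member[start : start + block], called, dosage0, het)
            for start in range(0, n_perm + 1, block)
        ]
    )
    theta_obs = float(theta[0])
    exceed = int(np.sum(theta[1:] >= theta_obs))
    p_raw = (1.0 + exceed) / (1.0 + n_perm)

    if n_tests is None:
        k = len(populations.labels)
        n_tests = max(1, k * (k - 1) // 2)
    p_bonf = min(1.0, p_raw * n_tests)

    return PairwiseResult(
        pop_a=pair[0],
        pop_b=pair[1],
        fst=theta_obs,
        nei_d=nei_distance(matrix, populations, pair),
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# full pairwise analysis
# ---------------------------------------------------------------------------

def pairwise_analysis(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All population pairs: a square table with Fst in the upper triangle
    and Nei's D in the lower triangle, plus a tidy long table with p-values.
    """
    labels = populations.labels
    if len(labels) < 2:
        raise PopgenError("need at least two populations for a pairwise analysis")
    pairs = list(itertools.combinations(labels, 2))
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31, size=len(pairs))

    results = [
        fst_permutation_test(
            matrix, populations, pair, n_perm=n_perm, seed=int(s), n_tests=len(pairs)
        )
        for pair, s in zip(pairs, pair_seeds)
    ]

    square = pd.DataFrame(np.nan, index=labels, columns=labels)
    for res in results:
        square.loc[res.pop_a, res.pop_b] = res.fst
        square.loc[res.pop_b, res.pop_a] = res.nei_d
    tidy = pd.DataFrame(
        [
            {
                "pop_a": r.pop_a,
                "pop_b": r.pop_b,
                "fst": r.fst,
                "nei_d": r.nei_d,
                "p_raw": r.p_raw,
                "p_bonferroni": r.p_bonferroni,
                "n_permutations": r.n_permutations,
            }
            for r in results
        ]
    )
    return square, tidy
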