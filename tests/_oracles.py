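"""Independent reference implementations used only to cross-check the
package: scalar-loop variance components, exhaustive enumerations, and
third-party algorithms.  These deliberately avoid the package's vectorized
code paths."""

from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform


def wc_theta_brute(calls_pop1: np.ndarray, calls_pop2: np.ndarray) -> float:
    """Two-population Weir–Cockerham theta via an explicit per-locus loop
    over the textbook variance components (r = 2)."""
    L = calls_pop1.shape[1]
    sum_a = 0.0
    sum_abc = 0.0
    for l in range(L):
        summaries = []
        for calls in (calls_pop1, calls_pop2):
            c = calls[:, l]
            c = c[c >= 0]
            if len(c) == 0:
                break
            n_i = float(len(c))
            p_i = float(np.sum(c)) / (2.0 * n_i)
            h_i = float(np.mean(c == 1))
            summaries.append((n_i, p_i, h_i))
        if len(summaries) < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = summaries
        if n1 + n2 < 3:
            continue
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - 1.0
            / (nbar - 1.0)
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c_comp = hbar / 2.0
        sum_a += a
        sum_abc += a + b + c_comp
    return sum_a / sum_abc


def nei_d_brute(calls_pop1: np.ndarray, calls_pop2: np.ndarray) -> float:
    """Nei's (1978) unbiased standard distance via explicit per-locus sums."""
    import math

    jx_terms, jy_terms, jxy_terms = [], [], []
    for l in range(calls_pop1.shape[1]):
        cx = calls_pop1[:, l]
        cx = cx[cx >= 0]
        cy = calls_pop2[:, l]
        cy = cy[cy >= 0]
        if len(cx) < 2 or len(cy) < 2:
            continue
        nx, ny = float(len(cx)), float(len(cy))
        x_alt = float(np.sum(cx)) / (2 * nx)
        y_alt = float(np.sum(cy)) / (2 * ny)
        sx = x_alt**2 + (1 - x_alt) ** 2
        sy = y_alt**2 + (1 - y_alt) ** 2
        jx_terms.append((2 * nx * sx - 1) / (2 * nx - 1))
        jy_terms.append((2 * ny * sy - 1) / (2 * ny - 1))
        jxy_terms.append(x_alt * y_alt + (1 - x_alt) * (1 - y_alt))
    jx = float(np.mean(jx_terms))
    jy = float(np.mean(jy_terms))
    jxy = float(np.mean(jxy_terms))
    if jxy == 0:
        return float("inf")
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


def upgma_cophenetic_reference(values: np.ndarray) -> np.ndarray:
    """Cophenetic matrix from scipy's average-linkage implementation."""
    z = linkage(squareform(values, checks=False), method="average")
    return squareform(cophenet(z))


def allelic_richness_enumeration(n_ref_copies: int, n_alt_copies: int, g: int) -> float:
    """Expected number of distinct alleles in a size-g subsample, by
    exhaustive enumeration of all gene-copy subsets."""
    copies = ["R"] * n_ref_copies + ["A"] * n_alt_copies
    total = 0
    count = 0
    for combo in combinations(range(len(copies)), g):
        total += len({copies[i] for i in combo})
        count += 1
    return total / count


def indistinguishable_groups_brute(calls: np.ndarray, min_shared: int) -> list[set]:
    """Connected components of the zero-disagreement relation via networkx."""
    import networkx as nx

    n = calls.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            differ = 0
            for a, b in zip(calls[i], calls[j]):
                if a >= 0 and b >= 0:
                    shared += 1
                    if a != b:
                        differ += 1
            if shared >= min_shared and differ == 0:
                graph.add_edge(i, j)
    return [set(c) for c in nx.connected_components(graph) if len(c) >= 2]
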