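"""PCA and Euclidean/UPGMA structure summaries of the accession collection.

Genotypes are encoded as 0/1/2 ALT-dosages.  For PCA, missing calls are
imputed to the locus mean and columns centered (standard genotype-PCA
practice; no frequency scaling).  For distances, missing data are handled
pairwise-complete: loci missing in either accession are excluded and the
squared distance rescaled by ``L / L_shared`` before the square root, so
that near-duplicate detection is driven only by observed disagreements.

UPGMA is implemented directly (average linkage with a deterministic
lexicographic tie-break) so that dendrograms are reproducible across runs
and platforms; merge heights are half the merge distance, making cophenetic
distances equal merge distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationAssignment


class ClusteringError(ValueError):
    """Degenerate input to a clustering operation."""


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric: str = "euclidean_genotype"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ClusteringError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ClusteringError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ClusteringError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ClusteringError("distance matrix has negative entries")
        self.values = np.maximum(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class _Node:
    height: float
    label: str | None = None
    children: tuple["_Node", "_Node"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class Dendrogram:
    """Rooted ultrametric binary tree from agglomerative clustering.

    Node heights are merge distances halved, so every leaf sits at height 0
    and the cophenetic distance between two leaves equals the merge distance
    of their lowest common ancestor.
    """

    root: _Node
    labels: list[str]
    linkage: np.ndarray  # scipy-style (n-1, 4) linkage matrix

    def cophenetic(self) -> DistanceMatrix:
        n = len(self.labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        values = np.zeros((n, n))

        def walk(node: _Node) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            left = walk(node.children[0])
            right = walk(node.children[1])
            d = 2.0 * node.height
            for a in left:
                for b in right:
                    values[index[a], index[b]] = d
                    values[index[b], index[a]] = d
            return left + right

        walk(self.root)
        return DistanceMatrix(labels=list(self.labels), values=values, metric="cophenetic")

    def to_newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{length:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def pca_genotypes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal component analysis of the 0/1/2 genotype matrix.

    Missing calls are imputed to the locus mean; all-missing loci are dropped
    with a warning.  Returns the accession scores (n x k) and the fraction of
    total variance explained by each component (non-increasing, summing to 1
    over all components).
    """
    if matrix.n_accessions < 2 or matrix.n_loci < 2:
        raise ClusteringError("PCA needs at least 2 accessions and 2 loci")
    dosage = matrix.alt_dosage()
    all_missing = np.isnan(dosage).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} all-missing loci before PCA",
            stacklevel=2,
        )
        dosage = dosage[:, ~all_missing]
    col_mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), col_mean[None, :], dosage)
    centered = filled - col_mean[None, :]
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return scores, explained


def euclidean_distances(
    matrix: GenotypeMatrix, min_shared_frac: float = 0.5
) -> DistanceMatrix:
    """Pairwise-complete Euclidean distance over 0/1/2 genotype encodings.

    For each accession pair, loci missing in either member are excluded and
    the squared-difference sum is rescaled by ``L / L_shared`` before the
    square root.  Pairs sharing fewer than ``min_shared_frac * L`` called
    loci (or none at all) raise an error naming the pair.
    """
    if matrix.n_accessions < 2:
        raise ClusteringError("need at least 2 accessions")
    L = matrix.n_loci
    dosage = matrix.alt_dosage()
    called = ~np.isnan(dosage)
    x = np.where(called, dosage, 0.0)
    m = called.astype(np.float64)

    shared = m @ m.T
    sq = x**2
    d2 = (sq * m) @ m.T + m @ (sq * m).T - 2.0 * (x @ x.T)

    off = ~np.eye(matrix.n_accessions, dtype=bool)
    deficient = (shared < max(1.0, min_shared_frac * L)) & off
    if deficient.any():
        i, j = np.argwhere(deficient)[0]
        raise ClusteringError(
            f"accessions {matrix.accessions[i]!r} and {matrix.accessions[j]!r} share "
            f"only {int(shared[i, j])} of {L} called loci "
            f"(minimum fraction {min_shared_frac})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = d2 * (L / shared)
    np.fill_diagonal(scaled, 0.0)
    values = np.sqrt(np.maximum(scaled, 0.0))
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return DistanceMatrix(
        labels=list(matrix.accessions), values=values, metric="euclidean_genotype"
    )


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Among all minimum-distance cluster pairs, the pair whose (lexicographically
    smallest) representative leaf labels sort first is merged, so the output
    is deterministic.  The linkage matrix follows the scipy convention
    (cluster ids, merge distance, cluster size).
    """
    n = len(dist.labels)
    if n == 1:
        return Dendrogram(
            root=_Node(height=0.0, label=dist.labels[0]),
            labels=list(dist.labels),
            linkage=np.empty((0, 4)),
        )
    nodes: dict[int, _Node] = {
        i: _Node(height=0.0, label=lab) for i, lab in enumerate(dist.labels)
    }
    sizes = {i: 1 for i in range(n)}
    reps = {i: dist.labels[i] for i in range(n)}
    d = {
        (i, j): float(dist.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    linkage_rows = []
    next_id = n
    active = set(range(n))

    while len(active) > 1:
        min_val = min(d.values())
        i, j = min(
            (pair for pair, v in d.items() if v == min_val),
            key=lambda pair: tuple(sorted((reps[pair[0]], reps[pair[1]]))),
        )
        val = d.pop((i, j))
        node = _Node(height=val / 2.0, children=(nodes[i], nodes[j]))
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        reps[next_id] = min(reps[i], reps[j])
        linkage_rows.append([float(i), float(j), val, float(sizes[next_id])])
        active -= {i, j}
        for k in active:
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(k, next_id), max(k, next_id))] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        active.add(next_id)
        next_id += 1

    root = nodes[next_id - 1]
    return Dendrogram(
        root=root, labels=list(dist.labels), linkage=np.asarray(linkage_rows)
    )


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_pca(
    scores: np.ndarray,
    explained: np.ndarray,
    populations: PopulationAssignment,
    accessions: Sequence[str],
    path: str,
) -> None:
    """PC1–PC2 scatter colored by population label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = [populations.label_of(a) or "excluded" for a in accessions]
    for lab in dict.fromkeys(labels):
        sel = [i for i, l in enumerate(labels) if l == lab]
        ax.scatter(scores[sel, 0], scores[sel, 1], s=18, label=lab, alpha=0.8)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(dendrogram: Dendrogram, path: str) -> None:
    """Render the UPGMA tree via scipy's dendrogram plotting."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(8, max(3, 0.12 * len(dendrogram.labels))))
    hierarchy.dendrogram(
        dendrogram.linkage,
        labels=dendrogram.labels,
        orientation="left",
        leaf_font_size=5,
        ax=ax,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
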