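"""Variety identification: score a marker panel's ability to distinguish
accessions and report indistinguishable groups.

Two accessions are *indistinguishable* under a panel when they share at
least ``min_shared`` loci where both are called and their calls agree at
every shared locus — i.e. zero observed disagreements (equivalently, a
panel-restricted pairwise-complete Euclidean distance of zero).  A
missing-vs-called comparison never counts as a difference, which is the
conservative choice for variety-protection use.  Because missing-data
patterns can make the relation non-transitive, accessions are grouped as
connected components of the relation; distinguished accessions are exactly
the singleton components.  Pairs sharing fewer than ``min_shared`` called
loci are flagged as uncallable and never merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .panel_design import PanelDefinition


@dataclass
class IdentificationReport:
    """Identification outcome of one panel over one collection."""

    panel_id: str
    n_accessions: int
    n_distinguished: int
    identification_rate: float
    groups: list[list[str]]
    group_shared_loci: list[int]
    uncallable_pairs: list[tuple[str, str]]

    def summary(self) -> dict:
        return {
            "panel_id": self.panel_id,
            "n_accessions": self.n_accessions,
            "n_distinguished": self.n_distinguished,
            "identification_rate": self.identification_rate,
            "n_groups": len(self.groups),
            "n_uncallable_pairs": len(self.uncallable_pairs),
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per accession with its group id (NaN when distinguished)."""
        rows = []
        for gid, members in enumerate(self.groups):
            for m in members:
                rows.append({"accession_id": m, "group_id": gid})
        return pd.DataFrame(rows)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _panel_markers(panel: PanelDefinition | Sequence[str]) -> list[str]:
    if isinstance(panel, PanelDefinition):
        return list(panel.markers)
    return list(panel)


def _panel_name(panel: PanelDefinition | Sequence[str]) -> str:
    markers = _panel_markers(panel)
    return f"panel_{len(markers)}"


def indistinguishable_groups(
    matrix: GenotypeMatrix,
    panel: PanelDefinition | Sequence[str],
    min_shared: int | None = None,
) -> IdentificationReport:
    """Group accessions whose panel genotype profiles show no disagreement.

    ``min_shared`` defaults to half the panel size (rounded up), guarding
    against spurious matches between low-call-rate accessions.
    """
    markers = _panel_markers(panel)
    if not markers:
        raise ValueError("panel is empty")
    sub = matrix.subset_loci(markers)
    if min_shared is None:
        min_shared = math.ceil(0.5 * len(markers))
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")

    calls = sub.calls
    called = (calls != MISSING).astype(np.float64)
    shared = called @ called.T
    agreements = np.zeros_like(shared)
    for state in (0, 1, 2):
        s = (calls == state).astype(np.float64)
        agreements += s @ s.T
    disagreements = shared - agreements

    n = sub.n_accessions
    uf = _UnionFind(n)
    uncallable: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared:
                uncallable.append((sub.accessions[i], sub.accessions[j]))
            elif disagreements[i, j] == 0:
                uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    groups = []
    group_shared = []
    for root in sorted(components):
        members = components[root]
        if len(members) >= 2:
            groups.append([sub.accessions[i] for i in members])
            group_shared.append(
                int(
                    min(
                        shared[i, j]
                        for a, i in enumerate(members)
                        for j in members[a + 1 :]
                    )
                )
            )
    n_grouped = sum(len(g) for g in groups)
    n_distinguished = n - n_grouped
    return IdentificationReport(
        panel_id=_panel_name(panel),
        n_accessions=n,
        n_distinguished=n_distinguished,
        identification_rate=n_distinguished / n,
        groups=groups,
        group_shared_loci=group_shared,
        uncallable_pairs=uncallable,
    )


def evaluate_panels(
    matrix: GenotypeMatrix,
    panels: Sequence[PanelDefinition | Sequence[str]],
    min_shared: int | None = None,
) -> list[IdentificationReport]:
    """One identification report per panel (e.g. a nested chain).

    For nested panels on complete data, shrinking the panel can only merge
    groups, never split them, so identification rates are non-increasing
    along the chain.
    """
    return [indistinguishable_groups(matrix, p, min_shared=min_shared) for p in panels]
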