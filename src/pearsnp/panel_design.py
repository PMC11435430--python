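"""Core-panel selection under informativeness and genome-distribution
constraints, and nested subset derivation.

Candidates are the markers passing the informativeness gate (PIC above and
heterozygosity rate below their thresholds).  Per-chromosome quotas are
allocated deterministically: every chromosome holding at least one candidate
receives a base seat when the target allows, and the remaining seats are
apportioned to chromosomes proportionally to the physical span of their
candidates, with largest-remainder rounding.  Within a chromosome,
candidates are taken greedily in descending PIC, skipping any candidate
closer than the minimum spacing to an already selected marker; quota
shortfalls are redistributed to the other chromosomes, and only if no
spacing-respecting candidate remains anywhere is the spacing constraint
relaxed (each relaxation is recorded on the panel).

Selection is fully deterministic: ties in PIC break by position, then
marker id.  Nested subsets re-run the same procedure restricted to the
parent panel's markers, so each subset is contained in its parent by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import LocusInfo
from .marker_stats import LocusStats, core_candidate_gate


class PanelError(ValueError):
    """Infeasible or inconsistent panel request."""


@dataclass
class PanelDefinition:
    """An ordered marker panel plus the parameters that produced it."""

    markers: list[str]
    records: pd.DataFrame  # marker_id, chromosome, position_bp, pic, het_rate
    parameters: dict
    relaxations: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.markers)

    def per_chromosome_counts(self) -> dict:
        sel = self.records[self.records["marker_id"].isin(self.markers)]
        return sel.groupby("chromosome", sort=True).size().to_dict()

    def chromosomes_covered(self) -> set:
        return set(self.per_chromosome_counts())

    def to_frame(self) -> pd.DataFrame:
        sel = self.records.set_index("marker_id").loc[self.markers].reset_index()
        return sel[["marker_id", "chromosome", "position_bp", "pic", "het_rate"]]


def _candidate_records(
    stats: pd.DataFrame | Sequence[LocusStats],
    loci: Sequence[LocusInfo] | None,
) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        frame = stats.copy()
    else:
        frame = pd.DataFrame(
            {
                "marker_id": [s.marker_id for s in stats],
                "pic": [s.pic for s in stats],
                "het_rate": [s.het_rate for s in stats],
            }
        )
    if "chromosome" not in frame.columns or "position_bp" not in frame.columns:
        if loci is None:
            raise PanelError(
                "stats lack chromosome/position columns and no locus list was given"
            )
        pos = {l.marker_id: (l.chromosome, l.position_bp) for l in loci}
        frame["chromosome"] = [pos[m][0] for m in frame["marker_id"]]
        frame["position_bp"] = [pos[m][1] for m in frame["marker_id"]]
    return frame[["marker_id", "chromosome", "position_bp", "pic", "het_rate"]]


def _largest_remainder_quotas(
    spans: dict, n_seats: int, base: dict
) -> dict:
    """Apportion ``n_seats`` extra seats proportionally to spans."""
    quotas = dict(base)
    total_span = sum(spans.values())
    chroms = list(spans)
    if n_seats <= 0:
        return quotas
    if total_span <= 0:
        # all spans zero (single-candidate chromosomes): round-robin
        for i in range(n_seats):
            quotas[chroms[i % len(chroms)]] += 1
        return quotas
    raw = {c: n_seats * spans[c] / total_span for c in chroms}
    floors = {c: int(np.floor(raw[c])) for c in chroms}
    leftover = n_seats - sum(floors.values())
    order = sorted(chroms, key=lambda c: (-(raw[c] - floors[c]), str(c)))
    for c in chroms:
        quotas[c] += floors[c]
    for c in order[:leftover]:
        quotas[c] += 1
    return quotas


def _greedy_chromosome(
    cands: pd.DataFrame, quota: int, min_spacing_bp: int, chosen_pos: list[int]
) -> list[str]:
    """Take up to ``quota`` candidates in descending PIC respecting spacing."""
    taken: list[str] = []
    for row in cands.itertuples():
        if len(taken) >= quota:
            break
        if all(abs(row.position_bp - p) >= min_spacing_bp for p in chosen_pos):
            taken.append(row.marker_id)
            chosen_pos.append(row.position_bp)
    return taken


def select_core_panel(
    stats: pd.DataFrame | Sequence[LocusStats],
    loci: Sequence[LocusInfo] | None = None,
    target_size: int = 232,
    pic_min: float = 0.25,
    het_max: float = 0.35,
    min_spacing_bp: int = 500_000,
) -> PanelDefinition:
    """Select a core marker panel of ``target_size`` markers.

    Raises :class:`PanelError` (reporting the maximum feasible size) when
    fewer gated candidates exist than requested.
    """
    records = _candidate_records(stats, loci)
    gated_ids = set(core_candidate_gate(records, pic_min=pic_min, het_max=het_max))
    cands = records[records["marker_id"].isin(gated_ids)].copy()
    if target_size > len(cands):
        raise PanelError(
            f"target_size {target_size} exceeds the {len(cands)} gated candidates "
            f"(maximum feasible size: {len(cands)})"
        )
    cands = cands.sort_values(
        ["pic", "position_bp", "marker_id"], ascending=[False, True, True]
    )

    by_chrom = {c: g for c, g in cands.groupby("chromosome", sort=True)}
    chroms = sorted(by_chrom, key=str)
    spans = {
        c: int(g["position_bp"].max() - g["position_bp"].min())
        for c, g in by_chrom.items()
    }
    base = {c: 0 for c in chroms}
    extra = target_size
    if target_size >= len(chroms):
        base = {c: 1 for c in chroms}
        extra = target_size - len(chroms)
    quotas = _largest_remainder_quotas(spans, extra, base)
    for c in chroms:
        quotas[c] = min(quotas[c], len(by_chrom[c]))

    selected: dict = {c: [] for c in chroms}
    positions: dict = {c: [] for c in chroms}
    relaxations: list[str] = []
    for c in chroms:
        selected[c] = _greedy_chromosome(
            by_chrom[c], quotas[c], min_spacing_bp, positions[c]
        )

    def total() -> int:
        return sum(len(v) for v in selected.values())

    # redistribute shortfall: offer one extra seat per round, same greedy rule
    while total() < target_size:
        progressed = False
        for c in chroms:
            if total() >= target_size:
                break
            pool = by_chrom[c][~by_chrom[c]["marker_id"].isin(selected[c])]
            add = _greedy_chromosome(pool, 1, min_spacing_bp, positions[c])
            if add:
                selected[c].extend(add)
                progressed = True
        if not progressed:
            # no spacing-respecting candidate anywhere: relax spacing
            pool = cands[
                ~cands["marker_id"].isin(
                    {m for v in selected.values() for m in v}
                )
            ]
            row = pool.iloc[0]
            selected[row["chromosome"]].append(row["marker_id"])
            positions[row["chromosome"]].append(int(row["position_bp"]))
            relaxations.append(
                f"spacing relaxed on chromosome {row['chromosome']} "
                f"for {row['marker_id']}"
            )

    ordered = cands[cands["marker_id"].isin({m for v in selected.values() for m in v})]
    markers = list(ordered["marker_id"])
    return PanelDefinition(
        markers=markers,
        records=records.reset_index(drop=True),
        parameters={
            "target_size": target_size,
            "pic_min": pic_min,
            "het_max": het_max,
            "min_spacing_bp": min_spacing_bp,
        },
        relaxations=relaxations,
    )


def nested_subsets(
    panel: PanelDefinition, sizes: Sequence[int] = (192, 96, 48, 24)
) -> list[PanelDefinition]:
    """Derive nested subsets, each selected from the next-larger set by the
    same quota + descending-PIC rule; sizes must be strictly decreasing."""
    sizes = list(sizes)
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise PanelError("subset sizes must be strictly decreasing")
    if sizes and sizes[0] > panel.size:
        raise PanelError(
            f"subset size {sizes[0]} exceeds the parent panel size {panel.size}"
        )
    out: list[PanelDefinition] = []
    parent = panel
    for size in sizes:
        records = parent.records[
            parent.records["marker_id"].isin(parent.markers)
        ].reset_index(drop=True)
        sub = select_core_panel(
            records,
            target_size=size,
            pic_min=parent.parameters["pic_min"],
            het_max=parent.parameters["het_max"],
            min_spacing_bp=parent.parameters["min_spacing_bp"],
        )
        out.append(sub)
        parent = sub
    return out
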