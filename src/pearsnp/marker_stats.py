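"""Per-locus marker statistics and the SNP quality/informativeness gates.

Implements allele-frequency counting over diploid calls, polymorphic
information content (PIC), Nei's unbiased expected heterozygosity,
rarefaction-based allelic richness, the discovery-stage locus filter
(MAF / missing rate / minimum depth) and the core-candidate gate
(PIC / heterozygosity rate) used for panel design.

All thresholds follow strict inequalities: a locus is kept when
MAF > ``maf_min`` and missing rate < ``missing_max``; a candidate passes the
gate when PIC > ``pic_min`` and heterozygosity rate < ``het_max``.  Ties sit
on the excluded side.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, PopulationAssignment

logger = logging.getLogger(__name__)

#: Sentinel returned by :func:`allele_frequencies` for a locus with zero
#: called genotypes in the requested subset.
ALL_MISSING: tuple[float, float] = (float("nan"), float("nan"))


@dataclass(frozen=True)
class LocusStats:
    """Summary statistics of one biallelic locus over a set of accessions."""

    marker_id: str
    n_called: int
    maf: float
    missing_rate: float
    het_rate: float
    pic: float
    he_unbiased: float


@dataclass
class FilterReport:
    """Accounting of the locus filter: every input locus is attributed to
    exactly one outcome (first failing rule in the order missing -> MAF,
    after depth masking of individual calls)."""

    n_input: int
    n_retained: int
    n_dropped_missing: int
    n_dropped_maf: int
    n_depth_masked_calls: int
    dropped_missing: list[str] = field(default_factory=list)
    dropped_maf: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("retained", self.n_retained)]
        rows += [("dropped_missing_rate", self.n_dropped_missing)]
        rows += [("dropped_maf", self.n_dropped_maf)]
        rows += [("input", self.n_input)]
        return pd.DataFrame(rows, columns=["class", "n_loci"])


def _subset_indices(matrix: GenotypeMatrix, subset: Iterable[str] | None) -> np.ndarray:
    if subset is None:
        return np.arange(matrix.n_accessions, dtype=np.intp)
    wanted = set(subset)
    idx = np.array(
        [i for i, a in enumerate(matrix.accessions) if a in wanted], dtype=np.intp
    )
    if idx.size == 0:
        raise ValueError("accession subset is empty after intersection with the matrix")
    return idx


def allele_frequencies(
    matrix: GenotypeMatrix, locus: str, subset: Iterable[str] | None = None
) -> tuple[float, float]:
    """REF/ALT allele frequencies at a locus by allele counting.

    Each REF homozygote contributes two REF copies, each heterozygote one of
    each, each ALT homozygote two ALT copies; missing calls are excluded.
    Returns :data:`ALL_MISSING` (a nan pair) when no genotype is called.
    """
    k = matrix.locus_index(locus)
    idx = _subset_indices(matrix, subset)
    calls = matrix.calls[idx, k]
    called = calls != MISSING
    n = int(called.sum())
    if n == 0:
        return ALL_MISSING
    alt = float(calls[called].sum()) / (2.0 * n)
    return (1.0 - alt, alt)


def pic(p: Sequence[float]) -> float:
    """Polymorphic information content of an allele-frequency vector.

    ``PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``.  For a biallelic
    locus this is maximized at 0.375 when both alleles are equifrequent.
    """
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("allele frequencies must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1 (got {p.sum()!r})")
    sq = p**2
    cross = (np.sum(sq) ** 2 - np.sum(sq**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - sq.sum() - 2.0 * cross)


def expected_het_unbiased(p: Sequence[float], n: int) -> float:
    """Nei's unbiased expected heterozygosity (gene diversity).

    ``He = 2n/(2n-1) * (1 - sum_i p_i^2)`` for ``n`` diploid individuals.
    Always at least the plug-in gene diversity, converging to it as n grows.
    """
    if n < 2:
        raise ValueError("unbiased He requires n >= 2 diploid individuals")
    p = np.asarray(p, dtype=np.float64)
    return float((2.0 * n / (2.0 * n - 1.0)) * (1.0 - np.sum(p**2)))


def _absent_prob(total_copies: int, allele_copies: int, g: int) -> float:
    """P(an allele with ``allele_copies`` of ``total_copies`` gene copies is
    absent from a subsample of size ``g``) = C(total-copies, g)/C(total, g)."""
    if total_copies - allele_copies < g:
        return 0.0
    # log-space binomial ratio for numerical stability at large counts
    lognum = gammaln(total_copies - allele_copies + 1) - gammaln(g + 1) - gammaln(
        total_copies - allele_copies - g + 1
    )
    logden = gammaln(total_copies + 1) - gammaln(g + 1) - gammaln(total_copies - g + 1)
    return float(np.exp(lognum - logden))


def allelic_richness(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    g: int | None = None,
) -> dict[str, float]:
    """Rarefaction allelic richness per population (El Mousadik & Petit).

    Per locus, ``A = sum_alleles [1 - C(2N - N_i, g) / C(2N, g)]`` where
    ``N`` is the number of called diploids and ``N_i`` the gene copies of
    allele ``i``; the per-locus values are averaged within each population.
    ``g`` (gene copies) defaults to twice the smallest per-population,
    per-locus called sample, so every locus can be rarefied everywhere.
    """
    per_pop_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label in populations.labels:
        idx = populations.indices_for(matrix, label)
        calls = matrix.calls[idx, :]
        called = calls != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        per_pop_counts[label] = (n.astype(np.int64), alt.astype(np.int64))

    min_n = min(int(n.min()) for n, _ in per_pop_counts.values())
    if g is None:
        g = 2 * min_n
    g = int(g)
    if g < 1 or g > 2 * min_n:
        raise ValueError(
            f"rarefaction size g={g} must lie in [1, {2 * min_n}] gene copies"
        )

    out: dict[str, float] = {}
    for label, (n, alt) in per_pop_counts.items():
        values = np.empty(matrix.n_loci)
        for l in range(matrix.n_loci):
            total = int(2 * n[l])
            n_alt = int(alt[l])
            n_ref = total - n_alt
            a = 0.0
            for copies in (n_ref, n_alt):
                if copies > 0:
                    a += 1.0 - _absent_prob(total, copies, g)
            values[l] = a
        out[label] = float(values.mean())
    return out


def locus_stats_frame(
    matrix: GenotypeMatrix, subset: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-locus statistics table (one row per locus, matrix order).

    Columns: marker_id, chromosome, position_bp, n_called, maf,
    missing_rate, het_rate, pic, he_unbiased.  Loci with no called genotype
    (or fewer than 2 for the unbiased He) carry NaN statistics.
    """
    idx = _subset_indices(matrix, subset)
    calls = matrix.calls[idx, :]
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_total = len(idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
        het_rate = (calls == 1).sum(axis=0) / n_called
    p_alt = np.where(n_called > 0, p_alt, np.nan)
    p_ref = 1.0 - p_alt
    maf = np.minimum(p_alt, p_ref)
    missing_rate = 1.0 - n_called / n_total

    sq = p_ref**2 + p_alt**2
    pic_vals = 1.0 - sq - 2.0 * (p_ref**2) * (p_alt**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        he = (2.0 * n_called / (2.0 * n_called - 1.0)) * (1.0 - sq)
    he = np.where(n_called >= 2, he, np.nan)

    frame = matrix.loci_frame()[["marker_id", "chromosome", "position_bp"]].copy()
    frame["n_called"] = n_called
    frame["maf"] = maf
    frame["missing_rate"] = missing_rate
    frame["het_rate"] = np.where(n_called > 0, het_rate, np.nan)
    frame["pic"] = np.where(n_called > 0, pic_vals, np.nan)
    frame["he_unbiased"] = he
    return frame


def compute_locus_stats(
    matrix: GenotypeMatrix, subset: Iterable[str] | None = None
) -> list[LocusStats]:
    """Typed view of :func:`locus_stats_frame`."""
    frame = locus_stats_frame(matrix, subset)
    return [
        LocusStats(
            marker_id=row.marker_id,
            n_called=int(row.n_called),
            maf=float(row.maf),
            missing_rate=float(row.missing_rate),
            het_rate=float(row.het_rate),
            pic=float(row.pic),
            he_unbiased=float(row.he_unbiased),
        )
        for row in frame.itertuples()
    ]


def filter_loci(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.15,
    depth_min: int = 3,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Discovery-stage SNP filter: depth masking, then missing rate, then MAF.

    Calls with recorded depth below ``depth_min`` are first set to missing
    (a no-op with a warning when the matrix carries no depth).  Loci are then
    dropped when their missing rate is >= ``missing_max``, and otherwise when
    their MAF is <= ``maf_min`` (strict keep-side inequalities).  The filter
    is idempotent.
    """
    work = matrix.copy()
    masked_calls = 0
    if depth_min > 0:
        if work.depth is None:
            warnings.warn(
                "matrix has no depth information; depth filter is a no-op",
                stacklevel=2,
            )
        else:
            mask = (work.depth >= 0) & (work.depth < depth_min) & (work.calls != MISSING)
            masked_calls = int(mask.sum())
            work.calls[mask] = MISSING

    stats = locus_stats_frame(work)
    missing_fail = stats["missing_rate"].to_numpy() >= missing_max
    maf_vals = stats["maf"].to_numpy()
    maf_fail = ~missing_fail & (np.isnan(maf_vals) | (maf_vals <= maf_min))
    keep = ~missing_fail & ~maf_fail

    ids = np.asarray(stats["marker_id"])
    report = FilterReport(
        n_input=matrix.n_loci,
        n_retained=int(keep.sum()),
        n_dropped_missing=int(missing_fail.sum()),
        n_dropped_maf=int(maf_fail.sum()),
        n_depth_masked_calls=masked_calls,
        dropped_missing=list(ids[missing_fail]),
        dropped_maf=list(ids[maf_fail]),
    )
    filtered = work.subset_loci(list(ids[keep]))
    logger.info(
        "locus filter: %d -> %d (dropped %d by missing rate, %d by MAF; %d calls depth-masked)",
        report.n_input, report.n_retained, report.n_dropped_missing,
        report.n_dropped_maf, report.n_depth_masked_calls,
    )
    return filtered, report


def core_candidate_gate(
    stats: pd.DataFrame | Sequence[LocusStats],
    pic_min: float = 0.25,
    het_max: float = 0.35,
) -> list[str]:
    """Markers passing the core-candidate gate: PIC > pic_min and
    heterozygosity rate < het_max (strict).  The genome-distribution
    criterion is applied later, during panel design."""
    if not isinstance(stats, pd.DataFrame):
        stats = pd.DataFrame(
            {
                "marker_id": [s.marker_id for s in stats],
                "pic": [s.pic for s in stats],
                "het_rate": [s.het_rate for s in stats],
            }
        )
    ok = (stats["pic"] > pic_min) & (stats["het_rate"] < het_max)
    return list(stats.loc[ok.fillna(False), "marker_id"])


def default_rarefaction_size(
    matrix: GenotypeMatrix, populations: PopulationAssignment
) -> int:
    """Twice the smallest per-population, per-locus called diploid count."""
    min_n = None
    for label in populations.labels:
        idx = populations.indices_for(matrix, label)
        n = (matrix.calls[idx, :] != MISSING).sum(axis=0).min()
        min_n = int(n) if min_n is None else min(min_n, int(n))
    if not min_n:
        raise ValueError("some population has a locus with zero called genotypes")
    return 2 * min_n


def diversity_table(
    matrix: GenotypeMatrix,
    populations: PopulationAssignment,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-population diversity summary: sample size, allelic richness (A),
    unbiased expected heterozygosity (He), and PIC, plus a pooled "Total"
    row computed over all non-excluded accessions as one sample.

    A single rarefaction size is used for all rows (default: twice the
    smallest per-population, per-locus called sample) so richness values are
    comparable across populations and with the pooled total."""
    if g is None:
        g = default_rarefaction_size(matrix, populations)
    richness = allelic_richness(matrix, populations, g=g)
    rows = []
    pooled_ids: list[str] = []
    for label in populations.labels:
        members = populations.members(label)
        in_matrix = [a for a in members if a in set(matrix.accessions)]
        pooled_ids.extend(in_matrix)
        stats = locus_stats_frame(matrix, subset=in_matrix)
        rows.append(
            {
                "population": label,
                "sample_size": len(in_matrix),
                "A": richness[label],
                "He": float(stats["he_unbiased"].mean()),
                "PIC": float(stats["pic"].mean()),
            }
        )
    pooled_assign = PopulationAssignment(mapping={a: "Total" for a in pooled_ids})
    pooled_matrix = matrix.subset_accessions(pooled_ids)
    pooled_rich = allelic_richness(pooled_matrix, pooled_assign, g=g)
    pooled_stats = locus_stats_frame(matrix, subset=pooled_ids)
    rows.append(
        {
            "population": "Total",
            "sample_size": len(pooled_ids),
            "A": pooled_rich["Total"],
            "He": float(pooled_stats["he_unbiased"].mean()),
            "PIC": float(pooled_stats["pic"].mean()),
        }
    )
    return pd.DataFrame(rows)
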