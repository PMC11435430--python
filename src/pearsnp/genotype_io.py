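"""Genotype matrix container and readers/writers for the formats the pipeline touches.

Conventions
-----------
Calls are coded as small integers: ``0`` REF homozygote, ``1`` heterozygote,
``2`` ALT homozygote, ``-1`` (:data:`MISSING`) no call.  Coordinates are
1-based (VCF convention) and chromosome labels are normalized by stripping a
leading ``chr``/``Chr`` prefix.  Allele orientation (REF/ALT) is taken from
the input file as-is; mismatched alleles in a genotype table are validation
errors rather than candidates for strand flipping, because silent recoding
would corrupt downstream variety identification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_VALID_CALLS = frozenset({-1, 0, 1, 2})
_NA_TOKENS = frozenset({"", "na", "nan", "n/a", "--", ".", "./.", "-"})


class GenotypeIOError(ValueError):
    """Base class for genotype I/O and validation failures."""


class VcfParseError(GenotypeIOError):
    """Raised when a VCF cannot be parsed."""


class EmptyDatasetError(GenotypeIOError):
    """Raised when an input yields zero usable biallelic SNP records."""


class AlleleMismatchError(GenotypeIOError):
    """Raised when a table cell carries an allele outside {REF, ALT}."""


def normalize_chromosome(label: object) -> int | str:
    """Strip any ``chr``/``Chr`` prefix; return an int for numeric labels."""
    text = str(label).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    if text.isdigit():
        return int(text)
    return text


@dataclass(frozen=True)
class LocusInfo:
    """A biallelic SNP locus: identifier, map position and alleles."""

    marker_id: str
    chromosome: int | str
    position_bp: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.position_bp < 1:
            raise GenotypeIOError(
                f"{self.marker_id}: position_bp must be >= 1 (1-based), got {self.position_bp}"
            )
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise GenotypeIOError(
                f"{self.marker_id}: only single-nucleotide alleles are supported "
                f"(got {self.ref!r}/{self.alt!r})"
            )
        if self.ref == self.alt:
            raise GenotypeIOError(f"{self.marker_id}: REF and ALT alleles are identical")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic loci genotype grid with optional per-call depth.

    ``calls`` is an ``int8`` array of shape ``(n_accessions, n_loci)`` in the
    0/1/2/:data:`MISSING` coding.  ``depth`` is either ``None`` (no depth
    information anywhere) or an ``int32`` array of the same shape with ``-1``
    marking calls without a recorded depth.
    """

    accessions: list[str]
    loci: list[LocusInfo]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.accessions = [str(a) for a in self.accessions]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accessions), len(self.loci)):
            raise GenotypeIOError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.loci)} loci"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise GenotypeIOError("accession ids are not unique")
        bad = set(np.unique(self.calls)) - _VALID_CALLS
        if bad:
            raise GenotypeIOError(f"invalid call codes present: {sorted(bad)}")
        positions = [(l.chromosome, l.position_bp) for l in self.loci]
        if len(set(positions)) != len(positions):
            raise GenotypeIOError("(chromosome, position_bp) pairs are not unique")
        ids = [l.marker_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise GenotypeIOError("marker ids are not unique")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise GenotypeIOError("depth shape does not match calls shape")
            if (self.depth < -1).any():
                raise GenotypeIOError("depths must be >= 0 (or -1 for absent)")

    # -- basic properties -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def marker_ids(self) -> list[str]:
        return [l.marker_id for l in self.loci]

    def locus_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def accession_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(f"unknown accession id: {accession!r}") from None

    # -- derived views ----------------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    def het(self) -> np.ndarray:
        """Boolean mask of heterozygous calls."""
        return self.calls == 1

    def alt_dosage(self) -> np.ndarray:
        """Calls as float ALT-allele dosage, ``nan`` where missing."""
        d = self.calls.astype(np.float64)
        d[self.calls == MISSING] = np.nan
        return d

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": [l.chromosome for l in self.loci],
                "position_bp": [l.position_bp for l in self.loci],
                "ref": [l.ref for l in self.loci],
                "alt": [l.alt for l in self.loci],
            }
        )

    # -- subsetting --------------------------------------------------------

    def subset_loci(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_index(m) for m in marker_ids]
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            depth=None if self.depth is None else self.depth[:, idx].copy(),
        )

    def subset_accessions(self, accession_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.accession_index(a) for a in accession_ids]
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx, :].copy(),
            depth=None if self.depth is None else self.depth[idx, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=list(self.loci),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )


@dataclass
class PopulationAssignment:
    """Accession -> predefined population label, with an exclusion set.

    Populations are predefined by species (or hybrid class); accessions in
    ``excluded`` take part in no between-population statistic.
    """

    mapping: dict[str, str]
    excluded: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        self.excluded = frozenset(str(a) for a in self.excluded)

    @property
    def labels(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for acc, lab in self.mapping.items():
            if acc not in self.excluded:
                seen.setdefault(lab, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [
            a for a, l in self.mapping.items() if l == label and a not in self.excluded
        ]

    def label_of(self, accession: str) -> str | None:
        if accession in self.excluded:
            return None
        return self.mapping.get(accession)

    def indices_for(self, matrix: GenotypeMatrix, label: str) -> np.ndarray:
        members = set(self.members(label))
        return np.array(
            [i for i, a in enumerate(matrix.accessions) if a in members], dtype=np.intp
        )

    def validate(self, matrix: GenotypeMatrix) -> None:
        """Every non-excluded accession of the matrix must carry exactly one label."""
        missing = [
            a
            for a in matrix.accessions
            if a not in self.excluded and a not in self.mapping
        ]
        if missing:
            raise GenotypeIOError(
                f"{len(missing)} accessions lack a population label "
                f"(first: {missing[:3]})"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped; the count is logged and
    stored on the returned matrix as ``skipped_records``.  Phased and
    unphased genotypes are both accepted; per-sample DP, when present,
    populates the depth grid.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vf.header.samples)
    loci: list[LocusInfo] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    any_depth = False
    skipped = 0

    try:
        for rec in vf:
            alts = rec.alts
            if (
                alts is None
                or len(alts) != 1
                or rec.ref is None
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or not alts[0].isalpha()
            ):
                skipped += 1
                continue
            marker_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}"
            loci.append(
                LocusInfo(
                    marker_id=marker_id,
                    chromosome=rec.chrom,
                    position_bp=rec.pos,
                    ref=rec.ref,
                    alt=alts[0],
                )
            )
            calls = np.full(len(samples), MISSING, dtype=np.int8)
            depths = np.full(len(samples), -1, dtype=np.int32)
            for j, name in enumerate(samples):
                sample = rec.samples[name]
                gt = sample.get("GT")
                if gt is not None and None not in gt and len(gt) == 2:
                    calls[j] = gt[0] + gt[1]
                dp = sample.get("DP")
                if dp is not None:
                    depths[j] = int(dp)
                    any_depth = True
            call_rows.append(calls)
            depth_rows.append(depths)
    except (OSError, ValueError) as exc:  # malformed body
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    finally:
        vf.close()

    if not loci:
        raise EmptyDatasetError(f"{path}: no biallelic SNP records found")
    logger.info(
        "read %d biallelic SNP records from %s (skipped %d non-biallelic/non-SNP)",
        len(loci), path, skipped,
    )
    matrix = GenotypeMatrix(
        accessions=samples,
        loci=loci,
        calls=np.column_stack(call_rows),
        depth=np.column_stack(depth_rows) if any_depth else None,
    )
    matrix.skipped_records = skipped  # type: ignore[attr-defined]
    return matrix


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 text file.

    Round-trips through :func:`read_vcf` reproduce calls, accession order and
    locus order exactly.
    """
    path = Path(path)
    with_depth = matrix.depth is not None
    chroms: dict[str, int] = {}
    for locus in matrix.loci:
        key = str(locus.chromosome)
        chroms[key] = max(chroms.get(key, 0), locus.position_bp)
    lines: list[str] = ["##fileformat=VCFv4.2", "##source=pearsnp"]
    for chrom, length in chroms.items():
        lines.append(f"##contig=<ID={chrom},length={length + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if with_depth:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(matrix.accessions)
    lines.append("\t".join(header))

    fmt = "GT:DP" if with_depth else "GT"
    for k, locus in enumerate(matrix.loci):
        fields = [
            str(locus.chromosome),
            str(locus.position_bp),
            locus.marker_id,
            locus.ref,
            locus.alt,
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for i in range(matrix.n_accessions):
            gt = _GT_STRINGS[int(matrix.calls[i, k])]
            if with_depth:
                dp = int(matrix.depth[i, k])  # type: ignore[index]
                gt = f"{gt}:{dp if dp >= 0 else '.'}"
            fields.append(gt)
        lines.append("\t".join(fields))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise GenotypeIOError(f"cannot write VCF to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Wide genotype tables (Fluidigm-style exports)
# ---------------------------------------------------------------------------

def read_locus_table(path: str | Path) -> list[LocusInfo]:
    """Read the locus companion CSV (marker_id, chromosome, position_bp, ref, alt)."""
    df = pd.read_csv(path, dtype=str)
    required = {"marker_id", "chromosome", "position_bp", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"locus table {path} lacks columns: {sorted(missing)}")
    return [
        LocusInfo(
            marker_id=row.marker_id,
            chromosome=row.chromosome,
            position_bp=int(row.position_bp),
            ref=row.ref,
            alt=row.alt,
        )
        for row in df.itertuples()
    ]


def write_locus_table(loci: Iterable[LocusInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "marker_id": l.marker_id,
                "chromosome": l.chromosome,
                "position_bp": l.position_bp,
                "ref": l.ref,
                "alt": l.alt,
            }
            for l in loci
        ]
    ).to_csv(path, index=False)


def _decode_cell(cell: object, locus: LocusInfo, accession: str) -> int:
    text = str(cell).strip() if cell is not None else ""
    if text.lower() in _NA_TOKENS or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    if text in {"0", "1", "2"}:
        return int(text)
    if len(text) == 2 and text.isalpha():
        alleles = text.upper()
        valid = {locus.ref.upper(), locus.alt.upper()}
        if not set(alleles) <= valid:
            raise AlleleMismatchError(
                f"marker {locus.marker_id}, accession {accession}: call {text!r} "
                f"uses alleles outside REF={locus.ref}/ALT={locus.alt}"
            )
        return sum(1 for a in alleles if a == locus.alt.upper())
    raise GenotypeIOError(
        f"marker {locus.marker_id}, accession {accession}: cannot interpret cell {text!r}"
    )


def read_genotype_table(
    path: str | Path, locus_table: str | Path | Sequence[LocusInfo]
) -> GenotypeMatrix:
    """Read a wide CSV genotype table (rows=accessions, columns=markers).

    Cells may be two-letter calls (``AG``), 0/1/2 dosage codes, or blank/NA
    for missing.  Two-letter calls are mapped to dosages using per-marker
    REF/ALT from the companion locus table.
    """
    if isinstance(locus_table, (str, Path)):
        loci_all = read_locus_table(locus_table)
    else:
        loci_all = list(locus_table)
    by_id = {l.marker_id: l for l in loci_all}

    df = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    unknown = [m for m in df.columns if m not in by_id]
    if unknown:
        raise GenotypeIOError(
            f"genotype table {path} contains markers absent from the locus table: "
            f"{unknown[:5]}"
        )
    if df.shape[1] == 0:
        raise EmptyDatasetError(f"{path}: no marker columns")
    loci = [by_id[m] for m in df.columns]
    accessions = [str(a) for a in df.index]
    calls = np.full(df.shape, MISSING, dtype=np.int8)
    for k, marker in enumerate(df.columns):
        locus = by_id[marker]
        for i, accession in enumerate(accessions):
            calls[i, k] = _decode_cell(df.iat[i, k], locus, accession)
    return GenotypeMatrix(accessions=accessions, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# Accession metadata
# ---------------------------------------------------------------------------

def read_population_table(path: str | Path) -> PopulationAssignment:
    """Read the accession metadata CSV (accession_id, population[, excluded])."""
    df = pd.read_csv(path, dtype=str)
    required = {"accession_id", "population"}
    if not required <= set(df.columns):
        raise GenotypeIOError(
            f"metadata table {path} must have columns {sorted(required)}"
        )
    excluded: set[str] = set()
    if "excluded" in df.columns:
        flags = df["excluded"].fillna("").str.lower().isin({"1", "true", "yes"})
        excluded = set(df.loc[flags, "accession_id"])
    mapping = dict(zip(df["accession_id"], df["population"]))
    return PopulationAssignment(mapping=mapping, excluded=frozenset(excluded))


def write_population_table(populations: PopulationAssignment, path: str | Path) -> None:
    rows = [
        {
            "accession_id": acc,
            "population": lab,
            "excluded": acc in populations.excluded,
        }
        for acc, lab in populations.mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
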