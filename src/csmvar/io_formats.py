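"""Readers and writers for the external formats the pipeline touches.

Coordinate contract
-------------------
Variant positions are 1-based (VCF/MAF convention).  Genomic intervals are
stored 0-based half-open internally; BED is read as-is, GFF3 (1-based closed)
is converted on load.  All conversions happen here, at the I/O boundary.

Allele contract
---------------
Alleles are stored *pure*: an insertion has ``ref == ""`` and ``alt`` the
inserted bases, keyed by the 1-based position of the base before the
insertion; a deletion has ``ref`` the deleted bases and ``alt == ""``, keyed
by the first deleted base.  Dash placeholders and anchored (shared-base)
representations are rejected.

Chromosome names are matched after stripping an optional ``chr`` prefix,
since common-variant VCFs and tumor mutation tables disagree on naming.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SomaticVariant",
    "CommonLocusSet",
    "ClinicalRecord",
    "RegionSet",
    "RegionTotals",
    "ReferenceGenome",
    "TableReadResult",
    "normalize_chrom",
    "read_somatic_table",
    "write_somatic_table",
    "read_common_loci_vcf",
    "read_regions",
    "read_signature_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_fasta",
    "write_fasta",
    "write_common_loci_vcf",
    "write_bed",
]

VARIANT_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample_id",
    "cancer_type",
    "tumor_depth",
    "tumor_alt_reads",
    "normal_alt_reads",
    "variant_classification",
]

CLINICAL_TABLE_COLUMNS = [
    "sample_id",
    "age",
    "gender",
    "stage",
    "pfs_time",
    "pfs_event",
    "os_time",
    "os_event",
]

STAGES = ("I", "II", "III", "IV", "unknown")

_VALID_BASES = frozenset("ACGT")


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr``/``Chr`` prefix from a sequence name."""
    if name[:3].lower() == "chr":
        return name[3:]
    return name


def _infer_variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == 2 and len(alt) == 2:
        return "DBS"
    if len(ref) < len(alt):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    raise ValueError(f"cannot type alleles {ref!r}>{alt!r}")


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic small mutation with its read support and labels."""

    chrom: str
    pos: int  # 1-based first reference base affected
    ref: str
    alt: str
    sample_id: str
    cancer_type: str
    tumor_depth: int
    tumor_alt_reads: int
    normal_alt_reads: int
    variant_classification: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if "-" in self.ref or "-" in self.alt:
            raise ValueError("dash alleles are forbidden; use empty strings")
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a variant")
        for allele in (self.ref, self.alt):
            if allele and not set(allele) <= _VALID_BASES:
                raise ValueError(f"invalid allele {allele!r}")
        if min(self.tumor_depth, self.tumor_alt_reads, self.normal_alt_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.tumor_alt_reads > self.tumor_depth:
            raise ValueError("tumor_alt_reads exceeds tumor_depth")
        _infer_variant_type(self.ref, self.alt)  # raises if untypeable

    @property
    def variant_type(self) -> str:
        return _infer_variant_type(self.ref, self.alt)

    def vaf(self) -> float:
        """Tumor variant allele frequency; NaN when depth is zero."""
        if self.tumor_depth == 0:
            return float("nan")
        return self.tumor_alt_reads / self.tumor_depth

    @property
    def key(self) -> tuple[str, int, str]:
        """Site+allele key (chrom, pos, alt) used for recurrence counting."""
        return (normalize_chrom(self.chrom), self.pos, self.alt)

    @property
    def locus(self) -> tuple[str, int]:
        return (normalize_chrom(self.chrom), self.pos)


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age: float
    gender: str
    stage: str
    pfs_time: float
    pfs_event: int
    os_time: float
    os_event: int

    def __post_init__(self) -> None:
        if self.pfs_time < 0 or self.os_time < 0:
            raise ValueError("survival times must be >= 0")
        if self.pfs_event not in (0, 1) or self.os_event not in (0, 1):
            raise ValueError("events must be 0/1")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")


@dataclass(frozen=True)
class RegionTotals:
    """Per-region locus denominators: common loci vs all positions."""

    common: int
    total: int

    @property
    def noncommon(self) -> int:
        return self.total - self.common


class RegionSet:
    """Interval annotation set, 0-based half-open, queryable by 1-based point."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._intervals: list[tuple[str, int, int, str]] = []
        for chrom, start, end, label in intervals:
            if start < 0 or end < 0:
                raise ValueError(f"negative coordinate in interval {chrom}:{start}-{end}")
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            self._trees[normalize_chrom(chrom)].addi(start, end, label)
            self._intervals.append((chrom, start, end, label))

    def __len__(self) -> int:
        return len(self._intervals)

    @property
    def intervals(self) -> list[tuple[str, int, int, str]]:
        return list(self._intervals)

    @property
    def labels(self) -> set[str]:
        return {label for _, _, _, label in self._intervals}

    def labels_at(self, chrom: str, pos: int) -> set[str]:
        """All labels overlapping a 1-based point position."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos - 1)}

    def total_bases(self, label: str) -> int:
        """Number of distinct positions covered by intervals with ``label``."""
        per_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, start, end, lab in self._intervals:
            if lab == label:
                per_chrom[normalize_chrom(chrom)].addi(start, end)
        total = 0
        for tree in per_chrom.values():
            tree.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in tree)
        return total


class CommonLocusSet:
    """Exact-membership set of common-variant positions with region totals."""

    def __init__(
        self,
        loci: Iterable[tuple[str, int]],
        alleles: Mapping[tuple[str, int], set[str]] | None = None,
        region_totals: Mapping[str, RegionTotals] | None = None,
    ):
        self._loci = {(normalize_chrom(c), int(p)) for c, p in loci}
        self._alleles = {
            (normalize_chrom(c), int(p)): set(a) for (c, p), a in (alleles or {}).items()
        }
        self.region_totals: dict[str, RegionTotals] = dict(region_totals or {})

    def __len__(self) -> int:
        return len(self._loci)

    def __contains__(self, locus: tuple[str, int]) -> bool:
        chrom, pos = locus
        return (normalize_chrom(chrom), int(pos)) in self._loci

    @property
    def loci(self) -> set[tuple[str, int]]:
        return set(self._loci)

    def alleles_at(self, chrom: str, pos: int) -> set[str]:
        return set(self._alleles.get((normalize_chrom(chrom), int(pos)), set()))

    def compute_region_totals(self, regions: RegionSet) -> None:
        """Populate per-region denominators from a region annotation set."""
        counts: dict[str, int] = defaultdict(int)
        for chrom, pos in self._loci:
            for label in regions.labels_at(chrom, pos):
                counts[label] += 1
        self.region_totals = {
            label: RegionTotals(common=counts.get(label, 0), total=regions.total_bases(label))
            for label in regions.labels
        }


class ReferenceGenome:
    """Uniform fetch interface over a pyfaidx Fasta or an in-memory dict."""

    def __init__(self, source):
        self._source = source
        if isinstance(source, dict):
            self._names = {normalize_chrom(k): k for k in source}
        else:  # pyfaidx.Fasta or similar mapping of records
            self._names = {normalize_chrom(k): k for k in source.keys()}

    def contig_length(self, chrom: str) -> int:
        name = self._names[normalize_chrom(chrom)]
        return len(self._source[name])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases [start, end] inclusive, 1-based. Raises on out-of-contig."""
        key = normalize_chrom(chrom)
        if key not in self._names:
            raise KeyError(f"unknown contig {chrom!r}")
        name = self._names[key]
        n = len(self._source[name])
        if start < 1 or end > n or start > end:
            raise ValueError(f"window {chrom}:{start}-{end} outside contig of length {n}")
        seq = self._source[name][start - 1 : end]
        return str(seq).upper()

    def contigs(self) -> list[str]:
        return list(self._names.values())


@dataclass
class TableReadResult:
    """Parsed variants plus a record of rows that failed validation."""

    variants: list[SomaticVariant]
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_somatic_table(path: str | os.PathLike, dialect: str = "maf_like") -> TableReadResult:
    """Read a tab-separated MAF-like mutation table.

    Malformed rows (bad types, invariant violations) are skipped and reported
    with their 1-based file line numbers; a missing mandatory column is a hard
    error naming the column.
    """
    if dialect != "maf_like":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in VARIANT_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from {path}")
    result = TableReadResult(variants=[])
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        try:
            v = SomaticVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                cancer_type=row.cancer_type,
                tumor_depth=int(row.tumor_depth),
                tumor_alt_reads=int(row.tumor_alt_reads),
                normal_alt_reads=int(row.normal_alt_reads),
                variant_classification=row.variant_classification,
            )
        except (ValueError, TypeError) as exc:
            result.skipped.append((lineno, str(exc)))
            continue
        result.variants.append(v)
    return result


def write_somatic_table(variants: Iterable[SomaticVariant], path: str | os.PathLike) -> None:
    rows = [
        {col: getattr(v, col) for col in VARIANT_TABLE_COLUMNS}
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def variants_to_frame(variants: Iterable) -> pd.DataFrame:
    """Tidy DataFrame view of SomaticVariant or ClassifiedVariant streams."""
    rows = []
    for v in variants:
        base = getattr(v, "variant", v)
        row = {col: getattr(base, col) for col in VARIANT_TABLE_COLUMNS}
        row["variant_type"] = base.variant_type
        for extra in ("is_csm", "qc_pass"):
            if hasattr(v, extra):
                row[extra] = getattr(v, extra)
        if hasattr(v, "region_labels"):
            row["region_labels"] = ",".join(sorted(v.region_labels))
        if hasattr(v, "qc_reasons"):
            row["qc_reasons"] = ",".join(v.qc_reasons)
        rows.append(row)
    return pd.DataFrame(rows)


def read_common_loci_vcf(
    path: str | os.PathLike, regions: RegionSet | None = None
) -> CommonLocusSet:
    """Load common loci from a VCF; multi-allelic rows contribute one locus."""
    from cyvcf2 import VCF

    loci: set[tuple[str, int]] = set()
    alleles: dict[tuple[str, int], set[str]] = defaultdict(set)
    vcf = VCF(str(path))
    for rec in vcf:
        key = (normalize_chrom(rec.CHROM), rec.POS)
        loci.add(key)
        for alt in rec.ALT:
            alleles[key].add(alt)
    vcf.close()
    out = CommonLocusSet(loci, alleles=alleles)
    if regions is not None:
        out.compute_region_totals(regions)
    return out


def read_regions(path: str | os.PathLike) -> RegionSet:
    """Read BED4 (0-based half-open) or GFF3 (1-based closed) into a RegionSet."""
    path = str(path)
    is_gff = path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz"))
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gff:
                if len(fields) < 5:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                chrom, _, feature, start, end = fields[:5]
                s, e = int(start) - 1, int(end)
                label = feature
            else:
                if len(fields) < 3:
                    raise ValueError(f"malformed BED line: {line!r}")
                chrom, start, end = fields[:3]
                s, e = int(start), int(end)
                label = fields[3] if len(fields) > 3 else "region"
            if int(start) < 0 or int(end) < 0:
                raise ValueError(f"negative coordinate in {line!r}")
            intervals.append((chrom, s, e, label))
    return RegionSet(intervals)


def read_signature_matrix(path: str | os.PathLike, system: str = "SBS96") -> pd.DataFrame:
    """Read a TSV signature reference (channels x signatures).

    Rows are reordered to the canonical channel order for ``system`` and each
    column is renormalized to sum to 1.
    """
    from .mutation_context import canonical_channels

    channels = canonical_channels(system)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != len(channels):
        raise ValueError(
            f"{system} reference must have {len(channels)} rows, got {df.shape[0]}"
        )
    missing = set(channels) - set(df.index)
    if missing:
        raise ValueError(f"missing channels for {system}: {sorted(missing)[:5]} ...")
    df = df.loc[list(channels)]
    if (df.values < 0).any():
        raise ValueError("signature matrix must be non-negative")
    sums = df.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("signature column sums to zero")
    return df / sums


def read_clinical_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in CLINICAL_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory clinical column {col!r} missing")
    for col in ("pfs_time", "os_time"):
        if (df[col] < 0).any():
            raise ValueError(f"{col} contains negative times")
    for col in ("pfs_event", "os_event"):
        if not df[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CLINICAL_TABLE_COLUMNS)


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    from pyfaidx import Fasta

    return ReferenceGenome(Fasta(str(path), sequence_always_upper=True))


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_common_loci_vcf(
    loci: Sequence[tuple[str, int, str, str]], path: str | os.PathLike
) -> None:
    """Write (chrom, pos, ref, alt) records as a minimal VCF 4.2 file."""
    chroms: dict[str, int] = {}
    for chrom, pos, _, _ in loci:
        chroms[chrom] = max(chroms.get(chrom, 0), pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(loci, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
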