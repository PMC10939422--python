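"""COSMIC-style mutation-class systems: SBS-96, DBS-78 and ID-83.

Single-base substitutions are pyrimidine-centric: a variant whose reference
base is a purine is reverse-complemented (together with its +-1 context)
before channel assignment, so every SNV maps to exactly one of the 96
channels.  Doublet substitutions are canonicalized to the 78-class catalog by
reverse-complementing non-canonical reference doublets (and, for
self-complementary doublets, the alternate pair).  Small indels follow the
83-class convention: 1-bp events record the pyrimidine identity of the
inserted/deleted base and the homopolymer run length around the event
(inclusive 1..6+ for deletions, neighbor count 0..5+ for insertions); longer
events record tandem-repeat copy number, and non-repetitive deletions record
flanking microhomology length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ReferenceGenome, normalize_chrom

__all__ = [
    "MutationClass",
    "SBS96_CHANNELS",
    "DBS78_CHANNELS",
    "ID83_CHANNELS",
    "SIX_SUBSTITUTION_TYPES",
    "canonical_channels",
    "revcomp",
    "classify_sbs",
    "classify_dbs",
    "classify_id",
    "build_spectra",
    "cpg_ct_fraction",
    "six_type_distribution",
]

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


SIX_SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SIX_SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

# Canonical reference doublets and their alternate sets (78 channels).
_DBS_CATALOG: dict[str, tuple[str, ...]] = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}

DBS78_CHANNELS: tuple[str, ...] = tuple(
    f"{ref}>{alt}" for ref, alts in _DBS_CATALOG.items() for alt in alts
)

_ID83: list[str] = []
for base in ("C", "T"):
    _ID83 += [f"1:Del:{base}:{n}" for n in range(1, 7)]
for base in ("C", "T"):
    _ID83 += [f"1:Ins:{base}:{n}" for n in range(0, 6)]
for length in (2, 3, 4, 5):
    _ID83 += [f"{length}:Del:R:{n}" for n in range(1, 7)]
for length in (2, 3, 4, 5):
    _ID83 += [f"{length}:Ins:R:{n}" for n in range(0, 6)]
_ID83 += ["2:Del:M:1"]
_ID83 += [f"3:Del:M:{n}" for n in (1, 2)]
_ID83 += [f"4:Del:M:{n}" for n in (1, 2, 3)]
_ID83 += [f"5:Del:M:{n}" for n in (1, 2, 3, 4, 5)]
ID83_CHANNELS: tuple[str, ...] = tuple(_ID83)
assert len(ID83_CHANNELS) == 83

_SYSTEMS = {
    "SBS96": SBS96_CHANNELS,
    "DBS78": DBS78_CHANNELS,
    "ID83": ID83_CHANNELS,
}


def canonical_channels(system: str) -> tuple[str, ...]:
    try:
        return _SYSTEMS[system]
    except KeyError:
        raise ValueError(f"unknown class system {system!r}") from None


@dataclass(frozen=True)
class MutationClass:
    system: str
    channel: str
    cpg_flag: bool = False

    def __post_init__(self) -> None:
        if self.channel not in _SYSTEMS[self.system]:
            raise ValueError(f"{self.channel!r} not a {self.system} channel")


class ContextMismatchError(ValueError):
    """Reference base at the variant position does not match the ref allele."""


def _variant_of(v):
    return getattr(v, "variant", v)


def classify_sbs(v, reference: ReferenceGenome) -> MutationClass:
    """Assign a pyrimidine-centric trinucleotide channel to an SNV.

    The CpG flag marks C>T substitutions whose pyrimidine-strand context is
    NCG (the 5-methylcytosine deamination hallmark).
    """
    var = _variant_of(v)
    if var.variant_type != "SNV":
        raise ValueError(f"classify_sbs requires an SNV, got {var.variant_type}")
    ref_base = reference.fetch(var.chrom, var.pos, var.pos)
    if ref_base != var.ref:
        raise ContextMismatchError(
            f"reference has {ref_base} at {var.chrom}:{var.pos}, variant says {var.ref}"
        )
    context = reference.fetch(var.chrom, var.pos - 1, var.pos + 1)
    ref, alt = var.ref, var.alt
    if ref in "AG":
        context = revcomp(context)
        ref, alt = revcomp(ref), revcomp(alt)
    channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
    cpg = ref == "C" and alt == "T" and context[2] == "G"
    return MutationClass(system="SBS96", channel=channel, cpg_flag=cpg)


def classify_dbs(v) -> MutationClass:
    var = _variant_of(v)
    if var.variant_type != "DBS":
        raise ValueError(f"classify_dbs requires a DBS, got {var.variant_type}")
    ref, alt = var.ref, var.alt
    if ref == alt:
        raise ValueError("ref == alt doublet")
    if ref not in _DBS_CATALOG:
        ref, alt = revcomp(ref), revcomp(alt)
    if alt not in _DBS_CATALOG[ref]:
        # self-complementary reference doublet: canonicalize the alternate
        alt = revcomp(alt)
    channel = f"{ref}>{alt}"
    if channel not in DBS78_CHANNELS:
        raise ValueError(f"cannot canonicalize doublet {var.ref}>{var.alt}")
    return MutationClass(system="DBS78", channel=channel)


def _run_length(seq: str, start: int, base: str) -> int:
    """Tandem copies of ``base`` in ``seq`` scanning right from ``start``."""
    n = 0
    i = start
    while i < len(seq) and seq[i] == base:
        n += 1
        i += 1
    return n


def _tandem_copies(reference: ReferenceGenome, chrom: str, start: int, unit: str) -> tuple[int, int]:
    """Copies of ``unit`` tandemly repeated left of / right of 1-based start."""
    u = len(unit)
    left = 0
    p = start - u
    while p >= 1 and reference.fetch(chrom, p, p + u - 1) == unit:
        left += 1
        p -= u
    right = 0
    n = reference.contig_length(chrom)
    p = start
    while p + u - 1 <= n and reference.fetch(chrom, p, p + u - 1) == unit:
        right += 1
        p += u
    return left, right


def classify_id(v, reference: ReferenceGenome) -> MutationClass:
    """Assign an ID-83 channel to a pure-representation insertion or deletion."""
    var = _variant_of(v)
    vt = var.variant_type
    if vt not in ("INS", "DEL"):
        raise ValueError(f"classify_id requires INS/DEL, got {vt}")
    if var.ref and var.alt:
        raise ValueError(
            "indel carries shared flanking bases; normalize to pure ref/alt first"
        )
    chrom, pos = var.chrom, var.pos
    if vt == "DEL":
        seq = var.ref
        observed = reference.fetch(chrom, pos, pos + len(seq) - 1)
        if observed != seq:
            raise ContextMismatchError(
                f"reference has {observed} at {chrom}:{pos}, deletion says {seq}"
            )
        if len(seq) == 1:
            base = seq if seq in "CT" else revcomp(seq)
            left, right = _tandem_copies(reference, chrom, pos, seq[0])
            # the deleted base itself is one of the "right" copies
            run = left + right
            return MutationClass("ID83", f"1:Del:{base}:{min(run, 6)}")
        length = min(len(seq), 5)
        left, right = _tandem_copies(reference, chrom, pos, seq)
        copies = left + right  # includes the deleted copy
        if copies >= 2:
            return MutationClass("ID83", f"{length}:Del:R:{min(copies, 6)}")
        mh = _microhomology(reference, chrom, pos, seq)
        if mh > 0:
            cap = 5 if length == 5 else length - 1
            return MutationClass("ID83", f"{length}:Del:M:{min(mh, cap)}")
        return MutationClass("ID83", f"{length}:Del:R:1")
    # insertion after base ``pos``
    seq = var.alt
    if len(seq) == 1:
        base = seq if seq in "CT" else revcomp(seq)
        left, right = _tandem_copies(reference, chrom, pos + 1, seq[0])
        run = left + right  # existing neighbors only
        return MutationClass("ID83", f"1:Ins:{base}:{min(run, 5)}")
    length = min(len(seq), 5)
    left, right = _tandem_copies(reference, chrom, pos + 1, seq)
    copies = left + right
    return MutationClass("ID83", f"{length}:Ins:R:{min(copies, 5)}")


def _microhomology(reference: ReferenceGenome, chrom: str, pos: int, deleted: str) -> int:
    """Longest partial-copy overlap between the deleted sequence and its flanks."""
    n = reference.contig_length(chrom)
    best = 0
    for m in range(1, len(deleted)):
        right_start = pos + len(deleted)
        if right_start + m - 1 <= n:
            if reference.fetch(chrom, right_start, right_start + m - 1) == deleted[:m]:
                best = max(best, m)
        if pos - m >= 1:
            if reference.fetch(chrom, pos - m, pos - 1) == deleted[-m:]:
                best = max(best, m)
    return best


def classify_variant(v, reference: ReferenceGenome) -> MutationClass:
    """Dispatch to the class system matching the variant type."""
    var = _variant_of(v)
    vt = var.variant_type
    if vt == "SNV":
        return classify_sbs(v, reference)
    if vt == "DBS":
        return classify_dbs(v)
    return classify_id(v, reference)


def build_spectra(
    variants: Iterable,
    reference: ReferenceGenome,
    grouping: str = "sample",
    system: str = "SBS96",
    group_filter: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[object, str]]]:
    """Count-channel matrix (channels x groups) for one class system.

    Returns the matrix and a list of (variant, message) classification errors;
    errored variants are excluded from the spectrum.  Column sums therefore
    equal the number of *classified* variants per group.
    """
    if grouping not in ("sample", "cancer_type"):
        raise ValueError("grouping must be 'sample' or 'cancer_type'")
    channels = canonical_channels(system)
    wanted_types = {"SBS96": ("SNV",), "DBS78": ("DBS",), "ID83": ("INS", "DEL")}[system]
    counts: dict[str, np.ndarray] = {}
    index = {ch: i for i, ch in enumerate(channels)}
    errors: list[tuple[object, str]] = []
    for v in variants:
        var = _variant_of(v)
        if var.variant_type not in wanted_types:
            continue
        group = var.sample_id if grouping == "sample" else var.cancer_type
        if group_filter is not None and group not in group_filter:
            continue
        try:
            mc = classify_variant(v, reference)
        except (ValueError, KeyError) as exc:
            errors.append((v, str(exc)))
            continue
        if group not in counts:
            counts[group] = np.zeros(len(channels), dtype=int)
        counts[group][index[mc.channel]] += 1
    if not counts:
        return pd.DataFrame(index=list(channels), dtype=int), errors
    df = pd.DataFrame(counts, index=list(channels)).sort_index(axis=1)
    return df, errors


_CPG_CT_CHANNELS = tuple(f"{five}[C>T]G" for five in "ACGT")


def cpg_ct_fraction(spectrum: pd.DataFrame | pd.Series) -> float:
    """Fraction of SBS-96 counts in C>T-at-NCG channels."""
    counts = spectrum.sum(axis=1) if isinstance(spectrum, pd.DataFrame) else spectrum
    total = counts.sum()
    if total == 0:
        return float("nan")
    return float(counts.loc[list(_CPG_CT_CHANNELS)].sum() / total)


def six_type_distribution(spectrum: pd.DataFrame | pd.Series) -> pd.Series:
    """Distribution over the six pyrimidine substitution types (sums to 1)."""
    counts = spectrum.sum(axis=1) if isinstance(spectrum, pd.DataFrame) else spectrum
    out = {}
    for sub in SIX_SUBSTITUTION_TYPES:
        mask = [ch for ch in counts.index if f"[{sub}]" in ch]
        out[sub] = float(counts.loc[mask].sum())
    s = pd.Series(out)
    total = s.sum()
    return s / total if total > 0 else s
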