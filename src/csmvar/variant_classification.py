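"""QC filtering and common-locus classification of somatic mutations.

A somatic mutation is removed when any of three read-support filters fires:
three or more supporting reads in the matched normal, tumor depth below 5x,
or tumor variant allele frequency below 0.05.  QC-passing mutations are then
partitioned into those at common germline loci (csm) and all others (ncsm);
the default intersection is position-only, with an allele-aware mode for the
stricter reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import CommonLocusSet, RegionSet, SomaticVariant

__all__ = [
    "QCDecision",
    "ClassifiedVariant",
    "ClassificationSummary",
    "qc_filter",
    "classify",
    "select_regulatory",
    "NORMAL_SUPPORT_MAX",
    "MIN_TUMOR_DEPTH",
    "MIN_VAF",
]

# Removal thresholds: normal_alt_reads >= 3, tumor_depth < 5, vaf < 0.05.
NORMAL_SUPPORT_MAX = 2
MIN_TUMOR_DEPTH = 5
MIN_VAF = 0.05

QC_REASONS = ("normal_support", "low_depth", "low_vaf")


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reasons: tuple[str, ...] = ()


def qc_filter(
    v: SomaticVariant,
    normal_support_max: int = NORMAL_SUPPORT_MAX,
    min_depth: int = MIN_TUMOR_DEPTH,
    min_vaf: float = MIN_VAF,
) -> QCDecision:
    """Decide removal, recording every applicable failure reason.

    Zero tumor depth makes the VAF undefined; such records are removed with
    reason ``low_depth`` only.
    """
    reasons: list[str] = []
    if v.normal_alt_reads > normal_support_max:
        reasons.append("normal_support")
    if v.tumor_depth < min_depth:
        reasons.append("low_depth")
    if v.tumor_depth > 0 and v.vaf() < min_vaf:
        reasons.append("low_vaf")
    return QCDecision(keep=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class ClassifiedVariant:
    """A somatic variant with QC outcome, common-locus flag and region labels."""

    variant: SomaticVariant
    qc_pass: bool
    qc_reasons: tuple[str, ...] = ()
    is_csm: bool | None = None  # defined only when qc_pass
    region_labels: frozenset[str] = frozenset()

    # delegate the fields downstream statistics read constantly
    @property
    def chrom(self):
        return self.variant.chrom

    @property
    def pos(self):
        return self.variant.pos

    @property
    def ref(self):
        return self.variant.ref

    @property
    def alt(self):
        return self.variant.alt

    @property
    def sample_id(self):
        return self.variant.sample_id

    @property
    def cancer_type(self):
        return self.variant.cancer_type

    @property
    def variant_classification(self):
        return self.variant.variant_classification

    @property
    def variant_type(self):
        return self.variant.variant_type

    @property
    def key(self):
        return self.variant.key

    @property
    def locus(self):
        return self.variant.locus


@dataclass
class ClassificationSummary:
    n_input: int = 0
    n_retained: int = 0
    n_csm: int = 0
    n_ncsm: int = 0
    removed_by_reason: dict[str, int] = field(default_factory=dict)
    n_removed: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_csm": self.n_csm,
            "n_ncsm": self.n_ncsm,
            "n_removed": self.n_removed,
            "removed_by_reason": dict(self.removed_by_reason),
        }


def classify(
    variants: Iterable[SomaticVariant],
    loci: CommonLocusSet,
    regions: RegionSet | None = None,
    mode: str = "position",
    **qc_kwargs,
) -> tuple[list[ClassifiedVariant], ClassificationSummary]:
    """QC-filter and partition a variant stream into csm / ncsm.

    ``mode='position'`` calls a variant csm when its (chrom, pos) is a common
    locus; ``mode='position_allele'`` additionally requires the alternate
    allele to match a recorded common allele, and is always a subset of the
    position-only calls.
    """
    if mode not in ("position", "position_allele"):
        raise ValueError(f"unknown intersection mode {mode!r}")
    out: list[ClassifiedVariant] = []
    summary = ClassificationSummary(removed_by_reason={r: 0 for r in QC_REASONS})
    for v in variants:
        v = getattr(v, "variant", v)  # idempotent over ClassifiedVariant input
        summary.n_input += 1
        decision = qc_filter(v, **qc_kwargs)
        labels = (
            frozenset(regions.labels_at(v.chrom, v.pos)) if regions is not None else frozenset()
        )
        if not decision.keep:
            summary.n_removed += 1
            for r in decision.reasons:
                summary.removed_by_reason[r] += 1
            out.append(
                ClassifiedVariant(
                    variant=v, qc_pass=False, qc_reasons=decision.reasons, region_labels=labels
                )
            )
            continue
        is_csm = v.locus in loci
        if is_csm and mode == "position_allele":
            is_csm = v.alt in loci.alleles_at(v.chrom, v.pos)
        summary.n_retained += 1
        if is_csm:
            summary.n_csm += 1
        else:
            summary.n_ncsm += 1
        out.append(
            ClassifiedVariant(variant=v, qc_pass=True, is_csm=is_csm, region_labels=labels)
        )
    return out, summary


def retained(variants: Iterable[ClassifiedVariant]) -> list[ClassifiedVariant]:
    return [v for v in variants if v.qc_pass]


def select_regulatory(
    variants: Iterable[ClassifiedVariant], regulatory: RegionSet
) -> list[ClassifiedVariant]:
    """csm variants falling inside at least one regulatory interval."""
    out = []
    for v in variants:
        if not (v.qc_pass and v.is_csm):
            continue
        labels = regulatory.labels_at(v.chrom, v.pos)
        if labels:
            out.append(
                ClassifiedVariant(
                    variant=v.variant,
                    qc_pass=True,
                    is_csm=True,
                    region_labels=v.region_labels | frozenset(labels),
                )
            )
    return out
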