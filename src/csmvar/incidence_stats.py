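"""Incidence, recurrence, call-rate and per-sample rate statistics.

Definitions
-----------
incidence rate (of a locus class within a region)
    number of distinct mutated loci divided by the total locus count of that
    class in the region.  Loci are positional: distinct (chrom, pos).
incidence ratio
    rate at common loci divided by rate at non-common loci; the ratio curve
    restricts both numerators to loci mutated in at least n samples.
recurrent site
    a distinct mutated site -- (chrom, pos, alt) -- observed in more than one
    sample; the recurrence rate is recurrent sites over all mutated sites.
call rate (per functional classification)
    fraction of mutations with that classification that are csm.
csm rate (per sample)
    csm count over total somatic small-mutation count for the sample;
    samples with more than 500 csm mutations are flagged hypermutators.

Duplicate rows (same sample, chrom, pos, alt) are removed before every
statistic.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CommonLocusSet
from .variant_classification import ClassifiedVariant

__all__ = [
    "IncidenceResult",
    "RecurrenceResult",
    "SampleRate",
    "GroupComparison",
    "incidence",
    "incidence_ratio",
    "recurrence",
    "recurrence_rate",
    "call_rates",
    "sample_rates",
    "HYPERMUTATOR_CSM_CUTOFF",
    "AGE_CUTOFF",
]

HYPERMUTATOR_CSM_CUTOFF = 500
AGE_CUTOFF = 60


def dedupe(variants: Iterable[ClassifiedVariant]) -> list[ClassifiedVariant]:
    """Drop duplicate (sample, chrom, pos, alt) rows, keeping first seen."""
    seen: set[tuple] = set()
    out = []
    for v in variants:
        k = (v.sample_id,) + v.key
        if k in seen:
            continue
        seen.add(k)
        out.append(v)
    return out


@dataclass
class IncidenceResult:
    region: str
    mutated_common: int
    total_common: int
    mutated_noncommon: int
    total_noncommon: int
    curve: dict[int, float] = field(default_factory=dict)
    p_value: float = float("nan")  # chi-square test of the 2x2 mutated/total table

    @property
    def rate_common(self) -> float:
        return self.mutated_common / self.total_common if self.total_common else float("nan")

    @property
    def rate_noncommon(self) -> float:
        return (
            self.mutated_noncommon / self.total_noncommon
            if self.total_noncommon
            else float("nan")
        )

    @property
    def ratio(self) -> float:
        return incidence_ratio(self.rate_common, self.rate_noncommon)


def incidence_ratio(rate_common: float, rate_noncommon: float) -> float:
    """Ratio of the common-locus incidence rate to the non-common rate."""
    if not rate_noncommon or math.isnan(rate_noncommon) or math.isnan(rate_common):
        return float("nan")
    return rate_common / rate_noncommon


def incidence(
    variants: Iterable[ClassifiedVariant],
    loci: CommonLocusSet,
    region: str,
    strict_curve: bool = False,
) -> IncidenceResult:
    """Distinct-locus incidence rates and the minimum-mutation-number curve.

    ``curve[n]`` is the incidence ratio restricted to loci mutated in at
    least ``n`` samples (``> n`` when ``strict_curve``); ``curve[1]`` equals
    the headline ratio.
    """
    totals = loci.region_totals.get(region)
    if totals is None:
        raise ValueError(f"no region totals for {region!r}; load/compute them first")
    sample_counts: dict[tuple[str, int], set[str]] = defaultdict(set)
    for v in dedupe(variants):
        if not v.qc_pass or region not in v.region_labels:
            continue
        sample_counts[v.locus].add(v.sample_id)
    mult_common = Counter()
    mult_noncommon = Counter()
    for locus, samples in sample_counts.items():
        m = len(samples)
        if locus in loci:
            mult_common[m] += 1
        else:
            mult_noncommon[m] += 1
    n_common = sum(mult_common.values())
    n_noncommon = sum(mult_noncommon.values())
    result = IncidenceResult(
        region=region,
        mutated_common=n_common,
        total_common=totals.common,
        mutated_noncommon=n_noncommon,
        total_noncommon=totals.noncommon,
    )
    n_max = max(list(mult_common) + list(mult_noncommon), default=0)
    for n in range(1, n_max + 1):
        thr = (lambda m: m > n) if strict_curve else (lambda m: m >= n)
        c = sum(cnt for m, cnt in mult_common.items() if thr(m))
        nc = sum(cnt for m, cnt in mult_noncommon.items() if thr(m))
        if totals.common and totals.noncommon and nc:
            result.curve[n] = (c / totals.common) / (nc / totals.noncommon)
    if totals.common and totals.noncommon and n_common + n_noncommon > 0:
        table = np.array(
            [
                [n_common, totals.common - n_common],
                [n_noncommon, totals.noncommon - n_noncommon],
            ]
        )
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            result.p_value = float(stats.chi2_contingency(table)[1])
    return result


@dataclass
class RecurrenceResult:
    group: str
    sites_total: int
    sites_recurrent: int

    @property
    def rate(self) -> float:
        return recurrence_rate(self.sites_recurrent, self.sites_total)


def recurrence_rate(sites_recurrent: int, sites_total: int) -> float:
    """Recurrent-site fraction; NaN for an empty group."""
    if sites_total == 0:
        return float("nan")
    return sites_recurrent / sites_total


def recurrence(variants: Iterable[ClassifiedVariant], group: str) -> RecurrenceResult:
    """Recurrence over distinct (chrom, pos, alt) sites for csm or ncsm."""
    if group not in ("csm", "ncsm"):
        raise ValueError("group must be 'csm' or 'ncsm'")
    want = group == "csm"
    samples_per_site: dict[tuple, set[str]] = defaultdict(set)
    for v in dedupe(variants):
        if not v.qc_pass or v.is_csm is not want:
            continue
        samples_per_site[v.key].add(v.sample_id)
    total = len(samples_per_site)
    recurrent = sum(1 for s in samples_per_site.values() if len(s) >= 2)
    return RecurrenceResult(group=group, sites_total=total, sites_recurrent=recurrent)


def call_rates(variants: Iterable[ClassifiedVariant]) -> dict[str, float]:
    """csm fraction per functional classification label; empty labels omitted."""
    csm = Counter()
    total = Counter()
    for v in dedupe(variants):
        if not v.qc_pass:
            continue
        label = v.variant_classification
        total[label] += 1
        if v.is_csm:
            csm[label] += 1
    return {label: csm[label] / total[label] for label in total}


@dataclass
class SampleRate:
    sample_id: str
    n_csm: int
    n_total: int
    hypermutator: bool

    @property
    def csm_rate(self) -> float:
        return self.n_csm / self.n_total if self.n_total else float("nan")


@dataclass
class GroupComparison:
    """Welch t-test between two groups, degenerate-variance aware."""

    mean_a: float
    mean_b: float
    t: float
    p: float
    n_a: int
    n_b: int
    degenerate: bool = False


def _ttest(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    comp = GroupComparison(
        mean_a=float(np.mean(a)) if a.size else float("nan"),
        mean_b=float(np.mean(b)) if b.size else float("nan"),
        t=float("nan"),
        p=float("nan"),
        n_a=a.size,
        n_b=b.size,
    )
    if a.size < 2 or b.size < 2:
        comp.degenerate = True
        return comp
    if np.var(a) == 0 and np.var(b) == 0:
        comp.degenerate = True
        comp.t, comp.p = 0.0, 1.0
        return comp
    t, p = stats.ttest_ind(a, b, equal_var=False)
    comp.t, comp.p = float(t), float(p)
    return comp


@dataclass
class SampleRateSummary:
    per_sample: pd.DataFrame
    median_rate: float
    rates_by_cancer_type: pd.Series
    young_vs_elder_rate: GroupComparison | None = None
    young_vs_elder_count: GroupComparison | None = None
    young_vs_elder_count_no_hyper: GroupComparison | None = None
    stage1_vs_rest_rate: GroupComparison | None = None


def sample_rates(
    variants: Iterable[ClassifiedVariant],
    clinical: pd.DataFrame | None = None,
    snv_only: bool = False,
    hypermutator_cutoff: int = HYPERMUTATOR_CSM_CUTOFF,
    age_cutoff: float = AGE_CUTOFF,
) -> SampleRateSummary:
    """Per-sample csm rates plus cohort summaries and group comparisons.

    ``snv_only`` restricts the numerator (and denominator) to single-base
    substitutions.  Samples with zero qualifying mutations are flagged and
    excluded from rate summaries.  Group comparisons (age, stage) require a
    clinical table and are reported on rates and raw counts, with the
    hypermutator-excluded count comparison alongside.
    """
    per_sample: dict[str, list[int]] = {}
    cancer_of: dict[str, str] = {}
    for v in dedupe(variants):
        if not v.qc_pass:
            continue
        if snv_only and v.variant_type != "SNV":
            continue
        rec = per_sample.setdefault(v.sample_id, [0, 0])
        rec[1] += 1
        if v.is_csm:
            rec[0] += 1
        cancer_of[v.sample_id] = v.cancer_type
    rows = []
    for sid, (n_csm, n_total) in sorted(per_sample.items()):
        rows.append(
            {
                "sample_id": sid,
                "cancer_type": cancer_of[sid],
                "n_csm": n_csm,
                "n_total": n_total,
                "csm_rate": n_csm / n_total if n_total else np.nan,
                "hypermutator": n_csm > hypermutator_cutoff,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "cancer_type", "n_csm", "n_total", "csm_rate", "hypermutator"],
    )
    usable = df[df["n_total"] > 0]
    summary = SampleRateSummary(
        per_sample=df,
        median_rate=float(usable["csm_rate"].median()) if len(usable) else float("nan"),
        rates_by_cancer_type=(
            usable.groupby("cancer_type")["csm_rate"].median()
            if len(usable)
            else pd.Series(dtype=float)
        ),
    )
    if clinical is not None and len(usable):
        merged = usable.merge(clinical, on="sample_id", how="inner")
        young = merged[merged["age"] <= age_cutoff]
        elder = merged[merged["age"] > age_cutoff]
        summary.young_vs_elder_rate = _ttest(young["csm_rate"], elder["csm_rate"])
        summary.young_vs_elder_count = _ttest(young["n_csm"], elder["n_csm"])
        nh = merged[~merged["hypermutator"]]
        summary.young_vs_elder_count_no_hyper = _ttest(
            nh.loc[nh["age"] <= age_cutoff, "n_csm"], nh.loc[nh["age"] > age_cutoff, "n_csm"]
        )
        stage1 = merged[merged["stage"] == "I"]
        rest = merged[merged["stage"].isin(["II", "III", "IV"])]
        summary.stage1_vs_rest_rate = _ttest(stage1["csm_rate"], rest["csm_rate"])
    return summary
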