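import numpy as np
import pandas as pd
import pytest

from conftest import make_variant
from csmvar import incidence_stats
from csmvar.incidence_stats import (
    call_rates,
    incidence,
    incidence_ratio,
    recurrence,
    recurrence_rate,
    sample_rates,
)
from csmvar.io_formats import CommonLocusSet, RegionSet, RegionTotals
from csmvar.variant_classification import classify


def _classified(variants, common=(), region=None):
    loci = CommonLocusSet(common)
    regions = RegionSet([region]) if region else None
    out, _ = classify(variants, loci, regions=regions)
    return out, loci


class TestIncidence:
    def test_simple_rate(self):
        loci = CommonLocusSet(
            [("1", p) for p in range(1, 1001)],
            region_totals={"coding": RegionTotals(common=1000, total=2000)},
        )
        variants = [
            make_variant(pos=p, sample_id=f"S{p}") for p in range(1, 101)
        ]  # 100 distinct common loci mutated
        classified, _ = classify(
            variants, loci, regions=RegionSet([("1", 0, 2000, "coding")])
        )
        res = incidence(classified, loci, "coding")
        assert res.mutated_common == 100
        assert res.rate_common == pytest.approx(0.10)

    def test_curve_is_nested_and_starts_at_ratio(self):
        loci = CommonLocusSet(
            [("1", 10), ("1", 20)],
            region_totals={"g": RegionTotals(common=2, total=100)},
        )
        regions = RegionSet([("1", 0, 100, "g")])
        variants = (
            [make_variant(pos=10, sample_id=f"S{i}") for i in range(3)]
            + [make_variant(pos=20, sample_id="S0")]
            + [make_variant(pos=30, sample_id=f"S{i}") for i in range(2)]
            + [make_variant(pos=40, sample_id="S0")]
        )
        classified, _ = classify(variants, loci, regions=regions)
        res = incidence(classified, loci, "g")
        assert res.curve[1] == pytest.approx(res.ratio)
        # locus 10 mutated in 3 samples, locus 20 in 1; non-common loci in 2
        # and 1 samples: enumerated ratios (common rate / non-common rate);
        # n=3 is absent because no non-common locus reaches 3 samples
        assert sorted(res.curve) == [1, 2]
        assert res.curve[1] == pytest.approx((2 / 2) / (2 / 98))
        assert res.curve[2] == pytest.approx((1 / 2) / (1 / 98))

    def test_distinct_locus_counting(self):
        # same locus mutated in two samples counts once for incidence
        loci = CommonLocusSet(
            [("1", 10)], region_totals={"g": RegionTotals(common=1, total=10)}
        )
        regions = RegionSet([("1", 0, 10, "g")])
        variants = [make_variant(pos=10, sample_id=s) for s in ("A", "B")]
        classified, _ = classify(variants, loci, regions=regions)
        assert incidence(classified, loci, "g").mutated_common == 1

    def test_zero_denominator_gives_nan(self):
        assert np.isnan(incidence_ratio(0.1, 0.0))
        assert np.isnan(incidence_ratio(float("nan"), 0.5))

    def test_printed_rates_round_to_published_ratio(self):
        assert round(incidence_ratio(0.1648, 0.0606), 1) == 2.7


class TestRecurrence:
    def test_multiplicities_enumeration(self):
        # site multiplicities [3, 1, 1] -> recurrence rate 1/3
        loci = CommonLocusSet([("1", 10), ("1", 20), ("1", 30)])
        variants = (
            [make_variant(pos=10, sample_id=f"S{i}") for i in range(3)]
            + [make_variant(pos=20, sample_id="S0")]
            + [make_variant(pos=30, sample_id="S1")]
        )
        classified, _ = classify(variants, loci)
        res = recurrence(classified, "csm")
        assert res.sites_total == 3 and res.sites_recurrent == 1
        assert res.rate == pytest.approx(1 / 3)

    def test_all_singletons_rate_zero(self):
        loci = CommonLocusSet([("1", 10)])
        classified, _ = classify([make_variant(pos=10)], loci)
        assert recurrence(classified, "csm").rate == 0.0

    def test_duplicate_rows_within_sample_counted_once(self):
        loci = CommonLocusSet([("1", 10)])
        variants = [make_variant(pos=10), make_variant(pos=10)]  # same sample+site
        classified, _ = classify(variants, loci)
        assert recurrence(classified, "csm").sites_recurrent == 0

    def test_sample_order_invariance(self):
        loci = CommonLocusSet([("1", 10), ("1", 20)])
        variants = [
            make_variant(pos=10, sample_id="A"),
            make_variant(pos=10, sample_id="B"),
            make_variant(pos=20, sample_id="C"),
        ]
        classified_fwd, _ = classify(variants, loci)
        classified_rev, _ = classify(variants[::-1], loci)
        assert recurrence(classified_fwd, "csm").rate == recurrence(classified_rev, "csm").rate

    def test_site_is_allele_aware(self):
        # same position, different alts -> two distinct sites
        loci = CommonLocusSet([("1", 10)])
        variants = [
            make_variant(pos=10, alt="T", sample_id="A"),
            make_variant(pos=10, alt="G", sample_id="B"),
        ]
        classified, _ = classify(variants, loci)
        res = recurrence(classified, "csm")
        assert res.sites_total == 2 and res.sites_recurrent == 0

    def test_empty_group_rate_nan(self):
        assert np.isnan(recurrence_rate(0, 0))

    def test_printed_counts_reproduce_published_rate(self):
        assert round(100 * recurrence_rate(123_489, 341_709), 2) == 36.14


class TestCallRates:
    def test_enumerated_fixture(self):
        loci = CommonLocusSet([("1", p) for p in (10, 20)])
        variants = (
            [make_variant(pos=10, variant_classification="Intron")]
            + [
                make_variant(pos=30 + i, sample_id=f"I{i}", variant_classification="Intron")
                for i in range(9)
            ]
            + [make_variant(pos=20, variant_classification="Missense")]
            + [
                make_variant(pos=100 + i, sample_id=f"M{i}", variant_classification="Missense")
                for i in range(3)
            ]
            + [make_variant(pos=200, variant_classification="Silent")]
        )
        classified, _ = classify(variants, loci)
        rates = call_rates(classified)
        assert rates["Intron"] == pytest.approx(0.10)
        assert rates["Missense"] == pytest.approx(0.25)
        assert rates["Silent"] == 0.0

    def test_absent_label_omitted(self):
        loci = CommonLocusSet([])
        classified, _ = classify([make_variant()], loci)
        assert "Missense" not in call_rates(classified)

    def test_weighted_average_equals_overall_fraction(self, default_cohort):
        classified = default_cohort["classified"]
        kept = incidence_stats.dedupe([v for v in classified if v.qc_pass])
        rates = call_rates(classified)
        totals = {}
        for v in kept:
            totals[v.variant_classification] = totals.get(v.variant_classification, 0) + 1
        weighted = sum(rates[k] * totals[k] for k in rates) / sum(totals.values())
        overall = sum(1 for v in kept if v.is_csm) / len(kept)
        assert weighted == pytest.approx(overall)


class TestSampleRates:
    def _clinical(self, sample_ids, ages):
        return pd.DataFrame(
            {
                "sample_id": sample_ids,
                "age": ages,
                "gender": ["Female"] * len(sample_ids),
                "stage": ["I"] * len(sample_ids),
                "pfs_time": [100.0] * len(sample_ids),
                "pfs_event": [1] * len(sample_ids),
                "os_time": [100.0] * len(sample_ids),
                "os_event": [0] * len(sample_ids),
            }
        )

    def test_simple_rate(self):
        loci = CommonLocusSet([("1", p) for p in range(10, 60, 10)])
        variants = [make_variant(pos=p) for p in range(10, 60, 10)] + [
            make_variant(pos=p) for p in range(1000, 1450, 10)
        ]
        classified, _ = classify(variants, loci)
        summary = sample_rates(classified)
        row = summary.per_sample.iloc[0]
        assert row["n_csm"] == 5 and row["n_total"] == 50
        assert row["csm_rate"] == pytest.approx(0.10)

    def test_degenerate_zero_variance_flagged(self):
        loci = CommonLocusSet([("1", 10)])
        variants = []
        for i in range(6):
            variants.append(make_variant(pos=10, sample_id=f"S{i}"))
            variants.append(make_variant(pos=1000 + i, sample_id=f"S{i}"))
        classified, _ = classify(variants, loci)
        clin = self._clinical([f"S{i}" for i in range(6)], [50, 50, 50, 70, 70, 70])
        summary = sample_rates(classified, clinical=clin)
        comp = summary.young_vs_elder_rate
        assert comp.degenerate and comp.p == 1.0

    def test_planted_age_difference_detected(self):
        # Higher csm rate planted in the young group; the comparison should
        # find the right direction at alpha=0.05 in >=90% of 20 seeds.
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            variants = []
            ages = []
            for i in range(60):
                young = i < 30
                p = 0.10 if young else 0.06
                n_csm = rng.binomial(40, p)
                sid = f"S{i}"
                ages.append(rng.integers(35, 61) if young else rng.integers(61, 90))
                for j in range(40):
                    pos = 10 + j if j < n_csm else 10_000 + 50 * i + j
                    variants.append(make_variant(pos=pos, sample_id=sid))
            loci = CommonLocusSet([("1", 10 + j) for j in range(40)])
            classified, _ = classify(variants, loci)
            clin = self._clinical([f"S{i}" for i in range(60)], ages)
            comp = sample_rates(classified, clinical=clin).young_vs_elder_rate
            if comp.p < 0.05 and comp.mean_a > comp.mean_b:
                detected += 1
        assert detected >= 18

    def test_hypermutator_flag(self):
        loci = CommonLocusSet([("1", p) for p in range(1, 502)])
        variants = [make_variant(pos=p) for p in range(1, 502)]
        classified, _ = classify(variants, loci)
        assert sample_rates(classified).per_sample["hypermutator"].iloc[0]
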