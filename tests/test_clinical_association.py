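import numpy as np
import pandas as pd
import pytest

from conftest import make_variant
from oracles import fisher_two_sided
from csmvar.clinical_association import (
    carrier_covariate_tables,
    carrier_fisher,
    cox_multivariate,
    frequent_csm,
    km_logrank,
    subtype_gene_frequency,
)
from csmvar.io_formats import CommonLocusSet
from csmvar.variant_classification import classify


def _clinical(n, seed=0, hr_covariate=None, beta=0.0, censor=2000.0):
    rng = np.random.default_rng(seed)
    z = hr_covariate if hr_covariate is not None else np.zeros(n)
    lam = np.log(2) / 500 * np.exp(beta * z)
    t = rng.exponential(1 / lam)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "age": rng.integers(30, 90, size=n),
            "gender": rng.choice(["Female", "Male"], size=n),
            "stage": rng.choice(["I", "II", "III", "IV"], size=n),
            "pfs_time": np.minimum(t, censor),
            "pfs_event": (t <= censor).astype(int),
            "os_time": np.minimum(t, censor),
            "os_event": (t <= censor).astype(int),
        }
    )


class TestFrequentCsm:
    def _cohort(self, multiplicities):
        loci = CommonLocusSet([("1", 10 * (i + 1)) for i in range(len(multiplicities))])
        variants = []
        for i, m in enumerate(multiplicities):
            for s in range(m):
                variants.append(make_variant(pos=10 * (i + 1), sample_id=f"S{s}"))
        return classify(variants, loci)[0]

    def test_strict_threshold_semantics(self):
        classified = self._cohort([16, 15])
        res = frequent_csm(classified, min_samples=15, strict=True)
        assert len(res.keys) == 1
        res_loose = frequent_csm(classified, min_samples=15, strict=False)
        assert len(res_loose.keys) == 2

    def test_bonferroni_alpha(self):
        classified = self._cohort([20, 20, 20, 20])
        res = frequent_csm(classified, min_samples=15)
        assert res.bonferroni_alpha == pytest.approx(0.05 / 4)

    def test_monotone_in_min_samples(self):
        classified = self._cohort([5, 10, 16, 20, 30])
        sizes = [len(frequent_csm(classified, min_samples=m).keys) for m in (4, 9, 15, 25)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_cohort(self):
        assert frequent_csm([], min_samples=15).keys == []


class TestCarrierFisher:
    def test_published_gender_table(self):
        # 30 carriers of 158 females vs 18 of 285 males
        res = carrier_fisher([[30, 128], [18, 267]])
        assert f"{res.p:.3g}" == "8.86e-05"

    def test_balanced_table_null(self):
        res = carrier_fisher([[5, 5], [5, 5]])
        assert res.p == 1.0 and res.odds_ratio == 1.0

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 7, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            res = carrier_fisher(t)
            assert res.p == pytest.approx(fisher_two_sided(t), rel=1e-9), t

    def test_zero_margin_flagged(self):
        res = carrier_fisher([[0, 0], [3, 4]])
        assert res.degenerate and np.isnan(res.p)


class TestCarrierCovariateTables:
    def test_sex_chromosome_excluded_from_gender(self):
        loci = CommonLocusSet([("X", 100), ("1", 100)])
        variants = [
            make_variant(chrom="X", pos=100, sample_id=f"S{i}") for i in range(3)
        ] + [make_variant(chrom="1", pos=100, sample_id=f"S{i}") for i in range(3)]
        classified, _ = classify(variants, loci)
        clin = _clinical(6)
        keys = [("X", 100, "T"), ("1", 100, "T")]
        gender = carrier_covariate_tables(classified, clin, keys, "gender")
        assert list(gender["chrom"]) == ["1"]
        age = carrier_covariate_tables(classified, clin, keys, "age")
        assert len(age) == 2

    def test_cell_counts_sum_to_cohort(self):
        loci = CommonLocusSet([("1", 100)])
        variants = [make_variant(pos=100, sample_id=f"S{i}") for i in range(4)]
        classified, _ = classify(variants, loci)
        clin = _clinical(10)
        out = carrier_covariate_tables(classified, clin, [("1", 100, "T")], "age")
        row = out.iloc[0]
        assert row.filter(like="n_").sum() == 10


class TestKMLogrank:
    def test_identical_groups_p1(self):
        clin = _clinical(40, seed=1)
        doubled = pd.concat(
            [clin, clin.assign(sample_id=[f"T{i}" for i in range(40)])],
            ignore_index=True,
        )
        flags = {f"S{i}": True for i in range(40)} | {f"T{i}": False for i in range(40)}
        res = km_logrank(doubled, flags)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)
        curves = res.extras["km_curves"]
        assert set(curves) == {"carrier", "noncarrier"}
        assert (curves["carrier"].to_numpy() == curves["noncarrier"].to_numpy()).all()

    def test_single_group_rejected(self):
        clin = _clinical(10)
        with pytest.raises(ValueError):
            km_logrank(clin, {f"S{i}": True for i in range(10)})

    def test_planted_hazard_ratio_detected(self):
        # carriers with half the hazard, n=300: detect at alpha=0.05 in
        # >=90% of 20 seeds
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            carrier = rng.random(300) < 0.5
            z = np.where(carrier, np.log(0.5), 0.0)
            clin = _clinical(300, seed=seed + 100, hr_covariate=z, beta=1.0)
            res = km_logrank(clin, dict(zip(clin["sample_id"], carrier)))
            detected += res.p < 0.05
        assert detected >= 18


class TestCoxMultivariate:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=500)
        clin = _clinical(500, seed=3, hr_covariate=z, beta=-0.8)
        clin["csm_rate"] = z
        res = cox_multivariate(clin, endpoint="pfs")
        beta_hat = float(np.log(res.hazard_ratios["csm_rate"]))
        assert beta_hat == pytest.approx(-0.8, abs=0.25)

    def test_null_coverage(self):
        # covariate independent of survival: 95% CI covers HR=1 in >=90%/20
        covered = 0
        for seed in range(20):
            # covariate drawn from an unrelated stream: truly independent of
            # the survival times generated inside _clinical
            rng = np.random.default_rng(seed + 1000)
            clin = _clinical(150, seed=seed)
            clin["csm_rate"] = rng.normal(size=150)
            res = cox_multivariate(clin, endpoint="pfs")
            lo, hi = res.confidence_intervals.loc["csm_rate"]
            covered += lo <= 1.0 <= hi
        assert covered >= 18

    def test_constant_covariate_named_in_error(self):
        clin = _clinical(50)
        clin["csm_rate"] = 1.0
        with pytest.raises(ValueError, match="csm_rate"):
            cox_multivariate(clin)

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=200)
        clin = _clinical(200, seed=4, hr_covariate=z, beta=-0.5)
        clin["csm_rate"] = z
        res_days = cox_multivariate(clin)
        months = clin.copy()
        months["pfs_time"] = months["pfs_time"] / 30.44
        res_months = cox_multivariate(months)
        assert float(res_days.hazard_ratios["csm_rate"]) == pytest.approx(
            float(res_months.hazard_ratios["csm_rate"]), rel=1e-6
        )


class TestSubtypeGeneFrequency:
    def test_extreme_frequencies(self):
        carriers = {"A", "B"}
        muts = pd.DataFrame(
            {"sample_id": ["A", "B"], "gene": ["TP53", "TP53"]}
        )
        out = subtype_gene_frequency(muts, carriers, ["A", "B", "C", "D"])
        row = out[out["gene"] == "TP53"].iloc[0]
        assert row["freq_carrier"] == 1.0 and row["freq_noncarrier"] == 0.0

    def test_identical_groups_all_q1(self):
        muts = pd.DataFrame(
            {"sample_id": ["A", "C"], "gene": ["KRAS", "KRAS"]}
        )
        out = subtype_gene_frequency(muts, {"A", "B"}, ["A", "B", "C", "D"])
        assert (out["q"] == 1.0).all()

    def test_planted_gene_top_ranked(self):
        # 40% vs 10% planted for one gene among 20: top-ranked in >=95% seeds
        top = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            samples = [f"S{i}" for i in range(100)]
            carriers = set(samples[:50])
            rows = []
            for g in range(20):
                gene = f"G{g}"
                p_car, p_non = (0.4, 0.1) if g == 0 else (0.1, 0.1)
                for s in samples:
                    p = p_car if s in carriers else p_non
                    if rng.random() < p:
                        rows.append({"sample_id": s, "gene": gene})
            out = subtype_gene_frequency(pd.DataFrame(rows), carriers, samples)
            top += out.iloc[0]["gene"] == "G0"
        assert top >= 19
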