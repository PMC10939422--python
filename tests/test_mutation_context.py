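import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant
from csmvar.io_formats import ReferenceGenome
from csmvar.mutation_context import (
    DBS78_CHANNELS,
    ID83_CHANNELS,
    SBS96_CHANNELS,
    build_spectra,
    classify_dbs,
    classify_id,
    classify_sbs,
    cpg_ct_fraction,
    revcomp,
    six_type_distribution,
)


class TestCatalogs:
    def test_channel_counts(self):
        assert len(SBS96_CHANNELS) == 96
        assert len(set(SBS96_CHANNELS)) == 96
        assert len(DBS78_CHANNELS) == 78
        assert len(ID83_CHANNELS) == 83


class TestClassifySBS:
    def test_cpg_context(self, toy_reference):
        ref, _ = toy_reference
        mc = classify_sbs(make_variant(chrom="chr1", pos=4, ref="C", alt="T"), ref)
        assert mc.channel == "A[C>T]G" and mc.cpg_flag

    def test_purine_strand_canonicalized(self, toy_reference):
        # G>A at CGT context reads A[C>T]G on the pyrimidine strand
        ref, _ = toy_reference
        mc = classify_sbs(make_variant(chrom="chr1", pos=5, ref="G", alt="A"), ref)
        assert mc.channel == "A[C>T]G" and mc.cpg_flag

    def test_t_center_not_cpg(self, toy_reference):
        ref, _ = toy_reference
        mc = classify_sbs(make_variant(chrom="chr1", pos=13, ref="T", alt="G"), ref)
        assert mc.channel == "A[T>G]A" and not mc.cpg_flag

    def test_reference_mismatch_raises(self, toy_reference):
        ref, _ = toy_reference
        with pytest.raises(ValueError, match="reference"):
            classify_sbs(make_variant(chrom="chr1", pos=4, ref="G", alt="T"), ref)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 61), st.integers(0, 2), st.data())
    def test_reverse_complement_invariance(self, offset, alt_i, data):
        rng = np.random.default_rng(offset * 7 + alt_i)
        seq = "".join(rng.choice(list("ACGT"), size=64))
        pos = offset + 2  # keep context inside
        base = seq[pos - 1]
        alt = [b for b in "ACGT" if b != base][alt_i]
        fwd = ReferenceGenome({"c": seq})
        rev = ReferenceGenome({"c": revcomp(seq)})
        mc_fwd = classify_sbs(
            make_variant(chrom="c", pos=pos, ref=base, alt=alt), fwd
        )
        mc_rev = classify_sbs(
            make_variant(
                chrom="c", pos=len(seq) - pos + 1, ref=revcomp(base), alt=revcomp(alt)
            ),
            rev,
        )
        assert mc_fwd.channel == mc_rev.channel
        assert mc_fwd.cpg_flag == mc_rev.cpg_flag


class TestClassifyDBS:
    @pytest.mark.parametrize(
        "ref,alt,channel",
        [
            ("TG", "CA", "TG>CA"),
            ("CA", "TG", "TG>CA"),  # reverse complement of TG>CA
            ("CC", "TT", "CC>TT"),
            ("AT", "TG", "AT>CA"),  # self-complementary ref: alt canonicalized
            ("GG", "AA", "CC>TT"),
        ],
    )
    def test_canonicalization(self, ref, alt, channel):
        assert classify_dbs(make_variant(ref=ref, alt=alt)).channel == channel

    def test_all_doublets_map_into_catalog(self):
        for ref_d in ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT",
                      "GA", "GC", "GG", "GT", "TA", "TC", "TG", "TT"):
            for a1 in "ACGT":
                for a2 in "ACGT":
                    alt = a1 + a2
                    if alt == ref_d or alt[0] == ref_d[0] or alt[1] == ref_d[1]:
                        continue  # COSMIC doublets change both bases
                    mc = classify_dbs(make_variant(ref=ref_d, alt=alt))
                    assert mc.channel in DBS78_CHANNELS


class TestClassifyID:
    def test_delete_single_c_run1(self):
        ref = ReferenceGenome({"c": "AACATTGG"})
        mc = classify_id(make_variant(chrom="c", pos=3, ref="C", alt=""), ref)
        assert mc.channel == "1:Del:C:1"

    def test_delete_c_in_longer_run(self):
        ref = ReferenceGenome({"c": "AACCCATT"})
        mc = classify_id(make_variant(chrom="c", pos=4, ref="C", alt=""), ref)
        assert mc.channel == "1:Del:C:3"

    def test_delete_g_canonicalized_to_c(self):
        ref = ReferenceGenome({"c": "AATGATT"})
        mc = classify_id(make_variant(chrom="c", pos=4, ref="G", alt=""), ref)
        assert mc.channel == "1:Del:C:1"

    def test_insert_t_no_neighbors(self):
        ref = ReferenceGenome({"c": "AACAA"})
        mc = classify_id(make_variant(chrom="c", pos=3, ref="", alt="T"), ref)
        assert mc.channel == "1:Ins:T:0"

    def test_insert_t_into_run(self):
        # insertion point between the two Ts: two existing neighbors
        ref = ReferenceGenome({"c": "AATTA"})
        mc = classify_id(make_variant(chrom="c", pos=3, ref="", alt="T"), ref)
        assert mc.channel == "1:Ins:T:2"

    def test_tandem_repeat_deletion(self):
        ref = ReferenceGenome({"c": "ACACACG"})
        mc = classify_id(make_variant(chrom="c", pos=1, ref="AC", alt=""), ref)
        assert mc.channel == "2:Del:R:3"

    def test_microhomology_deletion(self):
        # delete TAG; right flank begins TA (2-base homology), no full copy
        ref = ReferenceGenome({"c": "GCTAGTACC"})
        mc = classify_id(make_variant(chrom="c", pos=3, ref="TAG", alt=""), ref)
        assert mc.channel == "3:Del:M:2"

    def test_plain_deletion_no_repeat_no_mh(self):
        ref = ReferenceGenome({"c": "GGTACCCA"})
        mc = classify_id(make_variant(chrom="c", pos=3, ref="TAC", alt=""), ref)
        assert mc.channel == "3:Del:R:1"

    def test_unnormalized_indel_rejected(self):
        ref = ReferenceGenome({"c": "GGTAGCCA"})
        with pytest.raises(ValueError, match="normaliz"):
            classify_id(make_variant(chrom="c", pos=3, ref="TA", alt="T"), ref)

    def test_long_insertion_repeat_aware(self):
        ref = ReferenceGenome({"c": "AACACACAGG"})
        # insert CA after pos 2, adjacent to 3 existing CA copies
        mc = classify_id(make_variant(chrom="c", pos=2, ref="", alt="CA"), ref)
        assert mc.channel == "2:Ins:R:3"


class TestSpectra:
    def test_single_channel_column(self):
        seq = "GACGT" * 20
        ref = ReferenceGenome({"c": seq})
        # pos 3,8,... are C with context ACG
        variants = [
            make_variant(chrom="c", pos=3 + 5 * i, ref="C", alt="T") for i in range(5)
        ]
        matrix, errors = build_spectra(variants, ref, grouping="sample")
        assert not errors
        assert matrix.loc["A[C>T]G", "S1"] == 5
        assert matrix["S1"].sum() == 5

    def test_count_conservation_on_cohort(self, default_cohort):
        kept = [v for v in default_cohort["classified"] if v.qc_pass]
        snvs = [v for v in kept if v.variant_type == "SNV"]
        ref = default_cohort["genome"].reference
        matrix, errors = build_spectra(snvs, ref, grouping="cancer_type")
        assert not errors
        assert int(matrix.to_numpy().sum()) == len(
            {(v.sample_id,) + v.key for v in snvs}
        )

    def test_empty_stream_gives_labeled_zero_matrix(self, toy_reference):
        ref, _ = toy_reference
        matrix, _ = build_spectra([], ref)
        assert list(matrix.index) == list(SBS96_CHANNELS)
        assert matrix.shape[1] == 0


class TestCpGFraction:
    def test_all_mass_in_cpg_channel(self):
        s = pd.Series(0, index=list(SBS96_CHANNELS))
        s["A[C>T]G"] = 7
        assert cpg_ct_fraction(s) == 1.0

    def test_even_split_over_ct_channels(self):
        # 16 C>T context channels, 4 of which are NCG -> fraction 0.25
        s = pd.Series(0, index=list(SBS96_CHANNELS))
        for ch in SBS96_CHANNELS:
            if "[C>T]" in ch:
                s[ch] = 10
        assert cpg_ct_fraction(s) == pytest.approx(0.25)

    def test_six_type_distribution_pure_tc(self):
        s = pd.Series(0, index=list(SBS96_CHANNELS))
        for ch in SBS96_CHANNELS:
            if "[T>C]" in ch:
                s[ch] = 3
        dist = six_type_distribution(s)
        assert dist["T>C"] == 1.0
        assert dist.drop("T>C").sum() == 0.0

    def test_zero_total_is_nan(self):
        s = pd.Series(0, index=list(SBS96_CHANNELS))
        assert np.isnan(cpg_ct_fraction(s))
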