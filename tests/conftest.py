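import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from csmvar.io_formats import CommonLocusSet, ReferenceGenome, RegionSet, SomaticVariant
from csmvar.synthetic_data import (
    SimulationConfig,
    cohort_variants,
    simulate_cohort,
    simulate_genome,
)
from csmvar.variant_classification import classify


def make_variant(**kwargs) -> SomaticVariant:
    """A valid SNV with overridable fields, for terse test construction."""
    defaults = dict(
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        sample_id="S1",
        cancer_type="CT01",
        tumor_depth=50,
        tumor_alt_reads=10,
        normal_alt_reads=0,
        variant_classification="Intron",
    )
    defaults.update(kwargs)
    return SomaticVariant(**defaults)


@pytest.fixture(scope="session")
def qc_fixture():
    """Hand-enumerated 10-variant set: 2 at common loci, 3 QC failures
    (one per reason), 5 clean non-common variants."""
    loci = CommonLocusSet([("1", 100), ("1", 200)])
    variants = [
        make_variant(pos=100, ref="A", alt="T"),  # csm
        make_variant(pos=200, ref="C", alt="G", normal_alt_reads=1),  # csm
        make_variant(pos=300, ref="G", alt="A", normal_alt_reads=3),  # normal_support
        make_variant(pos=400, ref="T", alt="C", tumor_depth=4, tumor_alt_reads=4),  # low_depth
        make_variant(pos=500, ref="A", alt="C", tumor_depth=100, tumor_alt_reads=4),  # low_vaf
    ] + [make_variant(pos=600 + 100 * i, sample_id=f"S{i + 2}") for i in range(5)]
    return variants, loci


@pytest.fixture(scope="session")
def toy_reference():
    #          123456789012345678901234567890
    seq = "GGACGTTAGCCATACGGTAACCGATTAGCA"
    return ReferenceGenome({"chr1": seq}), seq


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default planted study conditions,
    classified against its own common-loci set."""
    cfg = SimulationConfig(seed=0)
    genome = simulate_genome(cfg)
    mutations, clinical = simulate_cohort(cfg, genome)
    loci = genome.locus_set()
    classified, summary = classify(cohort_variants(mutations), loci, regions=genome.regions)
    return {
        "config": cfg,
        "genome": genome,
        "mutations": mutations,
        "clinical": clinical,
        "loci": loci,
        "classified": classified,
        "summary": summary,
    }
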