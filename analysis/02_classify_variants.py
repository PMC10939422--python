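#!/usr/bin/env python
"""QC-filter the cohort and split it into csm / ncsm variants.

Reads the synthetic inputs written by 01_simulate_cohort.py, applies the
three read-support filters (normal support >= 3, tumor depth < 5x,
VAF < 0.05), intersects surviving mutations with the common-loci set, and
writes the classified table plus a count summary under results/.
"""

import json
from pathlib import Path

from csmvar.io_formats import (
    read_common_loci_vcf,
    read_regions,
    read_somatic_table,
    variants_to_frame,
)
from csmvar.variant_classification import classify

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    indir = ROOT / "synthetic"
    regions = read_regions(indir / "regions.bed")
    loci = read_common_loci_vcf(indir / "common_loci.vcf", regions=regions)
    table = read_somatic_table(indir / "mutations.tsv")
    print(f"read {len(table.variants)} mutations ({table.n_skipped} malformed rows)")

    classified, summary = classify(table.variants, loci, regions=regions)
    variants_to_frame(classified).to_csv(ROOT / "classified.tsv", sep="\t", index=False)
    (ROOT / "classify_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))

    s = summary.as_dict()
    print(f"QC removed {s['n_removed']} (by reason: {s['removed_by_reason']})")
    print(f"retained {s['n_retained']}: {s['n_csm']} csm, {s['n_ncsm']} ncsm "
          f"({100 * s['n_csm'] / s['n_retained']:.2f}% csm)")


if __name__ == "__main__":
    main()
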