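#!/usr/bin/env python
"""Inverted-repeat analysis of variant context windows.

Extracts 21-base context windows (10 flanking bases each side), finds
maximal inverted repeats (arm 4..20, gap <= 5, at most one mismatch, minus
the post-filters), classifies each window exact / near / none, and tests
enrichment of palindromic contexts in csm versus ncsm variants. Also scans
a CpG-flanked degenerate motif over both groups.
"""

import json
from pathlib import Path

from csmvar.io_formats import read_common_loci_vcf, read_fasta, read_somatic_table
from csmvar.palindrome_motif import extract_context, palindrome_enrichment, scan_motif
from csmvar.variant_classification import classify

ROOT = Path(__file__).resolve().parent.parent / "results"
MOTIF = "NCGDHNDHCGN"  # CpG-flanked degenerate pattern


def main() -> None:
    indir = ROOT / "synthetic"
    loci = read_common_loci_vcf(indir / "common_loci.vcf")
    reference = read_fasta(indir / "genome.fa")
    table = read_somatic_table(indir / "mutations.tsv")
    classified, _ = classify(table.variants, loci)
    kept = [v for v in classified if v.qc_pass]

    windows = {True: [], False: []}
    for v in kept:
        windows[bool(v.is_csm)].append(extract_context(v, reference))
    enr = palindrome_enrichment(windows[True], windows[False])
    for name, props in (("csm", enr.proportions_a), ("ncsm", enr.proportions_b)):
        pal = props["exact"] + props["near"]
        print(f"{name}: exact {100 * props['exact']:.2f}%, near {100 * props['near']:.2f}%, "
              f"palindromic total {100 * pal:.2f}%")
    print(f"Fisher exact (palindromic vs none): OR={enr.odds_ratio:.2f}, p={enr.p_value:.3g}")

    all_windows = windows[True] + windows[False]
    labels = ["csm"] * len(windows[True]) + ["ncsm"] * len(windows[False])
    scan = scan_motif(MOTIF, all_windows, group_labels=labels)
    print(f"motif {MOTIF}: matched {100 * scan.fraction:.2f}% of windows "
          f"(csm {100 * scan.by_group['csm']:.2f}%, ncsm {100 * scan.by_group['ncsm']:.2f}%)")

    (ROOT / "palindrome_enrichment.json").write_text(
        json.dumps(
            {
                "csm": enr.proportions_a,
                "ncsm": enr.proportions_b,
                "odds_ratio": enr.odds_ratio,
                "p": enr.p_value,
                "motif": {"pattern": MOTIF, "by_group": scan.by_group},
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
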