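#!/usr/bin/env python
"""Carrier association and survival analysis.

Screens frequently mutated csm variants for association with age group and
gender (Fisher exact, Bonferroni-guarded), then fits the multivariate Cox
proportional-hazards model of progression-free survival on age, gender,
stage and the standardized per-sample csm rate. The fitted log-hazard of
csm rate should recover the planted value of -0.8 (better survival at
higher csm rates).
"""

import json
from pathlib import Path

import numpy as np

from csmvar.clinical_association import (
    carrier_covariate_tables,
    cox_multivariate,
    frequent_csm,
)
from csmvar.incidence_stats import sample_rates
from csmvar.io_formats import read_clinical_table, read_common_loci_vcf, read_somatic_table
from csmvar.variant_classification import classify

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    indir = ROOT / "synthetic"
    loci = read_common_loci_vcf(indir / "common_loci.vcf")
    table = read_somatic_table(indir / "mutations.tsv")
    classified, _ = classify(table.variants, loci)
    clinical = read_clinical_table(indir / "clinical.tsv")
    kept = [v for v in classified if v.qc_pass]

    # desk-scale cohort: the full-cohort default cutoff of 15 samples is far
    # above this cohort's multiplicities, so screen recurrent variants (>1)
    freq = frequent_csm(kept, min_samples=1)
    print(f"{len(freq.keys)} csm variants mutated in >1 sample "
          f"(Bonferroni alpha {freq.bonferroni_alpha:.3g})")
    for covariate in ("gender", "age"):
        df = carrier_covariate_tables(kept, clinical, freq.keys, covariate)
        df.to_csv(ROOT / f"carrier_{covariate}.tsv", sep="\t", index=False)
        n_sig = int((df["p"] < 0.01).sum()) if len(df) else 0
        print(f"  {covariate}: {len(df)} variants tested, {n_sig} at p<0.01")

    sr = sample_rates(classified, clinical=clinical)
    merged = clinical.merge(sr.per_sample[["sample_id", "csm_rate"]], on="sample_id")
    z = merged["csm_rate"]
    merged["csm_rate"] = (z - z.mean()) / z.std()
    cox = cox_multivariate(merged, endpoint="pfs")
    beta = float(np.log(cox.hazard_ratios["csm_rate"]))
    lo, hi = np.log(cox.confidence_intervals.loc["csm_rate"])
    print(f"Cox PFS: log-hazard of standardized csm rate = {beta:.3f} "
          f"[{lo:.2f}, {hi:.2f}] (HR {np.exp(beta):.3f}, p={float(cox.p_values['csm_rate']):.3g})")
    print("  csm rate scaling: standardized per-sample fraction (z-score)")

    payload = {
        "n_frequent": len(freq.keys),
        "pfs_log_hazard_csm_rate": round(beta, 3),
        "ci": [round(lo, 3), round(hi, 3)],
        "p": float(cox.p_values["csm_rate"]),
    }
    (ROOT / "clinical_summary.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
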