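# csmvar — somatic mutations at common germline loci

About 1% of human genome positions carry a germline variant at ≥1% minor
allele frequency ("common loci", the dbSNP *common* set). Tumor somatic
mutations landing on those positions — **csmVariants** — turn out to be far
from a random subsample of all somatic mutations: their per-locus incidence
is several-fold that of non-common loci, they recur across patients, they
are dominated by C>T transitions at CpG sites (the 5-methylcytosine
deamination hallmark of the aging signature SBS1), their sequence contexts
are enriched for inverted repeats (DNA palindromes, which can stall
mismatch repair), and per-sample csmVariant rates associate with clinical
outcome.

`csmvar` is a tested reimplementation of that analysis as a reusable
pipeline, exercised end to end on synthetic cohorts with known planted
effect sizes:

- **io_formats** — MAF-like mutation tables, common-loci VCF, BED/GFF3
  regions, indexed FASTA, COSMIC-style signature TSVs, clinical TSVs; one
  internal coordinate convention (1-based variants, 0-based half-open
  intervals).
- **synthetic_data** — toy genomes, common-locus sets, tumor cohorts and
  clinical tables with planted incidence ratio, CpG C>T boost, palindrome
  plants, hypermutators and a survival effect.
- **variant_classification** — the three QC filters (normal support ≥ 3,
  tumor depth < 5×, VAF < 0.05 ⇒ removed) and the csm/ncsm partition.
- **incidence_stats** — incidence rates and ratios (rate = distinct mutated
  loci / total loci of the class), the ratio-vs-minimum-mutation-number
  curve, recurrence rates, per-classification call rates, per-sample
  csmVariant rates with age/stage comparisons.
- **mutation_context** — SBS-96 / DBS-78 / ID-83 channel classification and
  spectrum matrices; CpG C>T fractions.
- **signature_fitting** — non-negative least squares refitting of fixed
  reference signatures, a = argmin_{a≥0} ‖v − S a‖₂; contributions
  c_k = a_k/Σa; cosine reconstruction diagnostics; csm-vs-ncsm contribution
  t-tests.
- **palindrome_motif** — maximal inverted-repeat detection in 21-base
  context windows (arm 4–20, gap ≤ 5, ≤ 1 mismatch, post-filters),
  exact/near/none classification, Fisher enrichment, IUPAC motif scanning.
- **clinical_association** — frequent-variant screens, carrier × covariate
  Fisher tests, Kaplan–Meier/log-rank, multivariate Cox proportional
  hazards (age, gender, stage, csm rate).
- **cli / pipeline** — `csmvar simulate|classify|stats|spectra|fit|
  palindrome|motif|associate|survival|run` plus a one-config pipeline with
  a hashed run manifest.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (1 Mb genome, 10,000 common loci, 200 samples, planted incidence
ratio 2.7, CpG C>T boost 4, palindromes at 30% of common loci, log-hazard
−0.8 of standardized csm rate on PFS):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_classify_variants.py
python analysis/03_incidence_recurrence.py
python analysis/04_spectra_signatures.py
python analysis/05_palindrome_context.py
python analysis/06_clinical_association.py
```

Output of the run at seed 0 (abridged):

```
QC removed 703 (by reason: {'normal_support': 233, 'low_depth': 233, 'low_vaf': 237})
retained 11059: 306 csm, 10753 ncsm (2.77% csm)
genome: rate_common=0.0301 rate_noncommon=0.0108 ratio=2.79
csm: 231 SNVs classified, CpG C>T fraction 35.93%
ncsm: 8040 SNVs classified, CpG C>T fraction 11.72%
CpG C>T fold (csm/ncsm): 3.07
csm: exact 4.90%, near 58.17%, palindromic total 63.07%
ncsm: exact 4.21%, near 44.60%, palindromic total 48.81%
Fisher exact (palindromic vs none): OR=1.79, p=9.63e-07
Cox PFS: log-hazard of standardized csm rate = -0.762 [-0.96, -0.57] (HR 0.467, p=1.77e-14)
```

Reading these: the incidence ratio estimate 2.79 recovers the planted 2.7;
the csm arm shows the planted CpG C>T excess (≈36% vs ≈12%, fold ≈3) and
palindromic-context enrichment (63% vs 49% of windows with a surviving
inverted repeat); and the Cox model recovers the planted protective effect
of a higher csmVariant rate on progression-free survival (−0.76 vs planted
−0.8, hazard ratio 0.47). Tables land under `results/`.

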