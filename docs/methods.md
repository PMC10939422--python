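# Methods

## Problem setting

Somatic small mutations (SNVs, doublets, small indels) from a tumor cohort
are partitioned by whether they fall on *common loci* — genome positions
carrying a germline variant at ≥1% minor allele frequency in a reference
population — into csmVariants and ncsmVariants. The package quantifies how
the two classes differ in per-locus incidence, recurrence, mutation-class
spectrum, refit signature activity, sequence context, and clinical
association, and ships a generator that plants each of those effects so the
whole chain has parameter-recovery tests.

## Definitions and statistics

- **QC filters.** A mutation is removed when any of: ≥3 supporting reads in
  the matched normal, tumor depth <5×, or tumor VAF <0.05. The boundaries
  are read literally (3 removed; depth exactly 5 kept; VAF exactly 0.05
  kept). Zero tumor depth is removed as `low_depth`; the undefined VAF is
  not also charged as `low_vaf`. All applicable reasons are recorded.
- **Intersection.** Default csm membership is positional — (chrom, pos) in
  the common set, with `chr` prefixes stripped — because the source data
  define common *sites*; an allele-aware mode (alt must match a recorded
  common allele) is provided and is always a subset of the positional
  calls. Indels count as "at" a locus only when anchored exactly at it
  (insertions keyed by the base before the insertion, deletions by the
  first deleted base; alleles are stored pure, with no shared anchor
  bases).
- **Incidence rate** of a locus class in a region: distinct mutated
  positions / total positions of the class; the **incidence ratio** divides
  the common-locus rate by the non-common rate. The curve restricts the
  numerators to loci mutated in ≥ n samples (a strict > n variant is a
  flag). Denominators come from a user-supplied region set; the generator
  emits both a `coding` region and a whole-contig `genome` region.
- **Recurrence** is variant-level: distinct (chrom, pos, alt) sites seen in
  ≥2 samples over all such sites, per class. Incidence is positional but
  recurrence is allele-aware, matching how the two statistics are defined
  in the source analysis; duplicate rows (same sample and site) are
  always collapsed first.
- **Call rate** per functional classification: csm fraction of mutations
  with that label. **csm rate** per sample: csm / total small mutations,
  with an `--snv-only` variant; samples with >500 csmVariants are flagged
  hypermutators and group comparisons are re-run without them. Group
  comparisons (age ≤60 vs >60, stage I vs II–IV) use Welch t-tests;
  zero-variance inputs yield a flagged non-significant p = 1 instead of an
  exception.
- **Spectra.** SBS-96 channels are pyrimidine-centric trinucleotides;
  DBS-78 canonicalizes the reference doublet (and, for self-complementary
  doublets, the alternate pair) by reverse complement; ID-83 records 1-bp
  events by pyrimidine base identity and homopolymer run length (deletions
  1..6+ counting the deleted base; insertions 0..5+ counting existing
  neighbors), longer events by tandem-repeat copy number, and
  non-repetitive deletions by flanking microhomology length. Adjacent SNVs
  are never auto-merged into doublets; doublets must arrive as 2-bp
  substitutions. A reference-mismatch at classification time excludes the
  variant from spectra and is reported, not raised.
- **Signature refitting** is plain NNLS against a fixed, user-supplied
  reference whose columns sum to 1. Contributions are shares of attributed
  counts, so they are invariant to rescaling the spectrum. Contribution
  comparisons between matched groups use a paired t-test by default
  (the two arms share group labels by construction); an unpaired Welch
  variant is available.
- **Palindromes.** An inverted repeat is two arms (left = reverse
  complement of right, up to `max_mismatch` positions) around a gap, with
  arm ∈ [4, 20], gap ≤ 5, mismatches ≤ 1 by default — the parameter set of
  the reference tool with `-m`/`-M` read as *arm* length (configurable
  reading; the exclusion rule pairing "4 bp" with one mismatch supports
  it). Hits are **maximal**: reported only when the arms cannot be extended
  outward within the window and arm bound without exceeding the mismatch
  budget. Post-filters remove arm-4/1-mismatch hits and hits whose
  stem∪loop span misses the variant. A window is "exact" if a surviving
  hit has 0 mismatches, "near" at 1, else "none"; enrichment tests pool
  exact+near against none in a two-sided Fisher test. Truncated windows at
  contig edges are flagged and excluded from enrichment by default.
  Consequence of maximality worth knowing: an exact planted palindrome
  whose outward extension pairs one random complementary base becomes a
  longer 1-mismatch maximal hit, so planted palindromes mostly classify as
  "near" — this is by design and does not affect pooled enrichment.
- **Motif scanning** is single-strand sliding-window matching over
  degenerate codes (both-strand scanning by flag). The degeneracy table
  follows the motif catalog convention used in this analysis, in which
  `M` denotes C/G; the remaining IUPAC codes keep their standard meanings.
- **Clinical association.** Frequent csmVariants are those mutated in
  strictly more than `min_samples` (default 15) samples; the association
  screen is Bonferroni-guarded at 0.05/N_frequent. Carrier × gender tables
  exclude sex-chromosome variants; age dichotomizes at 60. Survival uses
  lifelines: log-rank for carrier groups, Cox proportional hazards (Efron
  ties) for age + gender + stage + csm rate. The csm-rate scaling
  (fraction vs standardized) is reported next to every hazard ratio, since
  hazard ratios are meaningless without it. Gene-level subtype frequency
  tables use per-gene Fisher tests with Benjamini–Hochberg correction.

## Synthetic study conditions

Defaults of `SimulationConfig` (one choice, used everywhere):

| parameter | default | meaning |
|---|---|---|
| genome_length | 1e6 | single random contig |
| common_fraction | 0.01 | fraction of positions designated common |
| n_samples | 200 | tumors |
| base_rate | 5e-5 | per-locus per-sample mutation probability |
| incidence_ratio | 2.7 | rate multiplier at common loci |
| cpg_ct_boost | 4.0 | rate multiplier at CpG-site common loci |
| palindrome_plant_fraction | 0.3 | common loci wrapped in an exact arm-5/gap-3 repeat |
| hypermutator_fraction / multiplier | 0.02 / 10 | heavy-tailed sample rates |
| indel fractions | 1/8 + 1/8 | SNV:INS:DEL = 6:1:1 |
| qc_violation_fraction | 0.02 per filter | labeled spoiled records |
| survival_effect | −0.8 | log-hazard of standardized csm rate on PFS |

Mutations are independent across samples and loci; recurrence arises only
from the elevated per-locus rate, which is exactly the contrast the
incidence statistics measure. The CpG boost acts on *which common loci
mutate* (CpG-site loci mutate `cpg_ct_boost`-fold faster, renormalized so
the mean common-locus rate is unchanged and the planted incidence ratio
stays exact) and on the drawn substitution (C>T mass at NCG contexts
boosted before renormalization); with boost 4 the csm CpG C>T fraction
lands in the low-30% range against ≈11–12% for ncsm, the regime the real
cohort shows. Planted palindromes are kept ≥13 bases apart so no plant
overwrites another. Substitutions are drawn conditionally on the local
trinucleotide from a mixture of two deterministic synthetic signature
columns (an aging-like CpG-C>T signature and a flat background); these are
synthetic stand-ins constructed in-package, not published catalog entries.
Clinical tables draw PFS from an exponential model with log-hazard
`survival_effect` × standardized realized csm rate, administratively
censored at 1500 days; overall survival carries no planted effect and
serves as a null.

What the generator does **not** emulate: real genome composition and SNP
ascertainment, linkage, clonal structure, sequencing error, and
region-dependent mutation-rate covariates. Passing recovery tests
therefore demonstrate correctness of the statistics under the planted
model, not that real cohorts will show these effect sizes.

## Numerical choices

- NNLS via active-set (`scipy.optimize.nnls`); deterministic given (v, S).
  All-zero spectra return flagged zero fits.
- Fisher tests are exact two-sided hypergeometric (`scipy.stats`); the test
  suite cross-checks them against an independent full-support enumeration.
- The palindrome finder enumerates gap placements and extends arms outward
  with cumulative mismatch counts; per placement the unique maximal arm is
  emitted. The suite proves it identical to an exhaustive
  (start, arm, gap) enumerator on >10,000 windows up to length 12,
  including homopolymer/alternating/planted adversarial cases.
  Overlapping and nested hits are all reported; window classification
  takes the best surviving hit (fewest mismatches, then longest arm, then
  smallest gap, then leftmost).
- Cox fits use Efron tie handling; non-convergence yields a flagged
  result, a constant covariate is a hard error naming the column.
- Simulation sizes in the recovery suites (1 Mb genome, 200 samples, 20
  fixed seeds; 300 kb for null calibration) are the package's chosen
  desk-scale study conditions; pilot runs at these sizes fixed the frozen
  test tolerances (incidence ratio within 15%, NNLS contributions within
  ±0.05, Cox CI coverage ≥90%, pooled palindrome enrichment at α = 1e-6
  with per-seed significance at 1e-3).

## Known limitations

- Position-only intersection cannot distinguish a somatic mutation at a
  common site from one recreating the common allele; the allele-aware mode
  exists but no claim is made about which the source analysis used.
- DBS records must be pre-formed; the `--merge-adjacent` preprocessing is
  intentionally not applied by default.
- ID-83 microhomology uses the larger of left/right partial overlap,
  capped per class; fully left-aligned input indels are assumed.
- The motif module scans and tests enrichment of *given* patterns; de-novo
  motif discovery is out of scope, as are PWM scores beyond IUPAC
  degeneracy, dN/dS driver-gene discovery, and functional-term clustering.
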