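"""Synthetic genomes, common-locus sets, tumor cohorts and clinical tables
with known planted parameters.

Every downstream stage gets a parameter-recovery test from this module: the
generator plants an elevated per-locus mutation probability at common loci
(the incidence ratio), a CpG C>T excess at common loci, exact inverted
repeats around a fraction of common loci, hypermutator samples, and a
log-hazard linking each sample's csm rate to progression-free survival.
Mutations at a locus are independent across samples; recurrence arises
purely from the elevated per-locus rate, which is exactly the contrast the
incidence statistics measure.

Identical (config, seed) produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CLINICAL_TABLE_COLUMNS,
    CommonLocusSet,
    ReferenceGenome,
    RegionSet,
    SomaticVariant,
    write_bed,
    write_common_loci_vcf,
    write_fasta,
    write_somatic_table,
)
from .mutation_context import SBS96_CHANNELS, revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_cohort",
    "default_signature_matrix",
    "random_signature_matrix",
    "write_cohort",
    "cohort_variants",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Planted parameters of one synthetic study.

    Defaults are the conditions the downstream recovery tests assume: a 1 Mb
    single-contig genome with 1% of loci designated common, 200 tumor
    samples, a per-locus per-sample mutation probability of 5e-5 away from
    common loci and 2.7x that at common loci, a CpG C>T channel boost of 4 at
    common loci, exact palindromes planted around 30% of common loci, 2%
    hypermutators at 10x rate, and a -0.8 log-hazard of standardized csm
    rate on progression-free survival.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 1
    common_fraction: float = 0.01
    n_samples: int = 200
    base_rate: float = 5e-5
    incidence_ratio: float = 2.7
    cpg_ct_boost: float = 4.0
    palindrome_plant_fraction: float = 0.3
    hypermutator_fraction: float = 0.02
    hypermutator_multiplier: float = 10.0
    signature_mixture: tuple[float, ...] = (0.6, 0.4)
    indel_fraction_ins: float = 1 / 8  # SNV:INS:DEL = 6:1:1
    indel_fraction_del: float = 1 / 8
    qc_violation_fraction: float = 0.02  # per filter
    coding_fraction: float = 0.3
    n_cancer_types: int = 4
    survival_effect: float = -0.8
    baseline_median_pfs: float = 500.0  # days
    censor_time: float = 1500.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "common_fraction",
            "palindrome_plant_fraction",
            "hypermutator_fraction",
            "qc_violation_fraction",
            "coding_fraction",
            "indel_fraction_ins",
            "indel_fraction_del",
        ):
            x = getattr(self, name)
            if not 0 <= x <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {x}")
        if self.incidence_ratio < 0 or self.base_rate < 0:
            raise ValueError("rates must be non-negative")
        if any(w < 0 for w in self.signature_mixture):
            raise ValueError("signature mixture weights must be non-negative")
        if abs(sum(self.signature_mixture) - 1) > 1e-9:
            raise ValueError("signature mixture weights must sum to 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_flat(self) -> dict[str, str]:
        out = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if isinstance(val, tuple):
                val = ",".join(str(x) for x in val)
            out[f.name] = str(val)
        return out


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    common_loci: set[tuple[str, int]]  # (chrom, 1-based pos)
    planted_palindrome_loci: set[tuple[str, int]]
    regions: RegionSet
    config: SimulationConfig

    @property
    def reference(self) -> ReferenceGenome:
        return ReferenceGenome(self.sequences)

    def locus_set(self) -> CommonLocusSet:
        out = CommonLocusSet(self.common_loci)
        out.compute_region_totals(self.regions)
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "vcf": outdir / "common_loci.vcf",
            "bed": outdir / "regions.bed",
        }
        write_fasta(self.sequences, paths["fasta"])
        records = []
        for chrom, pos in sorted(self.common_loci):
            ref = self.sequences[chrom][pos - 1]
            alt = "A" if ref != "A" else "G"
            records.append((chrom, pos, ref, alt))
        write_common_loci_vcf(records, paths["vcf"])
        write_bed(self.regions.intervals, paths["bed"])
        return paths


_PLANT_ARM = 5
_PLANT_GAP = 3
_PLANT_SPAN = 2 * _PLANT_ARM + _PLANT_GAP  # 13 bases, inside the 21-base window


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Random reference with designated common loci and planted palindromes.

    A ``palindrome_plant_fraction`` of common loci have their surroundings
    overwritten by an exact inverted repeat (arm 5, gap 3) centered so the
    locus sits on the loop; a "coding" interval covering ``coding_fraction``
    of each contig is emitted as the region annotation.
    """
    rng = np.random.default_rng(config.seed)
    margin = 25
    per_chrom = config.genome_length // config.n_chroms
    if per_chrom <= 2 * margin:
        raise ValueError("genome too short for the requested layout")
    n_common_total = int(round(config.genome_length * config.common_fraction))
    sequences: dict[str, str] = {}
    common: set[tuple[str, int]] = set()
    planted: set[tuple[str, int]] = set()
    intervals = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=per_chrom)
        n_common = n_common_total // config.n_chroms
        if n_common > per_chrom - 2 * margin:
            raise ValueError("genome too short for the requested common loci")
        positions = rng.choice(
            np.arange(margin + 1, per_chrom - margin), size=n_common, replace=False
        )
        positions.sort()
        n_plant = int(round(config.palindrome_plant_fraction * n_common))
        # plant in random order, keeping centers >= 13 bases apart so no
        # planted motif overwrites another
        plant_at: set[int] = set()
        blocked: set[int] = set()
        if n_plant:
            for cand in rng.permutation(positions):
                c = int(cand)
                if c in blocked:
                    continue
                plant_at.add(c)
                blocked.update(range(c - _PLANT_SPAN + 1, c + _PLANT_SPAN))
                if len(plant_at) == n_plant:
                    break
        for pos in positions:
            common.add((chrom, int(pos)))
            if pos in plant_at:
                arm = "".join(rng.choice(_BASES, size=_PLANT_ARM))
                gap = "".join(rng.choice(_BASES, size=_PLANT_GAP))
                motif = arm + gap + revcomp(arm)
                # center the 13-mer so the locus falls mid-loop
                start0 = int(pos) - 1 - (_PLANT_ARM + _PLANT_GAP // 2)
                seq[start0 : start0 + _PLANT_SPAN] = list(motif)
                planted.add((chrom, int(pos)))
        sequences[chrom] = "".join(seq)
        intervals.append((chrom, 0, per_chrom, "genome"))
        coding_len = int(per_chrom * config.coding_fraction)
        if coding_len > 0:
            intervals.append((chrom, 0, coding_len, "coding"))
    return SimulatedGenome(
        sequences=sequences,
        common_loci=common,
        planted_palindrome_loci=planted,
        regions=RegionSet(intervals),
        config=config,
    )


def default_signature_matrix(channels=SBS96_CHANNELS) -> pd.DataFrame:
    """Deterministic two-column COSMIC-style SBS reference (synthetic).

    ``aging_like`` concentrates 60% of its mass on the four N[C>T]G channels
    (the 5-methylcytosine deamination hallmark) with the rest on other C>T
    contexts; ``background`` is flat with a mild tilt toward T>C.  Synthetic
    stand-ins constructed here, not published catalog entries.
    """
    aging = pd.Series(0.0, index=list(channels))
    cpg = [f"{f}[C>T]G" for f in "ACGT"]
    other_ct = [ch for ch in channels if "[C>T]" in ch and ch not in cpg]
    aging[cpg] = 0.6 / len(cpg)
    aging[other_ct] = 0.4 / len(other_ct)
    background = pd.Series(1.0, index=list(channels))
    tc = [ch for ch in channels if "[T>C]" in ch]
    background[tc] = 2.0
    background /= background.sum()
    return pd.DataFrame({"aging_like": aging, "background": background})


def random_signature_matrix(k: int, seed: int, channels=SBS96_CHANNELS) -> pd.DataFrame:
    """k random non-degenerate signature columns (Dirichlet draws)."""
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(len(channels), 0.3), size=k).T
    return pd.DataFrame(
        cols, index=list(channels), columns=[f"SYN{i + 1}" for i in range(k)]
    )


def _is_cpg_site(seq: str, pos: int) -> bool:
    """True when the 1-based position is the C or the G of a CpG dinucleotide."""
    base = seq[pos - 1]
    if base == "C" and pos < len(seq) and seq[pos] == "G":
        return True
    if base == "G" and pos >= 2 and seq[pos - 2] == "C":
        return True
    return False


def _conditional_alt_probs(signature_probs: np.ndarray, boost_cpg: float) -> dict:
    """p(alt | trinucleotide context) tables from an SBS-96 probability vector.

    Keyed by the pyrimidine-strand context; the CpG boost multiplies the
    C>T mass of NCG contexts before renormalization.
    """
    index = {ch: i for i, ch in enumerate(SBS96_CHANNELS)}
    tables: dict[tuple[str, str, str], tuple[list[str], np.ndarray]] = {}
    for ref in "CT":
        alts = [b for b in "ACGT" if b != ref]
        for five in "ACGT":
            for three in "ACGT":
                w = np.array(
                    [signature_probs[index[f"{five}[{ref}>{a}]{three}"]] for a in alts]
                )
                if ref == "C" and three == "G" and boost_cpg != 1.0:
                    w = w.copy()
                    w[alts.index("T")] *= boost_cpg
                if w.sum() == 0:
                    w = np.ones(len(alts))
                tables[(five, ref, three)] = (alts, w / w.sum())
    return tables


def _draw_snv_alt(rng, context: str, tables) -> str:
    five, ref, three = context[0], context[1], context[2]
    flipped = ref in "AG"
    if flipped:
        rc = revcomp(context)
        five, ref, three = rc[0], rc[1], rc[2]
    alts, probs = tables[(five, ref, three)]
    alt = rng.choice(alts, p=probs)
    return revcomp(alt) if flipped else alt


def simulate_cohort(
    config: SimulationConfig,
    genome: SimulatedGenome,
    signature_matrix: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic mutation table and clinical table for one synthetic cohort.

    Returns (mutations, clinical).  The mutation table carries the standard
    MAF-like columns plus a ``planted_qc_fail`` label naming the filter each
    deliberately spoiled record violates, so filter tests can assert exact
    removal counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if signature_matrix is None:
        signature_matrix = default_signature_matrix()
    if signature_matrix.shape[1] != len(config.signature_mixture):
        raise ValueError("signature_mixture length must match signature columns")
    probs = signature_matrix.to_numpy() @ np.asarray(config.signature_mixture)
    tables_common = _conditional_alt_probs(probs, config.cpg_ct_boost)
    tables_noncommon = _conditional_alt_probs(probs, 1.0)

    # Per-locus rate multipliers at common loci: CpG-site loci mutate
    # cpg_ct_boost times faster, normalized so the mean multiplier is 1 and
    # the planted incidence ratio is preserved exactly.
    common_by_chrom: dict[str, np.ndarray] = {}
    common_mult: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        pos = np.array(sorted(p for c, p in genome.common_loci if c == chrom), dtype=int)
        common_by_chrom[chrom] = pos
        mult = np.ones(len(pos))
        for i, p in enumerate(pos):
            if _is_cpg_site(seq, int(p)):
                mult[i] = config.cpg_ct_boost
        if len(mult) and mult.mean() > 0:
            mult /= mult.mean()
        common_mult[chrom] = mult

    cancer_types = [f"CT{i + 1:02d}" for i in range(config.n_cancer_types)]
    rows: list[dict] = []
    sample_truth: list[dict] = []
    p_ins, p_del = config.indel_fraction_ins, config.indel_fraction_del

    for si in range(config.n_samples):
        sample_id = f"S{si + 1:04d}"
        cancer = cancer_types[si % len(cancer_types)]
        hyper = bool(rng.random() < config.hypermutator_fraction)
        mult = config.hypermutator_multiplier if hyper else 1.0
        mu_nc = min(config.base_rate * mult, 1.0)
        mu_c = min(config.base_rate * config.incidence_ratio * mult, 1.0)
        n_c_truth = 0
        n_total_truth = 0
        for chrom, seq in genome.sequences.items():
            n = len(seq)
            cpos = common_by_chrom[chrom]
            n_common = len(cpos)
            n_noncommon = n - n_common
            # common-locus mutations: independent per-locus Bernoulli draws
            # with CpG-weighted rates averaging to mu_c
            p_locus = np.minimum(mu_c * common_mult[chrom], 1.0)
            chosen_c = cpos[rng.random(n_common) < p_locus] if n_common else np.array([], int)
            # non-common mutations: draw genome positions, reject common loci
            k_nc = rng.binomial(n_noncommon, mu_nc) if n_noncommon else 0
            chosen_nc: list[int] = []
            cset = set(int(p) for p in cpos)
            while len(chosen_nc) < k_nc:
                cand = rng.integers(21, n - 20, size=k_nc - len(chosen_nc))
                for p in cand:
                    p = int(p)
                    if p not in cset and p not in chosen_nc:
                        chosen_nc.append(p)
            for pos, at_common in [(int(p), True) for p in chosen_c] + [
                (p, False) for p in chosen_nc
            ]:
                row = _make_mutation(
                    rng,
                    chrom,
                    pos,
                    seq,
                    at_common,
                    tables_common if at_common else tables_noncommon,
                    p_ins,
                    p_del,
                    config,
                    genome,
                    sample_id,
                    cancer,
                )
                if row is None:
                    continue
                rows.append(row)
                n_total_truth += 1
                if at_common:
                    n_c_truth += 1
        sample_truth.append(
            {
                "sample_id": sample_id,
                "cancer_type": cancer,
                "hypermutator": hyper,
                "n_csm_truth": n_c_truth,
                "n_total_truth": n_total_truth,
            }
        )

    mutations = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "sample_id",
            "cancer_type",
            "tumor_depth",
            "tumor_alt_reads",
            "normal_alt_reads",
            "variant_classification",
            "planted_qc_fail",
        ],
    )
    clinical = _simulate_clinical(rng, pd.DataFrame(sample_truth), config)
    return mutations, clinical


def _make_mutation(
    rng,
    chrom,
    pos,
    seq,
    at_common,
    tables,
    p_ins,
    p_del,
    config,
    genome,
    sample_id,
    cancer,
):
    u = rng.random()
    context = seq[pos - 2 : pos + 1]
    if len(context) < 3 or "N" in context:
        return None
    if u < p_ins:
        length = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        ref, alt = "", "".join(rng.choice(_BASES, size=length))
        vtype = "INS"
    elif u < p_ins + p_del:
        length = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        if pos + length - 1 > len(seq):
            return None
        ref, alt = seq[pos - 1 : pos - 1 + length], ""
        vtype = "DEL"
    else:
        ref = seq[pos - 1]
        alt = _draw_snv_alt(rng, context, tables)
        vtype = "SNV"

    depth = max(int(rng.poisson(60)), 8)
    vaf = float(rng.beta(5, 7))
    alt_reads = max(int(rng.binomial(depth, vaf)), max(1, int(np.ceil(0.05 * depth))))
    normal_alt = 0
    planted = ""
    if rng.random() < 3 * config.qc_violation_fraction:
        which = rng.choice(["normal_support", "low_depth", "low_vaf"])
        planted = which
        if which == "normal_support":
            normal_alt = 3 + int(rng.poisson(2))
        elif which == "low_depth":
            depth = int(rng.integers(1, 5))
            alt_reads = min(alt_reads, depth)
            if depth > 0 and alt_reads / depth < 0.05:
                alt_reads = depth  # keep only the depth filter firing
        else:
            alt_reads = max(int(np.floor(0.05 * depth)) - 1, 0)

    labels = genome.regions.labels_at(chrom, pos)
    if "coding" in labels:
        vclass = "Missense" if rng.random() < 0.7 else "Silent"
    else:
        vclass = "Intron"
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "sample_id": sample_id,
        "cancer_type": cancer,
        "tumor_depth": depth,
        "tumor_alt_reads": alt_reads,
        "normal_alt_reads": normal_alt,
        "variant_classification": vclass,
        "planted_qc_fail": planted,
    }


def _simulate_clinical(rng, truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    n = len(truth)
    ages = rng.integers(30, 91, size=n)
    genders = np.where(np.arange(n) % 2 == 0, "Female", "Male")
    stages = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.3, 0.3, 0.25, 0.15])
    rate = np.where(
        truth["n_total_truth"] > 0, truth["n_csm_truth"] / truth["n_total_truth"].clip(lower=1), 0.0
    )
    sd = rate.std()
    z = (rate - rate.mean()) / sd if sd > 0 else np.zeros(n)
    lam0 = np.log(2) / config.baseline_median_pfs
    lam = lam0 * np.exp(config.survival_effect * z)
    pfs_raw = rng.exponential(1.0 / lam)
    pfs_event = (pfs_raw <= config.censor_time).astype(int)
    pfs_time = np.minimum(pfs_raw, config.censor_time)
    os_raw = rng.exponential(config.baseline_median_pfs / np.log(2) * 1.5, size=n)
    os_event = (os_raw <= config.censor_time).astype(int)
    os_time = np.minimum(os_raw, config.censor_time)
    return pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "age": ages,
            "gender": genders,
            "stage": stages,
            "pfs_time": np.round(pfs_time, 1),
            "pfs_event": pfs_event,
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
        },
        columns=CLINICAL_TABLE_COLUMNS,
    )


def write_cohort(
    mutations: pd.DataFrame, clinical: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"mutations": outdir / "mutations.tsv", "clinical": outdir / "clinical.tsv"}
    mutations.to_csv(paths["mutations"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    return paths


def cohort_variants(mutations: pd.DataFrame) -> list[SomaticVariant]:
    """SomaticVariant objects from a generated mutation table (in memory)."""
    out = []
    for row in mutations.itertuples(index=False):
        out.append(
            SomaticVariant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                cancer_type=row.cancer_type,
                tumor_depth=int(row.tumor_depth),
                tumor_alt_reads=int(row.tumor_alt_reads),
                normal_alt_reads=int(row.normal_alt_reads),
                variant_classification=row.variant_classification,
            )
        )
    return out
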