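"""End-to-end orchestration of the csm-variant analysis stages.

A ``RunConfig`` fixes every input path, stage toggle and threshold; a run
executes the stages in dependency order (classify -> stats -> spectra ->
fit -> palindrome -> clinical), writes tidy TSV outputs, and records a
manifest with the serialized config, per-stage record counts and a content
hash for every output file, so re-running with identical config and inputs
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    clinical_association,
    incidence_stats,
    io_formats,
    mutation_context,
    palindrome_motif,
    signature_fitting,
    synthetic_data,
)
from .variant_classification import classify

logger = logging.getLogger("csmvar")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[csmvar] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """All paths, toggles and thresholds of one pipeline run.

    Threshold defaults are the analysis' stated values: QC triple
    (normal>=3 / depth<5 / VAF<0.05), frequent-variant cutoff >15 samples,
    hypermutator cutoff >500 csm mutations, context flank 10, palindrome
    arm 4..20 / gap<=5 / mismatch<=1, age cutoff 60.
    """

    outdir: str = "csmvar_run"
    mutations: str = ""
    common_vcf: str = ""
    regions: str = ""
    fasta: str = ""
    clinical: str = ""
    signatures: str = ""
    simulate: bool = False  # generate all inputs synthetically into outdir
    seed: int = 0
    mode: str = "position"
    region_label: str = "coding"
    # stage toggles
    run_stats: bool = True
    run_spectra: bool = True
    run_fit: bool = True
    run_palindrome: bool = True
    run_clinical: bool = True
    # thresholds
    normal_support_max: int = 2
    min_depth: int = 5
    min_vaf: float = 0.05
    min_samples: int = 15
    hypermutator_cutoff: int = 500
    flank: int = 10
    min_arm: int = 4
    max_arm: int = 20
    max_gap: int = 5
    max_mismatch: int = 1
    age_cutoff: float = 60.0

    def to_flat(self) -> dict[str, str]:
        return {f.name: str(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_flat(cls, mapping: dict[str, str]) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in mapping:
                continue
            raw = mapping[f.name]
            if f.type in ("bool", bool):
                kwargs[f.name] = raw in ("True", "true", "1")
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        mapping = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            mapping[key.strip()] = val.strip()
        return cls.from_flat(mapping)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{k}={v}\n" for k, v in self.to_flat().items())
        )

    def validate(self) -> list[str]:
        problems = []
        if not self.simulate:
            for name in ("mutations", "common_vcf", "fasta"):
                p = getattr(self, name)
                if not p:
                    problems.append(f"missing required input path: {name}")
                elif not Path(p).exists():
                    problems.append(f"input does not exist: {name}={p}")
        if self.min_arm < 1 or self.max_arm < self.min_arm:
            problems.append("palindrome arm bounds invalid")
        if not 0 <= self.min_vaf <= 1:
            problems.append("min_vaf must be in [0, 1]")
        return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_flat(), "stages": {}, "outputs": {}}
    stage = "inputs"
    try:
        if config.simulate:
            logger.info("simulate: generating synthetic inputs (seed=%d)", config.seed)
            sim = synthetic_data.SimulationConfig(seed=config.seed)
            genome = synthetic_data.simulate_genome(sim)
            paths = genome.write(outdir / "inputs")
            mutations_df, clinical_df = synthetic_data.simulate_cohort(sim, genome)
            cohort = synthetic_data.write_cohort(mutations_df, clinical_df, outdir / "inputs")
            config = dataclasses.replace(
                config,
                mutations=str(cohort["mutations"]),
                common_vcf=str(paths["vcf"]),
                regions=str(paths["bed"]),
                fasta=str(paths["fasta"]),
                clinical=str(cohort["clinical"]),
            )
            manifest["config"] = config.to_flat()

        regions = io_formats.read_regions(config.regions) if config.regions else None
        loci = io_formats.read_common_loci_vcf(config.common_vcf, regions=regions)
        reference = io_formats.read_fasta(config.fasta)
        table = io_formats.read_somatic_table(config.mutations)
        logger.info(
            "inputs: %d variants read, %d malformed rows skipped, %d common loci",
            len(table.variants),
            table.n_skipped,
            len(loci),
        )

        stage = "classify"
        classified, summary = classify(
            table.variants,
            loci,
            regions=regions,
            mode=config.mode,
            normal_support_max=config.normal_support_max,
            min_depth=config.min_depth,
            min_vaf=config.min_vaf,
        )
        manifest["stages"]["classify"] = summary.as_dict()
        logger.info(
            "classify: %(n_retained)d retained (%(n_csm)d csm / %(n_ncsm)d ncsm), "
            "%(n_removed)d removed",
            summary.as_dict(),
        )
        io_formats.variants_to_frame(classified).to_csv(
            outdir / "classified.tsv", sep="\t", index=False
        )
        (outdir / "classify_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))
        kept = [v for v in classified if v.qc_pass]

        if config.run_stats:
            stage = "stats"
            _run_stats(config, outdir, classified, kept, loci, regions, manifest)
        if config.run_spectra or config.run_fit:
            stage = "spectra"
            _run_spectra_fit(config, outdir, kept, reference, manifest)
        if config.run_palindrome:
            stage = "palindrome"
            _run_palindrome(config, outdir, kept, reference, manifest)
        if config.run_clinical and config.clinical:
            stage = "clinical"
            _run_clinical(config, outdir, kept, manifest)
    except Exception:
        logger.error("stage %r failed; partial outputs preserved in %s", stage, outdir)
        raise

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stats(config, outdir, classified, kept, loci, regions, manifest):
    stats_info = {}
    if regions is not None and loci.region_totals:
        inc = incidence_stats.incidence(classified, loci, config.region_label)
        pd.DataFrame(
            [
                {
                    "region": inc.region,
                    "mutated_common": inc.mutated_common,
                    "total_common": inc.total_common,
                    "mutated_noncommon": inc.mutated_noncommon,
                    "total_noncommon": inc.total_noncommon,
                    "rate_common": inc.rate_common,
                    "rate_noncommon": inc.rate_noncommon,
                    "ratio": inc.ratio,
                }
            ]
        ).to_csv(outdir / "incidence.tsv", sep="\t", index=False)
        pd.Series(inc.curve, name="ratio").rename_axis("min_mutation_number").to_csv(
            outdir / "incidence_curve.tsv", sep="\t"
        )
        stats_info["incidence_ratio"] = inc.ratio
    rec = {g: incidence_stats.recurrence(classified, g) for g in ("csm", "ncsm")}
    pd.DataFrame(
        [
            {"group": g, "sites_total": r.sites_total, "sites_recurrent": r.sites_recurrent, "rate": r.rate}
            for g, r in rec.items()
        ]
    ).to_csv(outdir / "recurrence.tsv", sep="\t", index=False)
    stats_info["recurrence"] = {g: r.rate for g, r in rec.items()}
    cr = incidence_stats.call_rates(classified)
    pd.Series(cr, name="call_rate").rename_axis("variant_classification").to_csv(
        outdir / "call_rates.tsv", sep="\t"
    )
    clin = io_formats.read_clinical_table(config.clinical) if config.clinical else None
    sr = incidence_stats.sample_rates(
        classified,
        clinical=clin,
        hypermutator_cutoff=config.hypermutator_cutoff,
        age_cutoff=config.age_cutoff,
    )
    sr.per_sample.to_csv(outdir / "sample_rates.tsv", sep="\t", index=False)
    stats_info["median_csm_rate"] = sr.median_rate
    manifest["stages"]["stats"] = stats_info
    logger.info("stats: median csm rate %.4f", sr.median_rate)


def _run_spectra_fit(config, outdir, kept, reference, manifest):
    info = {}
    fits = {}
    for label, want in (("csm", True), ("ncsm", False)):
        subset = [v for v in kept if v.is_csm is want]
        spectrum, errors = mutation_context.build_spectra(
            subset, reference, grouping="cancer_type", system="SBS96"
        )
        spectrum.to_csv(outdir / f"spectrum_sbs96_{label}.tsv", sep="\t")
        info[f"{label}_classified"] = int(spectrum.to_numpy().sum()) if spectrum.size else 0
        info[f"{label}_errors"] = len(errors)
        info[f"{label}_cpg_ct_fraction"] = (
            mutation_context.cpg_ct_fraction(spectrum) if spectrum.size else float("nan")
        )
        if config.run_fit and spectrum.size:
            if config.signatures:
                S = io_formats.read_signature_matrix(config.signatures, system="SBS96")
            else:
                S = synthetic_data.default_signature_matrix()
            fits[label] = signature_fitting.fit_spectrum_matrix(spectrum, S)
            rows = []
            for group, fit in fits[label].items():
                for sig, act, contrib in zip(
                    fit.signatures, fit.activities, fit.contributions
                ):
                    rows.append(
                        {
                            "group": group,
                            "signature": sig,
                            "activity": act,
                            "contribution": contrib,
                            "cosine": fit.cosine,
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / f"signature_fit_{label}.tsv", sep="\t", index=False)
    manifest["stages"]["spectra"] = info
    logger.info(
        "spectra: csm CpG C>T fraction %.4f vs ncsm %.4f",
        info.get("csm_cpg_ct_fraction", float("nan")),
        info.get("ncsm_cpg_ct_fraction", float("nan")),
    )


def _run_palindrome(config, outdir, kept, reference, manifest):
    params = dict(
        min_arm=config.min_arm,
        max_arm=config.max_arm,
        max_gap=config.max_gap,
        max_mismatch=config.max_mismatch,
    )
    windows = {True: [], False: []}
    for v in kept:
        windows[bool(v.is_csm)].append(
            palindrome_motif.extract_context(v, reference, flank=config.flank)
        )
    if windows[True] and windows[False]:
        enr = palindrome_motif.palindrome_enrichment(windows[True], windows[False], **params)
        result = {
            "csm": enr.proportions_a,
            "ncsm": enr.proportions_b,
            "odds_ratio": enr.odds_ratio,
            "p": enr.p_value,
        }
        (outdir / "palindrome_enrichment.json").write_text(json.dumps(result, indent=2))
        manifest["stages"]["palindrome"] = result
        logger.info(
            "palindrome: csm palindromic %.3f vs ncsm %.3f (p=%.3g)",
            enr.proportions_a["exact"] + enr.proportions_a["near"],
            enr.proportions_b["exact"] + enr.proportions_b["near"],
            enr.p_value,
        )


def _run_clinical(config, outdir, kept, manifest):
    clin = io_formats.read_clinical_table(config.clinical)
    freq = clinical_association.frequent_csm(kept, min_samples=config.min_samples)
    info = {"n_frequent": len(freq.keys), "bonferroni_alpha": freq.bonferroni_alpha}
    for covariate in ("gender", "age"):
        df = clinical_association.carrier_covariate_tables(
            kept, clin, freq.keys, covariate, age_cutoff=config.age_cutoff
        )
        df.to_csv(outdir / f"carrier_{covariate}.tsv", sep="\t", index=False)
    sr = incidence_stats.sample_rates(kept, clinical=clin, age_cutoff=config.age_cutoff)
    merged = clin.merge(
        sr.per_sample[["sample_id", "csm_rate"]], on="sample_id", how="inner"
    )
    try:
        cox = clinical_association.cox_multivariate(merged, endpoint="pfs")
        if cox.hazard_ratios is not None:
            info["pfs_hr_csm_rate"] = float(cox.hazard_ratios["csm_rate"])
            info["pfs_p"] = float(cox.p_values["csm_rate"])
            cox.hazard_ratios.rename("hazard_ratio").to_csv(
                outdir / "cox_pfs.tsv", sep="\t"
            )
    except ValueError as exc:
        info["cox_error"] = str(exc)
    manifest["stages"]["clinical"] = info
    logger.info("clinical: %d frequent csm variants", len(freq.keys))
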