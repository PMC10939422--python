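"""Carrier-status association and survival analysis for frequently mutated
csm variants.

Frequently mutated variants (somatically mutated in more than ``min_samples``
tumors, strictly by default) are screened for association with age group
(<=60 vs >60) and gender by two-sided Fisher exact tests, Bonferroni-guarded
at 0.05 over the number of frequent variants.  Survival is compared by
Kaplan-Meier / log-rank between carrier groups and by a multivariate Cox
proportional-hazards model adjusting for age, gender and stage (Efron tie
handling, via lifelines).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .incidence_stats import AGE_CUTOFF, dedupe
from .io_formats import normalize_chrom
from .variant_classification import ClassifiedVariant

__all__ = [
    "FrequentCsmResult",
    "FisherResult",
    "SurvivalResult",
    "frequent_csm",
    "carrier_fisher",
    "carrier_covariate_tables",
    "km_logrank",
    "cox_multivariate",
    "subtype_gene_frequency",
]

SEX_CHROMS = {"X", "Y"}


@dataclass
class FrequentCsmResult:
    keys: list[tuple[str, int, str]]
    min_samples: int
    bonferroni_alpha: float


def frequent_csm(
    variants: Iterable[ClassifiedVariant],
    min_samples: int = 15,
    strict: bool = True,
) -> FrequentCsmResult:
    """csm variant keys mutated in more than ``min_samples`` samples.

    The Bonferroni threshold for the downstream association screen is
    0.05 / (number of frequent variants).
    """
    samples_per_key: dict[tuple, set[str]] = defaultdict(set)
    for v in dedupe(variants):
        if v.qc_pass and v.is_csm:
            samples_per_key[v.key].add(v.sample_id)
    thr = (lambda m: m > min_samples) if strict else (lambda m: m >= min_samples)
    keys = sorted(k for k, s in samples_per_key.items() if thr(len(s)))
    alpha = 0.05 / len(keys) if keys else float("nan")
    return FrequentCsmResult(keys=keys, min_samples=min_samples, bonferroni_alpha=alpha)


@dataclass
class FisherResult:
    p: float
    odds_ratio: float
    table: np.ndarray
    degenerate: bool = False


def carrier_fisher(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test of a 2x2 carrier-by-covariate table.

    Exact hypergeometric two-sided p (sum of tables at most as probable as
    observed); the sample odds ratio is reported.  A zero margin gives a
    flagged undefined result.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FisherResult(p=float("nan"), odds_ratio=float("nan"), table=t, degenerate=True)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return FisherResult(p=float(p), odds_ratio=float(odds), table=t)


def carrier_covariate_tables(
    variants: Iterable[ClassifiedVariant],
    clinical: pd.DataFrame,
    keys: Sequence[tuple[str, int, str]],
    covariate: str,
    age_cutoff: float = AGE_CUTOFF,
) -> pd.DataFrame:
    """Per-variant 2x2 tables and Fisher tests against gender or age group.

    Sex-chromosome variants are excluded from gender tests.  Returns a tidy
    frame (variant key, cell counts, odds ratio, p).
    """
    if covariate not in ("gender", "age"):
        raise ValueError("covariate must be 'gender' or 'age'")
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for v in dedupe(variants):
        if v.qc_pass and v.is_csm and v.key in set(keys):
            carriers[v.key].add(v.sample_id)
    clin = clinical.dropna(subset=["age" if covariate == "age" else "gender"])
    if covariate == "age":
        level = clin["age"] <= age_cutoff
        level_names = (f"<={age_cutoff}", f">{age_cutoff}")
    else:
        level = clin["gender"] == "Female"
        level_names = ("Female", "Male")
    samples_a = set(clin.loc[level, "sample_id"])
    samples_b = set(clin.loc[~level, "sample_id"])
    rows = []
    for key in keys:
        chrom = normalize_chrom(key[0])
        if covariate == "gender" and chrom in SEX_CHROMS:
            continue
        carrier_set = carriers.get(key, set())
        a_car = len(carrier_set & samples_a)
        b_car = len(carrier_set & samples_b)
        table = [
            [a_car, len(samples_a) - a_car],
            [b_car, len(samples_b) - b_car],
        ]
        res = carrier_fisher(table)
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "alt": key[2],
                f"carriers_{level_names[0]}": a_car,
                f"n_{level_names[0]}": len(samples_a),
                f"carriers_{level_names[1]}": b_car,
                f"n_{level_names[1]}": len(samples_b),
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SurvivalResult:
    model: str
    p: float
    hazard_ratios: pd.Series | None = None
    confidence_intervals: pd.DataFrame | None = None
    p_values: pd.Series | None = None
    statistic: float = float("nan")
    flagged: str = ""
    extras: dict = field(default_factory=dict)


def _endpoint_cols(endpoint: str) -> tuple[str, str]:
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    return f"{endpoint}_time", f"{endpoint}_event"


def km_logrank(
    clinical: pd.DataFrame,
    groups: Mapping[str, bool] | pd.Series,
    endpoint: str = "pfs",
) -> SurvivalResult:
    """Log-rank comparison of carriers vs non-carriers on one endpoint.

    ``groups`` maps sample_id to carrier flag; every group must be non-empty
    and each must contain at least one event.
    """
    from lifelines.statistics import logrank_test

    tcol, ecol = _endpoint_cols(endpoint)
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    df = clinical.set_index("sample_id").join(groups.rename("carrier"), how="inner")
    df = df.dropna(subset=["carrier", tcol, ecol])
    g1 = df[df["carrier"].astype(bool)]
    g0 = df[~df["carrier"].astype(bool)]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both carrier groups must be non-empty")
    if g1[ecol].sum() == 0 or g0[ecol].sum() == 0:
        raise ValueError("each group needs at least one event")
    res = logrank_test(g1[tcol], g0[tcol], event_observed_A=g1[ecol], event_observed_B=g0[ecol])
    from lifelines import KaplanMeierFitter

    curves = {}
    for name, grp in (("carrier", g1), ("noncarrier", g0)):
        km = KaplanMeierFitter()
        km.fit(grp[tcol], event_observed=grp[ecol], label=name)
        curves[name] = km.survival_function_
    return SurvivalResult(
        model="km_logrank",
        p=float(res.p_value),
        statistic=float(res.test_statistic),
        extras={
            "n_carrier": len(g1),
            "n_noncarrier": len(g0),
            "km_curves": curves,
        },
    )


def cox_multivariate(
    clinical: pd.DataFrame,
    covariates: Sequence[str] = ("age", "gender", "stage", "csm_rate"),
    endpoint: str = "pfs",
) -> SurvivalResult:
    """Multivariate Cox proportional-hazards fit (Efron ties, lifelines).

    ``clinical`` must hold the covariate columns; ``gender`` is encoded
    Female=1, ``stage`` as ordinal I..IV (unknown dropped).  Constant
    covariates are a hard error naming the column; non-convergence yields a
    flagged result rather than an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    tcol, ecol = _endpoint_cols(endpoint)
    df = clinical.copy()
    if "gender" in covariates:
        df["gender"] = (df["gender"] == "Female").astype(float)
    if "stage" in covariates:
        stage_map = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}
        df["stage"] = df["stage"].map(stage_map)
    df = df.dropna(subset=[*covariates, tcol, ecol])
    if df[ecol].sum() == 0:
        raise ValueError("no events in the cohort")
    for cov in covariates:
        if df[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df[[*covariates, tcol, ecol]], duration_col=tcol, event_col=ecol)
    except (ConvergenceError, ValueError) as exc:
        return SurvivalResult(model="coxph", p=float("nan"), flagged=f"non-convergence: {exc}")
    return SurvivalResult(
        model="coxph",
        p=float(fitter.log_likelihood_ratio_test().p_value),
        hazard_ratios=fitter.hazard_ratios_,
        confidence_intervals=np.exp(fitter.confidence_intervals_),
        p_values=fitter.summary["p"],
        extras={
            "coefficients": fitter.params_,
            "n": len(df),
            "n_events": int(df[ecol].sum()),
        },
    )


def subtype_gene_frequency(
    mutations: pd.DataFrame,
    carriers: set[str] | Sequence[str],
    all_samples: Sequence[str],
) -> pd.DataFrame:
    """Per-gene mutation frequency in carrier vs non-carrier groups.

    ``mutations`` needs columns sample_id and gene.  Frequency is the
    fraction of group samples with at least one mutation in the gene; each
    gene gets a two-sided Fisher test with Benjamini-Hochberg correction
    across genes.
    """
    from statsmodels.stats.multitest import multipletests

    carriers = set(carriers)
    samples = list(dict.fromkeys(all_samples))
    non_carriers = [s for s in samples if s not in carriers]
    n_car, n_non = len(carriers), len(non_carriers)
    mutated: dict[str, set[str]] = defaultdict(set)
    for row in mutations[["sample_id", "gene"]].itertuples(index=False):
        mutated[row.gene].add(row.sample_id)
    rows = []
    for gene in sorted(mutated):
        m_car = len(mutated[gene] & carriers)
        m_non = len(mutated[gene] - carriers)
        freq_car = m_car / n_car if n_car else float("nan")
        freq_non = m_non / n_non if n_non else float("nan")
        res = carrier_fisher(
            [[m_car, n_car - m_car], [m_non, n_non - m_non]]
        )
        rows.append(
            {
                "gene": gene,
                "freq_carrier": freq_car,
                "freq_noncarrier": freq_non,
                "diff": freq_car - freq_non,
                "p": res.p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        ps = df["p"].fillna(1.0)
        df["q"] = multipletests(ps, method="fdr_bh")[1]
    return df.sort_values("diff", ascending=False).reset_index(drop=True)
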