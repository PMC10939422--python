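"""Refitting fixed reference signatures to mutation spectra.

The observed count vector v over channels is decomposed against a reference
matrix S (channels x signatures, columns summing to 1) by non-negative least
squares, a = argmin_{a>=0} ||v - S a||_2.  Activities a_k are mutation counts
attributed to signature k; contributions c_k = a_k / sum(a) are the shares
reported throughout.  The fit is deterministic given (v, S); reconstruction
quality is summarized by the cosine similarity between observed and fitted
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

__all__ = [
    "SignatureFit",
    "fit_signatures",
    "fit_spectrum_matrix",
    "cosine_similarity",
    "compare_contributions",
    "ContributionComparison",
]


@dataclass
class SignatureFit:
    group: str
    signatures: tuple[str, ...]
    activities: np.ndarray  # non-negative attributed counts
    reconstruction: np.ndarray
    residual_norm: float
    cosine: float
    degenerate: bool = False  # all-zero input spectrum

    @property
    def contributions(self) -> pd.Series:
        total = self.activities.sum()
        if total == 0:
            return pd.Series(np.nan, index=list(self.signatures))
        return pd.Series(self.activities / total, index=list(self.signatures))

    @property
    def activity_series(self) -> pd.Series:
        return pd.Series(self.activities, index=list(self.signatures))


def cosine_similarity(u: Sequence[float], w: Sequence[float]) -> float:
    """Cosine of the angle between two non-negative spectrum vectors."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise ValueError("vectors must have equal length")
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        return float("nan")
    return float(u @ w / (nu * nw))


def fit_signatures(
    v: Sequence[float] | pd.Series, S: pd.DataFrame, group: str = ""
) -> SignatureFit:
    """NNLS fit of one spectrum column against the signature reference."""
    if isinstance(v, pd.Series):
        v = v.reindex(S.index)
        if v.isna().any():
            raise ValueError("spectrum channels do not match signature reference")
        group = group or str(v.name or "")
        v = v.to_numpy(dtype=float)
    else:
        v = np.asarray(v, dtype=float)
    if v.shape[0] != S.shape[0]:
        raise ValueError(f"spectrum length {v.shape[0]} != reference rows {S.shape[0]}")
    if (v < 0).any():
        raise ValueError("spectrum counts must be non-negative")
    if v.sum() == 0:
        zeros = np.zeros(S.shape[1])
        return SignatureFit(
            group=group,
            signatures=tuple(S.columns),
            activities=zeros,
            reconstruction=zeros.copy(),
            residual_norm=0.0,
            cosine=float("nan"),
            degenerate=True,
        )
    a, rnorm = nnls(S.to_numpy(dtype=float), v)
    recon = S.to_numpy(dtype=float) @ a
    return SignatureFit(
        group=group,
        signatures=tuple(S.columns),
        activities=a,
        reconstruction=recon,
        residual_norm=float(rnorm),
        cosine=cosine_similarity(v, recon),
    )


def fit_spectrum_matrix(M: pd.DataFrame, S: pd.DataFrame) -> dict[str, SignatureFit]:
    """Fit every group column of a spectrum matrix; keys are group labels."""
    return {col: fit_signatures(M[col], S, group=str(col)) for col in M.columns}


@dataclass
class ContributionComparison:
    signature: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    n_groups: int
    fold: float = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.fold = self.mean_a / self.mean_b if self.mean_b else float("nan")


def compare_contributions(
    fits_a: Mapping[str, SignatureFit],
    fits_b: Mapping[str, SignatureFit],
    signature: str,
    paired: bool = True,
) -> ContributionComparison:
    """Two-sided t-test of per-group contributions of one signature.

    With ``paired`` (the default; groups must match) differences within each
    group are tested; otherwise a Welch test on the two arms.  Zero-variance
    inputs yield a flagged non-significant result (p = 1) rather than an
    exception.
    """
    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("need at least two groups in each arm")
    if paired:
        groups = sorted(set(fits_a) & set(fits_b))
        if len(groups) < 2:
            raise ValueError("paired comparison needs >=2 shared group labels")
        a = np.array([fits_a[g].contributions[signature] for g in groups])
        b = np.array([fits_b[g].contributions[signature] for g in groups])
    else:
        a = np.array([f.contributions[signature] for f in fits_a.values()])
        b = np.array([f.contributions[signature] for f in fits_b.values()])
    keep = ~(np.isnan(a) | np.isnan(b)) if paired else slice(None)
    if paired:
        a, b = a[keep], b[keep]
    else:
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n = min(len(a), len(b))
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if paired:
        diff = a - b
        if np.var(diff) == 0:
            return ContributionComparison(signature, mean_a, mean_b, 0.0, 1.0, n, degenerate=True)
        t, p = stats.ttest_rel(a, b)
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            return ContributionComparison(signature, mean_a, mean_b, 0.0, 1.0, n, degenerate=True)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return ContributionComparison(signature, mean_a, mean_b, float(t), float(p), n)
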