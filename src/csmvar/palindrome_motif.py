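"""Inverted-repeat (palindrome) detection and IUPAC motif scanning in
variant context windows.

A context window captures 10 flanking reference bases on each side of a
variant (21 bases for an SNV).  An inverted repeat consists of two arms --
the left arm equal, up to a bounded number of mismatches, to the reverse
complement of the right arm -- separated by a gap (the loop).  Hits are
reported *maximal*: a hit is emitted only when its arms cannot be extended
outward within the window and the arm-length bound without exceeding the
mismatch budget, which avoids double-counting every sub-arm.

Two post-filters follow detection: hits with arm length 4 carrying one
mismatch are discarded, and hits whose stem-plus-loop span does not contain
the variant are discarded.  A window is then classed "exact" if any
surviving hit is mismatch-free, "near" if any carries one mismatch, else
"none".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import ReferenceGenome
from .mutation_context import revcomp

__all__ = [
    "ContextWindow",
    "PalindromeHit",
    "extract_context",
    "find_palindromes",
    "classify_window",
    "palindrome_enrichment",
    "scan_motif",
    "iupac_match_positions",
    "IUPAC_CODES",
    "DEFAULT_FLANK",
]

DEFAULT_FLANK = 10

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class ContextWindow:
    """Reference sequence around one variant, with the variant span marked."""

    key: str
    sequence: str
    variant_start: int  # 0-based offset of the first variant base in sequence
    variant_end: int  # exclusive; == variant_start for a pure insertion point
    truncated: bool = False


def extract_context(v, reference: ReferenceGenome, flank: int = DEFAULT_FLANK) -> ContextWindow:
    """Window of ``flank`` bases either side of the variant's reference span.

    SNVs yield 21-base windows; a deletion of d bases yields d + 2*flank;
    insertions (no reference span) yield 2*flank bases around the insertion
    point.  Windows shortened by a contig edge are flagged truncated.
    """
    var = getattr(v, "variant", v)
    chrom, pos = var.chrom, var.pos
    n = reference.contig_length(chrom)
    if pos < 1 or pos > n:
        raise ValueError(f"position {chrom}:{pos} outside contig of length {n}")
    if var.variant_type == "INS":
        span_start, span_end = pos + 1, pos  # empty reference span after pos
    else:
        span_start, span_end = pos, pos + len(var.ref) - 1
    left = max(1, span_start - flank)
    right = min(n, span_end + flank)
    seq = reference.fetch(chrom, left, right)
    truncated = (span_start - flank < 1) or (span_end + flank > n)
    vstart = span_start - left
    vend = vstart + (span_end - span_start + 1)
    key = f"{chrom}:{pos}:{var.ref}>{var.alt}:{var.sample_id}"
    return ContextWindow(
        key=key, sequence=seq, variant_start=vstart, variant_end=vend, truncated=truncated
    )


@dataclass(frozen=True)
class PalindromeHit:
    arm_start_left: int  # 0-based offset of the left arm in the window
    arm_len: int
    gap_len: int
    mismatches: int
    covers_variant: str = "none"  # stem / loop / none

    @property
    def span(self) -> tuple[int, int]:
        """Half-open stem-plus-loop span within the window."""
        return (self.arm_start_left, self.arm_start_left + 2 * self.arm_len + self.gap_len)


def _covers(hit_start: int, arm: int, gap: int, vstart: int, vend: int) -> str:
    """Where the variant span falls relative to the hit: stem, loop or none."""
    span_start, span_end = hit_start, hit_start + 2 * arm + gap
    vs, ve = vstart, max(vend, vstart + 1)  # insertion point counts as one slot
    if ve <= span_start or vs >= span_end:
        return "none"
    loop_start, loop_end = hit_start + arm, hit_start + arm + gap
    # any overlap with an arm counts as stem
    if vs < loop_start or ve > loop_end:
        return "stem"
    return "loop"


def find_palindromes(
    window: ContextWindow | str,
    min_arm: int = 4,
    max_arm: int = 20,
    max_gap: int = 5,
    max_mismatch: int = 1,
    drop_arm4_mismatch1: bool = True,
    require_covers_variant: bool | None = None,
) -> list[PalindromeHit]:
    """Maximal inverted repeats in a window, after post-filters.

    The finder walks every gap placement and extends arms outward from the
    gap, accumulating mismatches; the unique maximal arm per placement is
    reported.  Post-filters: 4-bp arms with one mismatch are removed when
    ``drop_arm4_mismatch1``; when a variant span is available (a
    ``ContextWindow`` input), hits not covering the variant on stem or loop
    are removed unless ``require_covers_variant`` is False.
    """
    if isinstance(window, ContextWindow):
        seq = window.sequence.upper()
        vspan = (window.variant_start, window.variant_end)
        if require_covers_variant is None:
            require_covers_variant = True
    else:
        seq = window.upper()
        vspan = None
        require_covers_variant = bool(require_covers_variant)
    n = len(seq)
    hits: list[PalindromeHit] = []
    for gap in range(0, max_gap + 1):
        for gap_start in range(0, n - gap + 1):
            room = min(gap_start, n - gap_start - gap)
            limit = min(room, max_arm)
            if limit < min_arm:
                continue
            mism = 0
            arm = 0
            best = None
            while arm < limit:
                left = seq[gap_start - 1 - arm]
                right = seq[gap_start + gap + arm]
                if (left, right) not in _PAIRS:
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                best = (arm, mism)
            if best is None:
                continue
            arm_len, mismatches = best
            if arm_len < min_arm:
                continue
            hit = PalindromeHit(
                arm_start_left=gap_start - arm_len,
                arm_len=arm_len,
                gap_len=gap,
                mismatches=mismatches,
            )
            if vspan is not None:
                hit = PalindromeHit(
                    arm_start_left=hit.arm_start_left,
                    arm_len=hit.arm_len,
                    gap_len=hit.gap_len,
                    mismatches=hit.mismatches,
                    covers_variant=_covers(hit.arm_start_left, arm_len, gap, *vspan),
                )
            hits.append(hit)
    out = []
    for h in hits:
        if drop_arm4_mismatch1 and h.arm_len == 4 and h.mismatches == 1:
            continue
        if require_covers_variant and vspan is not None and h.covers_variant == "none":
            continue
        out.append(h)
    out.sort(key=lambda h: (h.mismatches, -h.arm_len, h.gap_len, h.arm_start_left))
    return out


def classify_window(hits: Sequence[PalindromeHit]) -> str:
    """'exact' if any surviving hit is mismatch-free, 'near' if any has one
    mismatch, else 'none'."""
    if any(h.mismatches == 0 for h in hits):
        return "exact"
    if any(h.mismatches == 1 for h in hits):
        return "near"
    return "none"


@dataclass
class PalindromeEnrichment:
    proportions_a: dict[str, float]
    proportions_b: dict[str, float]
    table: np.ndarray  # 2x2: group x (palindromic, none)
    odds_ratio: float
    p_value: float


def palindrome_enrichment(
    windows_a: Iterable[ContextWindow | str],
    windows_b: Iterable[ContextWindow | str],
    include_truncated: bool = False,
    **finder_kwargs,
) -> PalindromeEnrichment:
    """Per-class proportions and a Fisher exact test of palindromic
    (exact or near) versus none between two window groups."""

    def tally(windows):
        counts = {"exact": 0, "near": 0, "none": 0}
        for w in windows:
            if (
                not include_truncated
                and isinstance(w, ContextWindow)
                and w.truncated
            ):
                continue
            counts[classify_window(find_palindromes(w, **finder_kwargs))] += 1
        return counts

    ca, cb = tally(windows_a), tally(windows_b)
    na, nb = sum(ca.values()), sum(cb.values())
    if na == 0 or nb == 0:
        raise ValueError("both window groups must be non-empty")
    table = np.array(
        [[ca["exact"] + ca["near"], ca["none"]], [cb["exact"] + cb["near"], cb["none"]]]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return PalindromeEnrichment(
        proportions_a={k: v / na for k, v in ca.items()},
        proportions_b={k: v / nb for k, v in cb.items()},
        table=table,
        odds_ratio=float(odds),
        p_value=float(p),
    )


# Degenerate-code alphabet used by the motif catalogs this pipeline consumes.
# Note 'M' denotes C/G in that catalog convention.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
    "D": frozenset("AGT"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "H": frozenset("ACT"),
    "M": frozenset("CG"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "B": frozenset("CGT"),
}


def _validate_pattern(pattern: str) -> None:
    bad = set(pattern.upper()) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"undefined IUPAC codes in pattern: {sorted(bad)}")


def iupac_match_positions(pattern: str, sequence: str) -> list[int]:
    """Start offsets of every sliding-window match of a degenerate pattern."""
    _validate_pattern(pattern)
    pattern = pattern.upper()
    sequence = sequence.upper()
    sets = [IUPAC_CODES[c] for c in pattern]
    out = []
    for i in range(len(sequence) - len(pattern) + 1):
        if all(sequence[i + j] in sets[j] for j in range(len(pattern))):
            out.append(i)
    return out


@dataclass
class MotifScanResult:
    pattern: str
    fraction: float
    n_windows: int
    matched: list[bool]
    by_group: dict[str, float] | None = None


def scan_motif(
    pattern: str,
    windows: Sequence[ContextWindow | str],
    both_strands: bool = False,
    group_labels: Sequence[str] | None = None,
) -> MotifScanResult:
    """Fraction of windows containing at least one match of the pattern.

    Matching is single-strand by default (context windows are strand-anchored
    by their variant); ``both_strands`` also scans the reverse complement.
    """
    seqs = [w.sequence if isinstance(w, ContextWindow) else w for w in windows]
    if not seqs:
        raise ValueError("no windows supplied")
    if all(len(s) < len(pattern) for s in seqs):
        raise ValueError("pattern longer than every window")
    matched = []
    for s in seqs:
        hit = bool(iupac_match_positions(pattern, s))
        if not hit and both_strands:
            hit = bool(iupac_match_positions(pattern, revcomp(s)))
        matched.append(hit)
    result = MotifScanResult(
        pattern=pattern,
        fraction=sum(matched) / len(matched),
        n_windows=len(matched),
        matched=matched,
    )
    if group_labels is not None:
        if len(group_labels) != len(seqs):
            raise ValueError("group_labels length mismatch")
        by: dict[str, list[bool]] = {}
        for label, hit in zip(group_labels, matched):
            by.setdefault(label, []).append(hit)
        result.by_group = {k: sum(v) / len(v) for k, v in by.items()}
    return result


@dataclass
class MotifMatchBreakdown:
    n_matching: int
    n_cg_flanked: int  # matching windows beginning and ending with CG at the match
    n_palindromic: int  # matching windows whose match region holds an exact palindrome


def classify_motif_matches(
    pattern: str, windows: Sequence[ContextWindow | str], **finder_kwargs
) -> MotifMatchBreakdown:
    """Among windows matching the pattern, flag CG-flanked matches and
    sub-count those whose matched region contains an exact inverted repeat."""
    n_match = n_cg = n_pal = 0
    for w in windows:
        seq = w.sequence if isinstance(w, ContextWindow) else w
        positions = iupac_match_positions(pattern, seq)
        if not positions:
            continue
        n_match += 1
        regions = [seq[i : i + len(pattern)] for i in positions]
        if any(r.startswith("CG") and r.endswith("CG") for r in regions):
            n_cg += 1
        finder_kwargs.setdefault("require_covers_variant", False)
        if any(
            any(h.mismatches == 0 for h in find_palindromes(r, **finder_kwargs))
            for r in regions
        ):
            n_pal += 1
    return MotifMatchBreakdown(n_matching=n_match, n_cg_flanked=n_cg, n_palindromic=n_pal)
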