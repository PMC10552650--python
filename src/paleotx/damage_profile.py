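"""Position-wise nucleotide-misincorporation profiling.

Historical RNA carries end-biased chemical damage: cytidine deamination
(C -> U, sequenced as C -> T) and, less consistently, adenosine deamination
(A -> I, sequenced as A -> G), both concentrated toward fragment termini.
This module counts, for each position from either read end, every
substitution type against the number of aligned bases with that reference
base at that position, so rates are re-derivable from stored denominators.

Positions are 1-based from the respective end in original-read orientation.
Each aligned base contributes to the end it is nearer to (the middle base of
odd-length reads goes to the 5' tally), so no base is counted twice.
Indels are excluded: deamination is a substitution process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .formats_io import AlignmentRecord
from .preprocess import classify_length

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
ENDS = ("5p", "3p")


@dataclass
class MismatchProfile:
    """Substitution counts and opportunities per end/position/base pair."""

    length_class: str
    window: int
    n_reads: int = 0
    # [end, position, ref_base] aligned-base opportunities
    opportunities: np.ndarray = field(default=None)  # type: ignore[assignment]
    # [end, position, ref_base, read_base] mismatch counts
    mismatch_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.opportunities is None:
            self.opportunities = np.zeros((2, self.window, 4), dtype=np.int64)
        if self.mismatch_counts is None:
            self.mismatch_counts = np.zeros((2, self.window, 4, 4), dtype=np.int64)

    @property
    def is_empty(self) -> bool:
        return self.n_reads == 0

    def rate(self, end: str, position: int, substitution: tuple[str, str]) -> float:
        """Frequency of ref->read substitutions at a 1-based end position."""
        e = ENDS.index(end)
        ref, alt = (BASE_INDEX[b] for b in substitution)
        n = self.opportunities[e, position - 1, ref]
        if n == 0:
            return float("nan")
        return self.mismatch_counts[e, position - 1, ref, alt] / n

    def counts(self, end: str, position: int, substitution: tuple[str, str]) -> tuple[int, int]:
        e = ENDS.index(end)
        ref, alt = (BASE_INDEX[b] for b in substitution)
        return (
            int(self.mismatch_counts[e, position - 1, ref, alt]),
            int(self.opportunities[e, position - 1, ref]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: end, position, sub, mismatches, opportunities, rate."""
        rows = []
        for e, end in enumerate(ENDS):
            for pos in range(self.window):
                for r, ref in enumerate(BASES):
                    opp = int(self.opportunities[e, pos, r])
                    for a, alt in enumerate(BASES):
                        if r == a:
                            continue
                        mm = int(self.mismatch_counts[e, pos, r, a])
                        rows.append(
                            {
                                "end": end,
                                "position": pos + 1,
                                "sub": f"{ref}>{alt}",
                                "mismatches": mm,
                                "opportunities": opp,
                                "rate": mm / opp if opp else float("nan"),
                            }
                        )
        return pd.DataFrame(rows)


def _in_class(read_length: int, length_class: str) -> bool:
    if length_class == "all":
        return True
    return classify_length(read_length) == length_class


def misincorporation_profile(
    alignments: Iterable[AlignmentRecord],
    length_class: str = "all",
    K: int = 10,
) -> MismatchProfile:
    """Profile all 12 substitution rates over the first K positions per end.

    Requires records carrying their read sequence and mismatch calls (the
    reference base at a matching position is then the read base itself, and
    at a mismatching position the recorded reference base).  Records with
    weights (``count``) contribute with their multiplicity.
    """
    profile = MismatchProfile(length_class=length_class, window=K)
    for rec in alignments:
        if not _in_class(rec.read_length, length_class):
            continue
        if rec.sequence is None:
            raise ValueError(f"record {rec.read_id} has no sequence; cannot profile")
        L = rec.read_length
        mm = {pos: (ref, alt) for pos, ref, alt in rec.mismatches}
        positions: Sequence[int] = (
            rec.aligned_positions if rec.aligned_positions is not None else range(L)
        )
        w = rec.count
        for p in positions:
            d5 = p + 1
            d3 = L - p
            if d5 <= d3:
                end, pos = 0, d5
            else:
                end, pos = 1, d3
            if pos > K:
                continue
            if p in mm:
                ref, alt = mm[p]
            else:
                ref = alt = rec.sequence[p]
            if ref not in BASE_INDEX or alt not in BASE_INDEX:
                continue
            r = BASE_INDEX[ref]
            profile.opportunities[end, pos - 1, r] += w
            if ref != alt:
                profile.mismatch_counts[end, pos - 1, r, BASE_INDEX[alt]] += w
        profile.n_reads += w
    return profile


def compare_profiles(
    a: MismatchProfile,
    b: MismatchProfile,
    substitution: tuple[str, str] = ("C", "T"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position rate differences (a - b) with Wilson-based 95% CIs.

    The interval for the difference combines the two Wilson score intervals
    (Newcombe's method).  Positions where either profile has a zero
    denominator are reported with ``defined = False``; positions whose CI
    excludes zero are flagged ``significant``.
    """
    if a.window != b.window:
        raise ValueError(f"window mismatch: {a.window} vs {b.window}")
    rows = []
    for end in ENDS:
        for pos in range(1, a.window + 1):
            ma, na = a.counts(end, pos, substitution)
            mb, nb = b.counts(end, pos, substitution)
            defined = na > 0 and nb > 0
            if defined:
                pa, pb = ma / na, mb / nb
                la, ua = proportion_confint(ma, na, alpha=alpha, method="wilson")
                lb, ub = proportion_confint(mb, nb, alpha=alpha, method="wilson")
                diff = pa - pb
                lo = diff - np.sqrt((pa - la) ** 2 + (ub - pb) ** 2)
                hi = diff + np.sqrt((ua - pa) ** 2 + (pb - lb) ** 2)
                sig = lo > 0 or hi < 0
            else:
                diff = lo = hi = float("nan")
                sig = False
            rows.append(
                {
                    "end": end,
                    "position": pos,
                    "rate_a": ma / na if na else float("nan"),
                    "rate_b": mb / nb if nb else float("nan"),
                    "difference": diff,
                    "ci_low": lo,
                    "ci_high": hi,
                    "defined": defined,
                    "significant": sig,
                }
            )
    return pd.DataFrame(rows)


__all__ = [
    "MismatchProfile",
    "misincorporation_profile",
    "compare_profiles",
    "BASES",
    "ENDS",
]
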