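"""Sequence QC for degraded small-RNA libraries.

Implements the preprocessing stages applied to historical-specimen small-RNA
reads: 3' adapter trimming with an error tolerance, extraction of the 4+4-nt
UMI scheme, collapsing of identical PCR duplicates, directional UMI
deduplication of mapped reads, and read-length classing.

Adapter matching is suffix-anchored semi-global alignment with unit-cost
edits: the leftmost read position where the adapter (or an adapter prefix of
at least 3 nt at the read end) matches within ``floor(max_error_rate x
matched adapter length)`` edits wins.  Trimmed reads carry an 8-mer UMI (4 nt
from each insert end); reads without a detectable adapter keep a 4-mer UMI
from their 5' end and lose their last 4 nt.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Hashable, Iterable

import edlib

from .formats_io import ConfigurationError, ReadRecord

MIN_ADAPTER_MATCH = 3  # shortest adapter prefix accepted at the read end


@dataclass(frozen=True)
class TrimConfig:
    adapter: str
    max_error_rate: float = 0.10
    min_length_after_trim: int = 18
    umi5_len: int = 4
    umi3_len: int = 4

    def __post_init__(self) -> None:
        if len(self.adapter) < MIN_ADAPTER_MATCH:
            raise ConfigurationError("adapter must be at least 3 nt")
        if not 0 <= self.max_error_rate < 0.5:
            raise ConfigurationError("max_error_rate must be in [0, 0.5)")
        if self.min_length_after_trim < 1:
            raise ConfigurationError("min_length_after_trim must be >= 1")


@dataclass
class UmiGroup:
    """Reads sharing a mapping locus, keyed by UMI with their counts."""

    locus: tuple[str, int, str]  # (reference, leftmost aligned base, strand)
    members: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.members.values()):
            raise ValueError("UMI counts must be >= 1")


def find_adapter(sequence: str, cfg: TrimConfig) -> int | None:
    """Best suffix-anchored adapter start, or None if no hit.

    Candidate start ``i`` compares ``sequence[i:i+m]`` against the adapter
    prefix of length ``m = min(len(adapter), len(sequence)-i)`` under
    Levenshtein distance; a candidate qualifies when its distance is at most
    ``floor(max_error_rate * m)``.  Among qualifying candidates the fewest
    edits win, ties breaking to the leftmost position (a pure leftmost rule
    would systematically shift one base left, since an offset window is
    always reachable with one insertion plus one deletion).
    """
    n, adapter = len(sequence), cfg.adapter
    best: tuple[int, int] | None = None  # (distance, position)
    for i in range(0, n - MIN_ADAPTER_MATCH + 1):
        m = min(len(adapter), n - i)
        allowed = math.floor(cfg.max_error_rate * m)
        d = edlib.align(adapter[:m], sequence[i : i + m], task="distance")["editDistance"]
        if d <= allowed and (best is None or (d, i) < best):
            best = (d, i)
    return None if best is None else best[1]


def trim_adapter(read: ReadRecord, cfg: TrimConfig) -> ReadRecord:
    """Locate and remove the 3' adapter, classing the read by outcome."""
    if not read.sequence:
        raise ValueError("read has empty sequence")
    hit = find_adapter(read.sequence, cfg)
    if hit is None:
        return replace(read, trim_status="untrimmed")
    payload_len = hit - cfg.umi5_len - cfg.umi3_len
    if payload_len < cfg.min_length_after_trim:
        return replace(
            read,
            sequence=read.sequence[:hit],
            quality=read.quality[:hit] if read.quality else None,
            trim_status="discarded",
            discard_reason="too_short_after_trim",
        )
    return replace(
        read,
        sequence=read.sequence[:hit],
        quality=read.quality[:hit] if read.quality else None,
        trim_status="trimmed",
    )


def extract_umi(read: ReadRecord, cfg: TrimConfig) -> ReadRecord:
    """Move the UMI bases out of the insert into ``read.umi``.

    Trimmed inserts yield an 8-mer UMI (first 4 + last 4 nt joined);
    untrimmed reads yield a 4-mer UMI from their first 4 nt while their last
    4 nt are removed without joining the UMI.
    """
    if read.trim_status not in ("trimmed", "untrimmed"):
        raise ValueError("extract_umi requires a trimmed or untrimmed read")
    u5, u3 = cfg.umi5_len, cfg.umi3_len
    seq = read.sequence
    if len(seq) < u5 + u3 + 1:
        return replace(
            read, trim_status="discarded", discard_reason="too_short_for_umi"
        )
    if read.trim_status == "trimmed":
        umi = seq[:u5] + seq[-u3:] if u3 else seq[:u5]
    else:
        umi = seq[:u5]
    return replace(
        read,
        sequence=seq[u5 : len(seq) - u3],
        quality=read.quality[u5 : len(seq) - u3] if read.quality else None,
        umi=umi,
    )


def collapse_pcr_duplicates(
    reads: Iterable[ReadRecord],
) -> tuple[list[ReadRecord], float]:
    """Collapse reads identical in (payload, UMI); return duplication rate.

    The duplication rate is input reads / unique (payload, UMI) pairs.
    Discarded reads are ignored.
    """
    seen: dict[tuple[str, str], ReadRecord] = {}
    n_in = 0
    for read in reads:
        if read.trim_status == "discarded":
            continue
        n_in += read.count
        key = (read.sequence, read.umi)
        if key in seen:
            seen[key].count += read.count
        else:
            seen[key] = replace(read)
    unique = list(seen.values())
    rate = n_in / len(unique) if unique else float("nan")
    return unique, rate


def _hamming1(a: str, b: str) -> bool:
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def dedup_umi_directional(group: UmiGroup) -> set[str]:
    """Directional UMI clustering: one representative per error network.

    Builds a directed graph with an edge a->b iff Hamming(a, b) == 1 and
    count(a) >= 2 * count(b) - 1, then collapses every node reachable from a
    yet-unclaimed highest-count node (ties broken by count descending, then
    UMI lexicographically) onto that node.
    """
    if not group.members:
        raise ValueError("empty UMI group")
    umis = sorted(group.members)
    if len({len(u) for u in umis}) > 1:
        raise ValueError("UMIs of unequal length in one group")
    counts = group.members
    edges: dict[str, list[str]] = {u: [] for u in umis}
    for a in umis:
        for b in umis:
            if a != b and _hamming1(a, b) and counts[a] >= 2 * counts[b] - 1:
                edges[a].append(b)
    order = sorted(umis, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    representatives: set[str] = set()
    for root in order:
        if root in assigned:
            continue
        representatives.add(root)
        stack = [root]
        assigned.add(root)
        while stack:
            node = stack.pop()
            for nxt in edges[node]:
                if nxt not in assigned:
                    assigned.add(nxt)
                    stack.append(nxt)
    return representatives


def group_umis_by_locus(
    items: Iterable[tuple[tuple[str, int, str], str]],
) -> list[UmiGroup]:
    """Collect (locus, umi) observations into UmiGroups."""
    acc: dict[tuple[str, int, str], Counter] = {}
    for locus, umi in items:
        acc.setdefault(locus, Counter())[umi] += 1
    return [UmiGroup(locus, dict(c)) for locus, c in sorted(acc.items())]


LENGTH_CLASSES: tuple[tuple[str, int, int], ...] = (
    ("18-25", 18, 25),
    ("26-30", 26, 30),
    (">30", 31, 10**9),
)


def classify_length(length: int) -> str | None:
    for name, lo, hi in LENGTH_CLASSES:
        if lo <= length <= hi:
            return name
    return None


@dataclass
class LengthHistogram:
    per_length: Counter
    classes: dict[str, int]
    count_42: int

    @property
    def total(self) -> int:
        return sum(self.classes.values())


def length_histogram(reads: Iterable[ReadRecord | Hashable]) -> LengthHistogram:
    """Counts per length and per class {18-25, 26-30, >30}, plus 42-nt count.

    Accepts ReadRecords (payload lengths weighted by ``count``) or bare ints.
    """
    per_length: Counter = Counter()
    for item in reads:
        if isinstance(item, ReadRecord):
            per_length[len(item.sequence)] += item.count
        else:
            per_length[int(item)] += 1
    classes = {name: 0 for name, _, _ in LENGTH_CLASSES}
    for length, n in per_length.items():
        cls = classify_length(length)
        if cls is not None:
            classes[cls] += n
    return LengthHistogram(per_length, classes, per_length.get(42, 0))


def preprocess_reads(
    reads: Iterable[ReadRecord], cfg: TrimConfig
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Full trim + UMI stage: returns (trimmed, untrimmed, discarded)."""
    trimmed: list[ReadRecord] = []
    untrimmed: list[ReadRecord] = []
    discarded: list[ReadRecord] = []
    for read in reads:
        read = trim_adapter(read, cfg)
        if read.trim_status != "discarded":
            read = extract_umi(read, cfg)
        if read.trim_status == "discarded":
            discarded.append(read)
        elif read.trim_status == "trimmed":
            trimmed.append(read)
        else:
            untrimmed.append(read)
    return trimmed, untrimmed, discarded


__all__ = [
    "TrimConfig",
    "UmiGroup",
    "find_adapter",
    "trim_adapter",
    "extract_umi",
    "collapse_pcr_duplicates",
    "dedup_umi_directional",
    "group_umis_by_locus",
    "length_histogram",
    "LengthHistogram",
    "classify_length",
    "preprocess_reads",
    "LENGTH_CLASSES",
]
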