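"""Genome-wide window aggregation, hotspot calling, and the DNA-likeness
heuristic for intergenic reads.

Degraded-RNA libraries concentrate their reads into expression hotspots,
whereas genomic DNA sequenced from the same specimen spreads evenly.  This
module tiles each scaffold into fixed, non-overlapping windows (250 kb by
default), counts each read once in the window containing its leftmost
aligned base, and derives per-window breadth and depth plus genome-wide
summaries.  Hotspots are the top-k windows by read count; sharing between
two libraries is the size of the intersection of their top-k sets.

The DNA-likeness heuristic flags windows whose RNA coverage pattern is
within a twofold band of a depth-normalized DNA track in both breadth and
depth.  The DNA track is rescaled to the read total of the population being
examined (by default the intergenic reads when they are supplied, otherwise
the whole RNA library); breadth is rescaled through the uniform-coverage
relation b' = 1 - (1 - b)^scale, the Lander-Waterman transform of a
depth rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .formats_io import AlignmentRecord

DEFAULT_WINDOW = 250_000


@dataclass
class WindowTrack:
    window_size: int
    windows: pd.DataFrame  # chrom, start, end, reads, breadth, depth
    genome_breadth: float
    genome_depth: float
    total_reads: int
    genome_lengths: dict[str, int]
    unplaced_reads: int = 0


def window_counts(
    alignments: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    window_size: int = DEFAULT_WINDOW,
) -> WindowTrack:
    """Tile scaffolds into fixed windows and aggregate read counts/coverage.

    Each read is counted once, in the window containing its leftmost aligned
    base (reads straddling a boundary stay in their start window).  Reads on
    scaffolds absent from ``genome_lengths`` are tallied as unplaced with a
    warning.
    """
    cov = {c: np.zeros(L, dtype=np.int32) for c, L in genome_lengths.items()}
    counts: dict[str, np.ndarray] = {
        c: np.zeros(-(-L // window_size), dtype=np.int64)
        for c, L in genome_lengths.items()
    }
    total = 0
    unplaced = 0
    for rec in alignments:
        if rec.reference not in cov:
            unplaced += rec.count
            continue
        total += rec.count
        counts[rec.reference][rec.start // window_size] += rec.count
        arr = cov[rec.reference]
        for s, e in rec.blocks:
            arr[s:e] += rec.count
    if unplaced:
        warnings.warn(f"{unplaced} reads on unknown scaffolds counted as unplaced")

    rows = []
    for chrom, L in genome_lengths.items():
        arr = cov[chrom]
        for w in range(len(counts[chrom])):
            s = w * window_size
            e = min(s + window_size, L)
            seg = arr[s:e]
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "reads": int(counts[chrom][w]),
                    "breadth": float(np.count_nonzero(seg)) / (e - s),
                    "depth": float(seg.sum()) / (e - s),
                }
            )
    windows = pd.DataFrame(rows)
    genome_size = sum(genome_lengths.values())
    covered = sum(int(np.count_nonzero(a)) for a in cov.values())
    depth_total = sum(int(a.sum(dtype=np.int64)) for a in cov.values())
    return WindowTrack(
        window_size=window_size,
        windows=windows,
        genome_breadth=covered / genome_size,
        genome_depth=depth_total / genome_size,
        total_reads=total,
        genome_lengths=dict(genome_lengths),
        unplaced_reads=unplaced,
    )


def top_hotspots(track: WindowTrack, k: int = 20) -> pd.DataFrame:
    """Top-k windows ranked by read count, ties broken by (chrom, start)."""
    if k > len(track.windows):
        raise ValueError(f"k={k} exceeds {len(track.windows)} windows")
    ranked = track.windows.sort_values(
        ["reads", "chrom", "start"], ascending=[False, True, True]
    )
    return ranked.head(k).reset_index(drop=True)


def shared_hotspots(a: WindowTrack, b: WindowTrack, k: int = 20) -> tuple[int, float]:
    """Overlap of the two top-k hotspot sets: (count, fraction of k)."""
    if a.window_size != b.window_size or a.genome_lengths != b.genome_lengths:
        raise ValueError("tracks must tile the same genome")
    ka = {(r.chrom, r.start) for r in top_hotspots(a, k).itertuples()}
    kb = {(r.chrom, r.start) for r in top_hotspots(b, k).itertuples()}
    n = len(ka & kb)
    return n, n / k


@dataclass
class DnaLikeResult:
    flagged: pd.DataFrame  # window table with a dna_like column
    n_flagged: int
    n_comparable: int
    intergenic_reads_in_flagged: int
    intergenic_reads_total: int
    fraction_of_intergenic: float
    fraction_of_library: float
    scale: float


def flag_dna_like_windows(
    rna: WindowTrack,
    dna: WindowTrack,
    intergenic_alignments: Iterable[AlignmentRecord] | None = None,
    fold: float = 2.0,
    require_both: bool = True,
    scale: float | None = None,
) -> DnaLikeResult:
    """Flag windows whose RNA coverage resembles depth-normalized DNA.

    A window is DNA-like iff its breadth and depth both (or either, with
    ``require_both=False``) lie within ``[1/fold, fold]`` of the rescaled DNA
    window values.  Windows with zero DNA coverage are unflaggable and
    excluded.  When ``intergenic_alignments`` are given, the comparison track
    is built from those reads alone (the population whose DNA-likeness is in
    question -- genic windows would otherwise be masked by genuine
    expression), the scale factor defaults to their read total over the DNA
    total, and the fraction of intergenic reads inside flagged windows is
    reported both relative to the intergenic population and to the whole RNA
    library (a per-library DNA-contamination estimate).
    """
    if rna.window_size != dna.window_size or rna.genome_lengths != dna.genome_lengths:
        raise ValueError("tracks must tile the same genome")
    intergenic = list(intergenic_alignments) if intergenic_alignments is not None else None
    if scale is None:
        numerator = (
            sum(r.count for r in intergenic) if intergenic is not None else rna.total_reads
        )
        if dna.total_reads == 0:
            raise ValueError("empty DNA background")
        scale = numerator / dna.total_reads

    if intergenic is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            compare = window_counts(intergenic, rna.genome_lengths, rna.window_size)
    else:
        compare = rna
    table = compare.windows.copy()
    dna_depth = dna.windows["depth"].to_numpy() * scale
    dna_breadth = 1.0 - np.power(
        np.clip(1.0 - dna.windows["breadth"].to_numpy(), 1e-12, 1.0), scale
    )
    comparable = dna.windows["depth"].to_numpy() > 0

    def in_band(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ref > 0, x / ref, np.inf)
        return (ratio >= 1.0 / fold) & (ratio <= fold)

    depth_ok = in_band(table["depth"].to_numpy(), dna_depth)
    breadth_ok = in_band(table["breadth"].to_numpy(), dna_breadth)
    flagged = (depth_ok & breadth_ok) if require_both else (depth_ok | breadth_ok)
    flagged &= comparable
    table["dna_like"] = flagged

    in_flagged = total_intergenic = 0
    if intergenic is not None:
        keys = {
            (r.chrom, r.start)
            for r in table[table["dna_like"]].itertuples()
        }
        for rec in intergenic:
            total_intergenic += rec.count
            wstart = (rec.start // rna.window_size) * rna.window_size
            if (rec.reference, wstart) in keys:
                in_flagged += rec.count
    return DnaLikeResult(
        flagged=table,
        n_flagged=int(flagged.sum()),
        n_comparable=int(comparable.sum()),
        intergenic_reads_in_flagged=in_flagged,
        intergenic_reads_total=total_intergenic,
        fraction_of_intergenic=(in_flagged / total_intergenic) if total_intergenic else float("nan"),
        fraction_of_library=(in_flagged / rna.total_reads) if rna.total_reads else float("nan"),
        scale=scale,
    )


def write_bed(track: WindowTrack, path) -> None:
    """Window track as BED with a read-count column."""
    track.windows.to_csv(
        path,
        sep="\t",
        header=False,
        index=False,
        columns=["chrom", "start", "end", "reads"],
    )


__all__ = [
    "WindowTrack",
    "DnaLikeResult",
    "window_counts",
    "top_hotspots",
    "shared_hotspots",
    "flag_dna_like_windows",
    "write_bed",
    "DEFAULT_WINDOW",
]
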