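"""Taxonomic tallies of ultrashort reads mapped to a multi-species reference.

For reads too short for k-mer classifiers (18-30 nt), taxonomic origin is
estimated by end-to-end alignment against a concatenated multi-species
reference, keeping only uniquely placed reads (MAPQ >= 1 as the uniqueness
proxy) and tallying them by the taxon of their reference sequence.
Percentages are computed over uniquely assigned reads only; ambiguous and
unassigned reads are reported alongside so that the partition
unique + ambiguous + unassigned always equals the in-range input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import AlignmentRecord


@dataclass
class TaxonTally:
    unique_reads: dict[str, int]
    ambiguous_discarded: int
    unassigned: int
    n_input: int  # reads within the length window
    n_length_excluded: int
    min_taxon_reads: int | None = None

    @property
    def percents(self) -> dict[str, float]:
        counts = self.filtered_counts
        total = sum(counts.values())
        if total == 0:
            return {}
        return {t: 100.0 * n / total for t, n in counts.items()}

    @property
    def filtered_counts(self) -> dict[str, int]:
        if self.min_taxon_reads is None:
            return dict(self.unique_reads)
        return {
            t: n for t, n in self.unique_reads.items() if n >= self.min_taxon_reads
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percents
        rows = [
            {"taxon": t, "unique_reads": self.unique_reads[t], "percent": pct.get(t, 0.0)}
            for t in sorted(self.unique_reads, key=lambda t: -self.unique_reads[t])
        ]
        return pd.DataFrame(rows)


def unique_assignment_tally(
    alignments: Iterable[AlignmentRecord],
    seqid_to_taxon: Mapping[str, str],
    min_len: int = 18,
    max_len: int = 30,
    min_mapq: int = 1,
    min_taxon_reads: int | None = None,
) -> TaxonTally:
    """Tally uniquely mapping reads in the [min_len, max_len] window by taxon.

    Reads below ``min_mapq`` are counted as ambiguous; reads whose reference
    id is absent from the seqid -> taxon mapping are counted unassigned with
    a warning.  ``min_taxon_reads`` optionally suppresses low-support taxa
    from the percentage report (support-count filter for report parity).
    """
    unique: dict[str, int] = {}
    ambiguous = unassigned = n_input = n_excluded = 0
    missing_refs: set[str] = set()
    for rec in alignments:
        if not min_len <= rec.read_length <= max_len:
            n_excluded += rec.count
            continue
        n_input += rec.count
        if rec.mapq < min_mapq:
            ambiguous += rec.count
            continue
        taxon = seqid_to_taxon.get(rec.reference)
        if taxon is None:
            unassigned += rec.count
            missing_refs.add(rec.reference)
            continue
        unique[taxon] = unique.get(taxon, 0) + rec.count
    if missing_refs:
        warnings.warn(
            f"{len(missing_refs)} reference ids absent from the taxon map: "
            + ", ".join(sorted(missing_refs)[:5])
        )
    return TaxonTally(
        unique_reads=unique,
        ambiguous_discarded=ambiguous,
        unassigned=unassigned,
        n_input=n_input,
        n_length_excluded=n_excluded,
        min_taxon_reads=min_taxon_reads,
    )


def read_seqid_map(path) -> dict[str, str]:
    """Two-column TSV: reference sequence id -> taxon label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seqid", "taxon"], dtype=str)
    return dict(zip(df["seqid"], df["taxon"]))


def write_seqid_map(mapping: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"seqid": list(mapping), "taxon": [mapping[k] for k in mapping]}
    ).to_csv(path, sep="\t", header=False, index=False)


__all__ = [
    "TaxonTally",
    "unique_assignment_tally",
    "read_seqid_map",
    "write_seqid_map",
]
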