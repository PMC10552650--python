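"""Readers/writers for the standard formats the pipeline touches.

Normalizes FASTQ reads, SAM alignments, and GFF3 gene annotations into the
package's domain types.  Conventions used throughout the package:

* all genomic intervals are 0-based, half-open; GFF3's 1-based closed
  coordinates are converted on read;
* mismatch positions are stored in original-read orientation (5'->3' of the
  sequenced molecule), so that end-biased chemical damage remains anchored to
  the molecule's termini regardless of mapping strand;
* soft-clipped bases are excluded from alignment blocks and from mismatch
  accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BIOTYPES = frozenset(
    {"protein_coding", "rRNA", "tRNA", "snRNA", "snoRNA", "lncRNA", "miRNA", "other"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigurationError(ValueError):
    """Raised when an operation is invoked without the inputs it needs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReadRecord:
    """A sequenced small-RNA read.

    ``sequence`` holds the current payload: the raw read before trimming, the
    insert after adapter removal, or the UMI-stripped payload, depending on
    pipeline stage.  ``umi`` is empty, 4 nt (untrimmed reads) or 8 nt
    (trimmed reads, 4 nt from each end joined).  ``count`` carries the
    multiplicity after PCR-duplicate collapsing.
    """

    read_id: str
    sequence: str
    quality: list[int] | None = None
    umi: str = ""
    trim_status: str | None = None  # trimmed | untrimmed | discarded | None
    discard_reason: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.trim_status == "discarded" and not self.discard_reason:
            raise ValueError("discarded reads must carry a discard reason")
        if len(self.umi) not in (0, 4, 8):
            raise ValueError(f"UMI length must be 0, 4 or 8, got {len(self.umi)}")


@dataclass
class AlignmentRecord:
    """One aligned read against a reference.

    ``blocks`` are sorted, non-overlapping, 0-based half-open reference
    intervals (CIGAR M/=/X ops; splices and deletions split blocks).
    ``mismatches`` are ``(read_pos, ref_base, read_base)`` triples with
    ``read_pos`` counted from the original 5' end of the sequenced molecule.
    ``sequence`` is the read in original orientation; ``aligned_positions``
    lists the original-orientation read positions that are aligned to the
    reference (soft clips and insertions excluded).  When
    ``aligned_positions`` is None every position of the read is aligned.
    """

    read_id: str
    reference: str
    start: int
    blocks: tuple[tuple[int, int], ...]
    strand: str
    mapq: int
    read_length: int
    mismatches: tuple[tuple[int, str, str], ...] = ()
    sequence: str | None = None
    count: int = 1
    aligned_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for (s0, e0), (s1, e1) in zip(self.blocks, self.blocks[1:]):
            if s1 < e0:
                raise ValueError("alignment blocks must be sorted and non-overlapping")
        for pos, _, _ in self.mismatches:
            if not 0 <= pos < self.read_length:
                raise ValueError("mismatch position outside read")

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def positions(self) -> Iterator[int]:
        """Reference positions covered by the alignment."""
        for s, e in self.blocks:
            yield from range(s, e)


@dataclass
class GeneModel:
    """A gene reduced to its longest transcript isoform."""

    gene_id: str
    biotype: str
    chrom: str
    span: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    strand: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        s, e = self.span
        for (a, b) in self.exons:
            if not (s <= a < b <= e):
                raise ValueError(f"exon ({a},{b}) outside gene span {self.span}")
        for (a0, b0), (a1, b1) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons of the retained isoform."""
        return tuple(
            (b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]) if a1 > b0
        )

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def transcript_length(self) -> int:
        return self.exonic_length


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a 4-line FASTQ file, preserving order."""
    n = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ParseError(
                        f"sequence/quality length mismatch near line {4 * n + 1}"
                    )
                yield ReadRecord(
                    read_id=title.split()[0],
                    sequence=seq.upper(),
                    quality=[ord(c) - 33 for c in qual],
                )
                n += 1
        except ValueError as exc:  # Biopython signals malformed records
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"malformed FASTQ record near line {4 * n + 1}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            qual = rec.quality or [40] * len(rec.sequence)
            out.write(
                f"@{rec.read_id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _blocks_from_cigar(cigartuples, start: int) -> tuple[tuple[int, int], ...]:
    """Reference blocks from CIGAR M/=/X ops; D and N split/advance."""
    blocks: list[tuple[int, int]] = []
    ref = start
    open_start = None
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X consume both
            if open_start is None:
                open_start = ref
            ref += length
        elif op in (2, 3):  # D, N consume reference only
            if open_start is not None:
                blocks.append((open_start, ref))
                open_start = None
            ref += length
        # I, S, H, P consume no reference
    if open_start is not None:
        blocks.append((open_start, ref))
    return tuple(blocks)


def _checked(sam) -> Iterator[pysam.AlignedSegment]:
    """Re-raise htslib parse failures (e.g. CIGAR/sequence disagreement)."""
    it = iter(sam)
    while True:
        try:
            yield next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as exc:
            raise ParseError(f"malformed SAM record: {exc}") from exc


def parse_alignments(
    path: str | Path,
    genome: Mapping[str, str] | None = None,
    with_mismatches: bool = True,
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM file.

    Mismatches are recovered from the MD tag when present, otherwise by
    comparing the read against ``genome``.  Read positions of mismatches are
    re-oriented to the original 5' end for reverse-strand alignments.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        segments = _checked(sam)
        for seg in segments:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            qseq = seg.query_sequence.upper()
            qlen = len(qseq)
            cig_qlen = sum(
                length for op, length in seg.cigartuples if op in (0, 1, 4, 7, 8)
            )
            if cig_qlen != qlen:
                raise ParseError(
                    f"CIGAR consumes {cig_qlen} query bases but sequence is "
                    f"{qlen} nt for read {seg.query_name}"
                )
            blocks = _blocks_from_cigar(seg.cigartuples, seg.reference_start)
            mismatches: list[tuple[int, str, str]] = []
            aligned: list[int] = []
            if with_mismatches:
                if seg.has_tag("MD"):
                    pairs = seg.get_aligned_pairs(matches_only=True, with_seq=True)
                elif genome is not None:
                    ref_seq = genome[seg.reference_name]
                    pairs = [
                        (q, r, ref_seq[r])
                        for q, r in seg.get_aligned_pairs(matches_only=True)
                    ]
                else:
                    raise ConfigurationError(
                        "mismatch recovery requires an MD tag or a genome FASTA"
                    )
                for qpos, _rpos, ref_base in pairs:
                    ref_base = ref_base.upper()
                    read_base = qseq[qpos]
                    if seg.is_reverse:
                        opos = qlen - 1 - qpos
                        ref_base = ref_base.translate(COMPLEMENT)
                        read_base = read_base.translate(COMPLEMENT)
                    else:
                        opos = qpos
                    aligned.append(opos)
                    if ref_base != read_base and "N" not in (ref_base, read_base):
                        mismatches.append((opos, ref_base, read_base))
            sequence = revcomp(qseq) if seg.is_reverse else qseq
            yield AlignmentRecord(
                read_id=seg.query_name,
                reference=seg.reference_name,
                start=seg.reference_start,
                blocks=blocks,
                strand="-" if seg.is_reverse else "+",
                mapq=seg.mapping_quality,
                read_length=qlen,
                mismatches=tuple(sorted(mismatches)),
                sequence=sequence,
                aligned_positions=tuple(sorted(aligned)) if with_mismatches else None,
            )


def _md_tag(rec: AlignmentRecord) -> str:
    """MD string for an indel-free record (runs of matches + mismatch bases)."""
    if rec.sequence is None:
        raise ValueError("MD emission requires the read sequence")
    # walk aligned read positions in reference orientation
    mm = {pos: ref for pos, ref, _ in rec.mismatches}
    order = range(rec.read_length)
    if rec.strand == "-":
        order = reversed(order)
    parts: list[str] = []
    run = 0
    for pos in order:
        if pos in mm:
            ref_base = mm[pos]
            if rec.strand == "-":
                ref_base = ref_base.translate(COMPLEMENT)
            parts.append(str(run))
            parts.append(ref_base)
            run = 0
        else:
            run += 1
    parts.append(str(run))
    return "".join(parts)


def write_sam(
    records: Iterable[AlignmentRecord],
    genome_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Emit records as SAM text with an MD tag so mismatches round-trip.

    Only indel-free alignments (blocks separated by N skips) are written,
    which covers everything this package produces.
    """
    refs = list(genome_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": genome_lengths[name]} for name in refs],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            if rec.sequence is None:
                raise ValueError("SAM emission requires read sequences")
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.reference_id = refs.index(rec.reference)
            seg.reference_start = rec.start
            seg.mapping_quality = rec.mapq
            seg.flag = 16 if rec.strand == "-" else 0
            seq = rec.sequence if rec.strand == "+" else revcomp(rec.sequence)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            cigar: list[tuple[int, int]] = []
            prev_end = None
            for s, e in rec.blocks:
                if prev_end is not None:
                    cigar.append((3, s - prev_end))  # N skip
                cigar.append((0, e - s))
                prev_end = e
            seg.cigartuples = cigar
            seg.set_tag("MD", _md_tag(rec))
            seg.set_tag("NM", len(rec.mismatches))
            out.write(seg)


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------


def _biotype_of(feature) -> str:
    for key in ("biotype", "gene_biotype", "gene_type"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return "other"


def parse_annotation(path: str | Path) -> dict[str, GeneModel]:
    """Load gene models from GFF3, keeping the longest isoform per gene.

    The isoform with the largest summed exon length wins; ties break to the
    lexicographically smallest transcript id.  Unknown biotypes map to
    ``other`` with a warning.  Coordinates are converted to 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # every exon must have a transcript parent
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            raise ParseError(f"exon at {exon.seqid}:{exon.start} has no parent transcript")

    genes: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        biotype = _biotype_of(gene)
        if biotype not in VALID_BIOTYPES:
            warnings.warn(
                f"gene {gene.id}: unknown biotype {biotype!r} mapped to 'other'",
                stacklevel=2,
            )
            biotype = "other"
        best: tuple[int, str, tuple[tuple[int, int], ...]] | None = None
        for tx in db.children(gene, level=1):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                continue
            length = sum(e - s for s, e in exons)
            key = (-length, tx.id)
            if best is None or key < (-best[0], best[1]):
                best = (length, tx.id, tuple(exons))
        if best is None:
            continue
        genes[gene.id] = GeneModel(
            gene_id=gene.id,
            biotype=biotype,
            chrom=gene.seqid,
            span=(gene.start - 1, gene.end),
            exons=best[2],
            strand=gene.strand if gene.strand in "+-" else "+",
            transcript_id=best[1],
        )
    return genes


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (gene -> transcript -> exon)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            tx = g.transcript_id or f"{g.gene_id}.t1"
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            out.write(
                f"{g.chrom}\tpaleotx\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            out.write(
                f"{g.chrom}\tpaleotx\ttranscript\t{g.exons[0][0] + 1}\t{g.exons[-1][1]}"
                f"\t.\t{g.strand}\t.\tID={tx};Parent={g.gene_id}\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                out.write(
                    f"{g.chrom}\tpaleotx\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"ID={tx}.e{i};Parent={tx}\n"
                )


__all__ = [
    "ReadRecord",
    "AlignmentRecord",
    "GeneModel",
    "ParseError",
    "ConfigurationError",
    "parse_fastq",
    "write_fastq",
    "parse_fasta",
    "write_fasta",
    "parse_alignments",
    "write_sam",
    "parse_annotation",
    "write_annotation",
    "revcomp",
]
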