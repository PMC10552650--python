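"""Format readers/writers and domain-type invariants."""

import numpy as np
import pytest

from paleotx import formats_io as fio
from paleotx.synthetic_data import true_alignments


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def test_fastq_round_trip(tmp_path):
    records = [
        fio.ReadRecord("r1", "ACGTACGTACGTACGTAA", quality=list(range(18, 36))),
        fio.ReadRecord("r2", "TTTTGGGGCCCCAAAATT", quality=[40] * 18),
    ]
    path = tmp_path / "reads.fastq"
    fio.write_fastq(records, path)
    back = list(fio.parse_fastq(path))
    assert [(r.read_id, r.sequence, r.quality) for r in back] == [
        (r.read_id, r.sequence, r.quality) for r in records
    ]
    assert all(r.trim_status is None for r in back)


def test_fastq_empty_file(tmp_path):
    path = tmp_path / "empty.fastq"
    path.write_text("")
    assert list(fio.parse_fastq(path)) == []


def test_fastq_malformed_quality_errors_with_line(tmp_path):
    path = tmp_path / "bad.fastq"
    path.write_text("@ok\nACGTACGT\n+\nIIIIIIII\n@bad\nACGTACGT\n+\nIII\n")
    with pytest.raises(fio.ParseError, match="line 5"):
        list(fio.parse_fastq(path))


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"


def _parse_sam_text(tmp_path, body, **kw):
    path = tmp_path / "in.sam"
    path.write_text(SAM_HEADER + body)
    return list(fio.parse_alignments(path, **kw))


def test_single_block_cigar(tmp_path):
    rec = _parse_sam_text(
        tmp_path,
        "r1\t0\tchr1\t101\t30\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tMD:Z:20\n",
    )[0]
    assert rec.blocks == ((100, 120),)
    assert rec.strand == "+" and rec.mapq == 30
    assert rec.aligned_length == rec.read_length == 20


def test_spliced_cigar_blocks(tmp_path):
    rec = _parse_sam_text(
        tmp_path,
        "r1\t0\tchr1\t101\t30\t10M50N10M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tMD:Z:20\n",
    )[0]
    assert rec.blocks == ((100, 110), (160, 170))
    assert rec.aligned_length == 20


def test_soft_clips_excluded_from_blocks(tmp_path):
    rec = _parse_sam_text(
        tmp_path,
        "r1\t0\tchr1\t101\t30\t3S14M3S\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\tMD:Z:14\n",
    )[0]
    assert rec.blocks == ((100, 114),)
    assert rec.aligned_length == 14
    # soft-clipped positions absent from the aligned-position list
    assert set(rec.aligned_positions) == set(range(3, 17))


def test_unmapped_records_skipped(tmp_path):
    recs = _parse_sam_text(
        tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
    )
    assert recs == []


def test_cigar_sequence_disagreement_raises(tmp_path):
    with pytest.raises(fio.ParseError):
        _parse_sam_text(
            tmp_path,
            "r1\t0\tchr1\t101\t30\t30M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n",
        )


def test_mismatches_require_md_or_genome(tmp_path):
    body = "r1\t0\tchr1\t101\t30\t20M\t*\t0\t0\t" + "A" * 20 + "\t" + "I" * 20 + "\n"
    with pytest.raises(fio.ConfigurationError):
        _parse_sam_text(tmp_path, body)
    # genome provided: fine
    genome = {"chr1": "A" * 1000}
    assert _parse_sam_text(tmp_path, body, genome=genome)[0].mismatches == ()


def test_reverse_strand_mismatch_reoriented(tmp_path):
    """Mismatch positions on minus-strand reads are counted from the
    molecule's 5' end, verified by brute-force base comparison."""
    rng = np.random.default_rng(3)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=200))
    genome = {"chr1": ref}
    start, L = 50, 20
    molecule = fio.revcomp(ref[start : start + L])  # minus-strand molecule
    # damage the molecule's 5'-most base (genomic rightmost)
    damaged = ("T" if molecule[0] != "T" else "A") + molecule[1:]
    sam_seq = fio.revcomp(damaged)  # SAM stores the + strand
    body = f"r1\t16\tchr1\t{start + 1}\t30\t20M\t*\t0\t0\t{sam_seq}\t{'I' * 20}\n"
    rec = _parse_sam_text(tmp_path, body, genome=genome)[0]
    # oracle: compare molecule base-by-base against the reverse-complemented
    # reference slice
    expect = [
        (i, r, q)
        for i, (r, q) in enumerate(zip(fio.revcomp(ref[start : start + L]), damaged))
        if r != q
    ]
    assert list(rec.mismatches) == expect
    assert rec.mismatches[0][0] == 0  # 5'-most position of the molecule
    assert rec.sequence == damaged


def test_sam_round_trip_preserves_records(tmp_path, small_sim, muscle_lib):
    path = tmp_path / "lib.sam"
    original = true_alignments(muscle_lib)[:300]
    fio.write_sam(original, small_sim.genome_lengths, path)
    back = list(fio.parse_alignments(path))
    assert len(back) == len(original)
    for a, b in zip(original, back):
        assert (a.read_id, a.reference, a.start, a.blocks, a.strand) == (
            b.read_id,
            b.reference,
            b.start,
            b.blocks,
            b.strand,
        )
        assert a.sequence == b.sequence
        assert tuple(a.mismatches) == tuple(b.mismatches)
        assert b.aligned_length == sum(e - s for s, e in b.blocks)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF = """##gff-version 3
chr1\tx\tgene\t101\t1100\t.\t+\t.\tID=g1;biotype=protein_coding
chr1\tx\ttranscript\t101\t1100\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tx\texon\t101\t300\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1
chr1\tx\texon\t901\t1100\t.\t+\t.\tID=g1.t1.e2;Parent=g1.t1
chr1\tx\ttranscript\t101\t1100\t.\t+\t.\tID=g1.t2;Parent=g1
chr1\tx\texon\t101\t400\t.\t+\t.\tID=g1.t2.e1;Parent=g1.t2
chr1\tx\texon\t901\t1100\t.\t+\t.\tID=g1.t2.e2;Parent=g1.t2
chr1\tx\tgene\t2001\t2200\t.\t-\t.\tID=g2;biotype=rRNA
chr1\tx\ttranscript\t2001\t2200\t.\t-\t.\tID=g2.t1;Parent=g2
chr1\tx\texon\t2001\t2200\t.\t-\t.\tID=g2.t1.e1;Parent=g2.t1
"""


def test_longest_isoform_retained(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    genes = fio.parse_annotation(path)
    g1 = genes["g1"]
    # t2 has 300+200=500 exonic nt vs t1's 200+200=400
    assert g1.transcript_id == "g1.t2"
    assert g1.exons == ((100, 400), (900, 1100))
    assert g1.introns == ((400, 900),)
    assert g1.span == (100, 1100)


def test_single_exon_gene_has_no_introns(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    g2 = fio.parse_annotation(path)["g2"]
    assert g2.introns == ()
    assert g2.strand == "-" and g2.biotype == "rRNA"


def test_isoform_tie_breaks_to_smaller_transcript_id(tmp_path):
    gff = """##gff-version 3
chr1\tx\tgene\t1\t400\t.\t+\t.\tID=g;biotype=protein_coding
chr1\tx\ttranscript\t1\t400\t.\t+\t.\tID=g.tB;Parent=g
chr1\tx\texon\t1\t400\t.\t+\t.\tID=eB;Parent=g.tB
chr1\tx\ttranscript\t1\t400\t.\t+\t.\tID=g.tA;Parent=g
chr1\tx\texon\t1\t400\t.\t+\t.\tID=eA;Parent=g.tA
"""
    path = tmp_path / "tie.gff3"
    path.write_text(gff)
    assert fio.parse_annotation(path)["g"].transcript_id == "g.tA"


def test_unknown_biotype_maps_to_other_with_warning(tmp_path):
    gff = """##gff-version 3
chr1\tx\tgene\t1\t100\t.\t+\t.\tID=g;biotype=wibble
chr1\tx\ttranscript\t1\t100\t.\t+\t.\tID=g.t;Parent=g
chr1\tx\texon\t1\t100\t.\t+\t.\tID=e;Parent=g.t
"""
    path = tmp_path / "odd.gff3"
    path.write_text(gff)
    with pytest.warns(UserWarning, match="wibble"):
        genes = fio.parse_annotation(path)
    assert genes["g"].biotype == "other"


def test_annotation_round_trip(tmp_path, small_sim):
    path = tmp_path / "sim.gff3"
    small_sim.write_gff3(path)
    back = fio.parse_annotation(path)
    assert set(back) == set(small_sim.genes)
    for gid, g in small_sim.genes.items():
        assert back[gid].exons == g.exons
        assert back[gid].strand == g.strand
        assert back[gid].biotype == g.biotype
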