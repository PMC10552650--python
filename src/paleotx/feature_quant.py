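"""Per-gene quantification and RNA-authentication statistics.

Reads are assigned to genes by aligned-base overlap: a read belongs to the
gene whose exons overlap the majority (>50%) of its aligned bases; failing
any exonic overlap, to the gene whose span contains it (intronic); reads
overlapping no gene are intergenic.  Assignment is strand-aware (same-strand
genes are preferred) with ties broken by larger overlap, then smaller
gene id.

On top of the assignments this module computes the statistics used to
authenticate an RNA (rather than DNA) origin for a degraded library:

* per-gene breadth/depth of exonic coverage and the >=10%-breadth
  reliable-expression rule;
* exonic enrichment / intronic depletion relative to a DNA background
  sequenced from the same genome;
* the fraction of exon-assigned reads spanning exon-exon junctions (evidence
  of spliced, mature mRNA) and of intron-assigned reads spanning exon-intron
  junctions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from intervaltree import IntervalTree

from .formats_io import AlignmentRecord, GeneModel


@dataclass
class ReadAssignment:
    read_id: str
    count: int
    gene_id: str | None
    category: str  # exonic | intronic | intergenic
    aligned_length: int
    exonic_overlap: int


@dataclass
class GeneQuant:
    gene_id: str
    biotype: str
    reads: int
    breadth: float
    depth: float
    reliable: bool


@dataclass
class QuantResult:
    genes: dict[str, GeneQuant]
    biotype_counts: dict[str, int]
    assignments: list[ReadAssignment]
    threshold: float

    @property
    def category_counts(self) -> dict[str, int]:
        out = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for a in self.assignments:
            out[a.category] += a.count
        return out


@dataclass
class EnrichmentResult:
    exonic_fraction_rna: float
    intronic_fraction_rna: float
    exonic_fraction_dna: float
    intronic_fraction_dna: float
    fold_enrichment: float | None
    fold_depletion_intron: float | None
    n_rna: int
    n_dna: int


@dataclass
class JunctionStats:
    n_exonic_considered: int  # exon-assigned reads in multi-exon genes
    n_exon_exon_spanning: int
    n_intronic_considered: int
    n_exon_intron_spanning: int

    @property
    def exon_exon_fraction(self) -> float:
        if self.n_exonic_considered == 0:
            return float("nan")
        return self.n_exon_exon_spanning / self.n_exonic_considered

    @property
    def exon_intron_fraction(self) -> float:
        if self.n_intronic_considered == 0:
            return float("nan")
        return self.n_exon_intron_spanning / self.n_intronic_considered


def _overlap(blocks: Iterable[tuple[int, int]], intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    for bs, be in blocks:
        for s, e in intervals:
            total += max(0, min(be, e) - max(bs, s))
    return total


def _gene_trees(genes: Mapping[str, GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes.values():
        trees.setdefault(g.chrom, IntervalTree()).addi(g.span[0], g.span[1], g)
    return trees


def assign_reads(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel],
) -> list[ReadAssignment]:
    """Assign each alignment to a gene and an exonic/intronic/intergenic class."""
    trees = _gene_trees(genes)
    out: list[ReadAssignment] = []
    for rec in alignments:
        tree = trees.get(rec.reference)
        candidates: list[GeneModel] = []
        if tree is not None:
            hits = set()
            for s, e in rec.blocks:
                hits |= tree.overlap(s, e)
            candidates = [iv.data for iv in hits]
        same_strand = [g for g in candidates if g.strand == rec.strand]
        pool = same_strand if same_strand else candidates
        alen = rec.aligned_length
        best_gene: GeneModel | None = None
        best_exonic = 0
        best_span = 0
        for g in sorted(pool, key=lambda g: g.gene_id):
            ex = _overlap(rec.blocks, g.exons)
            sp = _overlap(rec.blocks, [g.span])
            if (ex, sp) > (best_exonic, best_span):
                best_gene, best_exonic, best_span = g, ex, sp
        if best_gene is None:
            out.append(
                ReadAssignment(rec.read_id, rec.count, None, "intergenic", alen, 0)
            )
        else:
            category = "exonic" if best_exonic * 2 > alen else "intronic"
            out.append(
                ReadAssignment(
                    rec.read_id, rec.count, best_gene.gene_id, category, alen, best_exonic
                )
            )
    return out


def quantify_genes(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel],
    threshold: float = 0.10,
) -> QuantResult:
    """Per-gene deduplicated read counts, exonic breadth/depth, biotype tallies.

    Breadth is the fraction of the retained isoform's exonic bases covered by
    at least one assigned read; a gene is ``reliable`` when breadth >=
    ``threshold``.
    """
    alignments = list(alignments)
    assignments = assign_reads(alignments, genes)
    by_read = {a.read_id: a for a in assignments}

    # exonic coverage accumulators with genomic->exon-space offsets
    coverage: dict[str, np.ndarray] = {}
    offsets: dict[str, list[tuple[int, int, int]]] = {}
    for g in genes.values():
        coverage[g.gene_id] = np.zeros(g.exonic_length, dtype=np.int32)
        off, acc = [], 0
        for s, e in g.exons:
            off.append((s, e, acc))
            acc += e - s
        offsets[g.gene_id] = off

    reads_per_gene: dict[str, int] = {gid: 0 for gid in genes}
    for rec in alignments:
        a = by_read.get(rec.read_id)
        if a is None or a.gene_id is None:
            continue
        reads_per_gene[a.gene_id] += rec.count
        cov = coverage[a.gene_id]
        for bs, be in rec.blocks:
            for es, ee, acc in offsets[a.gene_id]:
                lo, hi = max(bs, es), min(be, ee)
                if lo < hi:
                    cov[acc + lo - es : acc + hi - es] += rec.count

    quants: dict[str, GeneQuant] = {}
    biotype_counts: dict[str, int] = {}
    for gid, g in genes.items():
        cov = coverage[gid]
        breadth = float(np.count_nonzero(cov)) / len(cov) if len(cov) else 0.0
        depth = float(cov.sum()) / len(cov) if len(cov) else 0.0
        quants[gid] = GeneQuant(
            gene_id=gid,
            biotype=g.biotype,
            reads=reads_per_gene[gid],
            breadth=breadth,
            depth=depth,
            reliable=breadth >= threshold,
        )
        biotype_counts[g.biotype] = biotype_counts.get(g.biotype, 0) + reads_per_gene[gid]
    return QuantResult(quants, biotype_counts, assignments, threshold)


def exon_intron_enrichment(
    rna_alignments: Iterable[AlignmentRecord],
    dna_alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel],
    restrict_to_reliable: bool = True,
    threshold: float = 0.10,
) -> EnrichmentResult:
    """Exonic/intronic read fractions of RNA vs a DNA background.

    When ``restrict_to_reliable`` both datasets are scored over the genes
    whose RNA breadth of coverage meets the reliability threshold, mirroring
    the restriction to loci with dependable expression evidence.  Fractions
    are computed over gene-assigned reads; folds are None when a denominator
    is empty.
    """
    rna_alignments = list(rna_alignments)
    dna_alignments = list(dna_alignments)
    if restrict_to_reliable:
        quant = quantify_genes(rna_alignments, genes, threshold)
        genes = {
            gid: g for gid, g in genes.items() if quant.genes[gid].reliable
        }

    def fractions(alignments: list[AlignmentRecord]) -> tuple[float, float, int]:
        ex = intr = 0
        for a in assign_reads(alignments, genes):
            if a.category == "exonic":
                ex += a.count
            elif a.category == "intronic":
                intr += a.count
        total = ex + intr
        if total == 0:
            return float("nan"), float("nan"), 0
        return ex / total, intr / total, total

    ex_rna, in_rna, n_rna = fractions(rna_alignments)
    ex_dna, in_dna, n_dna = fractions(dna_alignments)
    fold = ex_rna / ex_dna if n_dna and n_rna and ex_dna > 0 else None
    fold_dep = in_dna / in_rna if n_dna and n_rna and in_rna > 0 else None
    return EnrichmentResult(ex_rna, in_rna, ex_dna, in_dna, fold, fold_dep, n_rna, n_dna)


def junction_spanning(
    alignments: Iterable[AlignmentRecord],
    genes: Mapping[str, GeneModel],
) -> JunctionStats:
    """Fractions of reads spanning exon-exon and exon-intron junctions.

    A read spans an exon-exon junction iff it covers the last base of one
    exon and the first base of the next exon of its assigned gene (>= 1 nt on
    each side); exon-intron junctions are the analogous boundaries in genome
    space.  Single-exon genes contribute no junction opportunities and are
    excluded from the exonic denominator.
    """
    alignments = list(alignments)
    assignments = assign_reads(alignments, genes)
    by_read = {a.read_id: a for a in assignments}
    stats = JunctionStats(0, 0, 0, 0)
    for rec in alignments:
        a = by_read[rec.read_id]
        if a.gene_id is None:
            continue
        g = genes[a.gene_id]
        covered = set(rec.positions())
        if a.category == "exonic":
            if len(g.exons) < 2:
                continue
            stats.n_exonic_considered += rec.count
            spans = any(
                (e0 - 1) in covered and s1 in covered
                for (_, e0), (s1, _) in zip(g.exons, g.exons[1:])
            )
            if spans:
                stats.n_exon_exon_spanning += rec.count
        elif a.category == "intronic":
            stats.n_intronic_considered += rec.count
            spans = any(
                ((s - 1) in covered and s in covered)
                or ((e - 1) in covered and e in covered)
                for s, e in g.introns
            )
            if spans:
                stats.n_exon_intron_spanning += rec.count
    return stats


def expected_junction_fraction(gene: GeneModel, read_length: int) -> float:
    """Closed-form exon-exon spanning fraction for uniform mature-mRNA
    fragments of fixed length: (J * (r - 1)) / (T - r + 1)."""
    T = gene.transcript_length
    J = len(gene.exons) - 1
    r = read_length
    if r > T:
        raise ValueError("read longer than transcript")
    return J * (r - 1) / (T - r + 1)


__all__ = [
    "ReadAssignment",
    "GeneQuant",
    "QuantResult",
    "EnrichmentResult",
    "JunctionStats",
    "assign_reads",
    "quantify_genes",
    "exon_intron_enrichment",
    "junction_spanning",
    "expected_junction_fraction",
]
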