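"""miRNA hairpin construction, annotation criteria, and arm quantification.

A candidate miRNA locus is a precursor hairpin whose 5p and 3p mature arms
flank a loop; the precursor extended by 30 nt on each side is the primary
(pri) hairpin used for mapping and quantification.  A candidate is accepted
as a novel miRNA when all four criteria hold:

1. at least two 18-25-nt reads are expressed from each arm;
2. supporting reads show consistent 5'-end homogeneity on both arms
   (modal 5' start fraction >= 0.5 by default);
3. the arms are complementary over at least 16 Watson-Crick positions
   (ungapped, small offsets; G:U wobble optionally accepted);
4. the loop is between 8 and 40 nt long.

Reads mapping within the stem but outside both mature arms, or whose offset
nucleotides exceed 25% of their length relative to the mature arm, are
unreliable mapping events and are discarded before arm counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats_io import AlignmentRecord, revcomp

PRI_FLANK = 30


@dataclass(frozen=True)
class HairpinLocus:
    """Genomic annotation of a precursor hairpin (input to model building)."""

    hairpin_id: str
    chrom: str
    strand: str
    pre: tuple[int, int]
    arm5p: tuple[int, int]  # genomic coordinates, half-open
    arm3p: tuple[int, int]


@dataclass
class HairpinModel:
    """Pri-hairpin with strand-correct part sequences.

    Intervals ``arm5p``/``arm3p``/``loop`` are in pri-hairpin coordinates
    (0-based offsets into ``pri_seq``, which always runs 5'->3' on the
    annotated strand).  ``clipped`` marks hairpins whose 30-nt flanks were
    truncated at a scaffold edge.
    """

    hairpin_id: str
    chrom: str
    strand: str
    pre_interval: tuple[int, int]
    pri_interval: tuple[int, int]
    arm5p: tuple[int, int]
    arm3p: tuple[int, int]
    loop: tuple[int, int]
    pri_seq: str
    clipped: bool = False

    @property
    def arm5p_seq(self) -> str:
        return self.pri_seq[self.arm5p[0] : self.arm5p[1]]

    @property
    def arm3p_seq(self) -> str:
        return self.pri_seq[self.arm3p[0] : self.arm3p[1]]

    @property
    def loop_seq(self) -> str:
        return self.pri_seq[self.loop[0] : self.loop[1]]

    @property
    def loop_length(self) -> int:
        return self.loop[1] - self.loop[0]


def build_pri_hairpin(
    locus: HairpinLocus,
    genome: Mapping[str, str],
    flank: int = PRI_FLANK,
) -> HairpinModel:
    """Extend a precursor by ``flank`` nt per side and extract sequences.

    Minus-strand hairpins are reverse-complemented so that ``arm5p`` is the
    5'-most arm of ``pri_seq``.  Precursors within ``flank`` nt of a scaffold
    edge are clipped and flagged.
    """
    seq = genome[locus.chrom]
    s, e = locus.pre
    ps, pe = max(0, s - flank), min(len(seq), e + flank)
    clipped = ps != s - flank or pe != e + flank
    pri = seq[ps:pe]
    if locus.strand == "-":
        pri = revcomp(pri)

        def to_pri(iv: tuple[int, int]) -> tuple[int, int]:
            return (pe - iv[1], pe - iv[0])

    else:

        def to_pri(iv: tuple[int, int]) -> tuple[int, int]:
            return (iv[0] - ps, iv[1] - ps)

    a5, a3 = to_pri(locus.arm5p), to_pri(locus.arm3p)
    if a5[0] > a3[0]:
        raise ValueError(
            f"{locus.hairpin_id}: arm5p must precede arm3p in 5'->3' orientation"
        )
    loop = (a5[1], a3[0])
    return HairpinModel(
        hairpin_id=locus.hairpin_id,
        chrom=locus.chrom,
        strand=locus.strand,
        pre_interval=(s, e),
        pri_interval=(ps, pe),
        arm5p=a5,
        arm3p=a3,
        loop=loop,
        pri_seq=pri,
        clipped=clipped,
    )


WOBBLE_PAIRS = {("G", "A"), ("T", "C")}  # vs the reverse complement of arm3p


def arm_complementarity(
    arm5p: str,
    arm3p: str,
    max_offset: int = 4,
    wobble: bool = False,
) -> int:
    """Maximum matched pairing positions between arm5p and the reverse
    complement of arm3p over ungapped offsets in [-max_offset, +max_offset].

    A Watson-Crick pair corresponds to identical letters after
    reverse-complementing arm3p; G:U wobble (when enabled) appears as G/A or
    T/C letter pairs in that frame.
    """
    rc3 = revcomp(arm3p)
    best = 0
    for off in range(-max_offset, max_offset + 1):
        matched = 0
        for i, base in enumerate(arm5p):
            j = i + off
            if 0 <= j < len(rc3):
                if base == rc3[j] or (wobble and (base, rc3[j]) in WOBBLE_PAIRS):
                    matched += 1
        best = max(best, matched)
    return best


@dataclass(frozen=True)
class CriteriaParams:
    min_reads_per_arm: int = 2
    read_length_range: tuple[int, int] = (18, 25)
    min_homogeneity: float = 0.5
    min_complementarity: int = 16
    loop_range: tuple[int, int] = (8, 40)
    max_offset: int = 4
    wobble: bool = False
    max_offset_fraction: float = 0.25


@dataclass
class CriteriaReport:
    hairpin_id: str
    reads_5p: int
    reads_3p: int
    homogeneity_5p: float
    homogeneity_3p: float
    complementarity: int
    loop_len: int
    pass_expression: bool
    pass_homogeneity: bool
    pass_complementarity: bool
    pass_loop: bool

    @property
    def passes(self) -> bool:
        return (
            self.pass_expression
            and self.pass_homogeneity
            and self.pass_complementarity
            and self.pass_loop
        )


@dataclass
class ArmQuant:
    count_5p: int
    count_3p: int
    discarded: int
    discard_reasons: dict[str, int] = field(default_factory=dict)


def quantify_arms(
    alignments: Iterable[AlignmentRecord],
    hairpin: HairpinModel,
    max_offset_fraction: float = 0.25,
) -> ArmQuant:
    """Assign pri-hairpin alignments to the 5p or 3p arm.

    A read counts toward an arm iff it overlaps that arm and its offset
    nucleotides (bases outside the mature arm) are <= ``max_offset_fraction``
    of its length; the 25% boundary is inclusive.  Reads overlapping both
    arms equally, or neither arm acceptably, are discarded.
    """
    quant = ArmQuant(0, 0, 0)

    def overlap(iv: tuple[int, int], s: int, e: int) -> int:
        return max(0, min(e, iv[1]) - max(s, iv[0]))

    for rec in alignments:
        s, e = rec.start, rec.start + rec.read_length
        length = rec.read_length
        ov5 = overlap(hairpin.arm5p, s, e)
        ov3 = overlap(hairpin.arm3p, s, e)
        ok5 = ov5 > 0 and (length - ov5) <= max_offset_fraction * length
        ok3 = ov3 > 0 and (length - ov3) <= max_offset_fraction * length
        if ok5 and ok3 and ov5 == ov3:
            quant.discarded += rec.count
            quant.discard_reasons["ambiguous"] = (
                quant.discard_reasons.get("ambiguous", 0) + rec.count
            )
        elif ok5 and (not ok3 or ov5 > ov3):
            quant.count_5p += rec.count
        elif ok3 and (not ok5 or ov3 > ov5):
            quant.count_3p += rec.count
        else:
            reason = "offset_gt_max" if (ov5 or ov3) else "outside_arms"
            quant.discarded += rec.count
            quant.discard_reasons[reason] = (
                quant.discard_reasons.get(reason, 0) + rec.count
            )
    return quant


def _arm_stats(
    alignments: list[AlignmentRecord],
    hairpin: HairpinModel,
    arm: tuple[int, int],
    params: CriteriaParams,
) -> tuple[int, float]:
    """(read count in length range, modal 5'-start fraction) for one arm."""

    def assigned(rec: AlignmentRecord) -> bool:
        s, e = rec.start, rec.start + rec.read_length
        ov = max(0, min(e, arm[1]) - max(s, arm[0]))
        other = hairpin.arm3p if arm == hairpin.arm5p else hairpin.arm5p
        ov_other = max(0, min(e, other[1]) - max(s, other[0]))
        ok = ov > 0 and (rec.read_length - ov) <= params.max_offset_fraction * rec.read_length
        return ok and ov > ov_other

    lo, hi = params.read_length_range
    starts: dict[int, int] = {}
    n = 0
    for rec in alignments:
        if not assigned(rec) or not lo <= rec.read_length <= hi:
            continue
        n += rec.count
        starts[rec.start] = starts.get(rec.start, 0) + rec.count
    homogeneity = max(starts.values()) / n if n else 0.0
    return n, homogeneity


def evaluate_annotation_criteria(
    hairpin: HairpinModel,
    arm_reads: Iterable[AlignmentRecord],
    params: CriteriaParams = CriteriaParams(),
) -> CriteriaReport:
    """Apply the four novel-miRNA annotation criteria to one hairpin.

    ``arm_reads`` are alignments in pri-hairpin coordinates (reference is the
    hairpin id; ``start`` is the offset into ``pri_seq``).
    """
    if hairpin.arm5p[1] <= hairpin.arm5p[0] or hairpin.arm3p[1] <= hairpin.arm3p[0]:
        raise ValueError(f"{hairpin.hairpin_id}: arms undefined, cannot evaluate")
    reads = [r for r in arm_reads if r.reference == hairpin.hairpin_id]
    n5, h5 = _arm_stats(reads, hairpin, hairpin.arm5p, params)
    n3, h3 = _arm_stats(reads, hairpin, hairpin.arm3p, params)
    comp = arm_complementarity(
        hairpin.arm5p_seq,
        hairpin.arm3p_seq,
        max_offset=params.max_offset,
        wobble=params.wobble,
    )
    loop_len = hairpin.loop_length
    return CriteriaReport(
        hairpin_id=hairpin.hairpin_id,
        reads_5p=n5,
        reads_3p=n3,
        homogeneity_5p=h5,
        homogeneity_3p=h3,
        complementarity=comp,
        loop_len=loop_len,
        pass_expression=n5 >= params.min_reads_per_arm and n3 >= params.min_reads_per_arm,
        pass_homogeneity=(
            n5 > 0 and n3 > 0 and h5 >= params.min_homogeneity and h3 >= params.min_homogeneity
        ),
        pass_complementarity=comp >= params.min_complementarity,
        pass_loop=params.loop_range[0] <= loop_len <= params.loop_range[1],
    )


def arm_ratio(count_5p: int, count_3p: int) -> tuple[float | None, str]:
    """5p/3p abundance ratio and the dominant arm.

    Returns ``(ratio, arm)`` where ratio is None when the 3p count is zero
    (infinite preference) and arm is one of 5p, 3p, co-dominant.
    """
    if count_5p == 0 and count_3p == 0:
        raise ValueError("both arm counts are zero; ratio undefined")
    ratio = count_5p / count_3p if count_3p else None
    if count_5p > count_3p:
        arm = "5p"
    elif count_3p > count_5p:
        arm = "3p"
    else:
        arm = "co-dominant"
    return ratio, arm


def project_to_pri(rec: AlignmentRecord, hairpin: HairpinModel) -> AlignmentRecord | None:
    """Re-express a contiguous genome alignment in pri-hairpin coordinates.

    Returns None for reads outside the pri interval or on the wrong strand.
    The projected record runs 5'->3' along the hairpin, so downstream arm
    logic never needs to know the genomic strand.
    """
    if rec.reference != hairpin.chrom or rec.strand != hairpin.strand:
        return None
    if len(rec.blocks) != 1:
        return None
    s, e = rec.blocks[0]
    ps, pe = hairpin.pri_interval
    if s < ps or e > pe:
        return None
    if hairpin.strand == "+":
        start = s - ps
    else:
        start = pe - e
    return AlignmentRecord(
        read_id=rec.read_id,
        reference=hairpin.hairpin_id,
        start=start,
        blocks=((start, start + (e - s)),),
        strand="+",
        mapq=rec.mapq,
        read_length=rec.read_length,
        sequence=rec.sequence,
        count=rec.count,
    )


def parse_hairpin_annotation(path) -> list[HairpinLocus]:
    """Read hairpin loci from GFF3 (pre_miRNA features with miRNA arm
    children carrying an ``arm=5p|3p`` attribute)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    loci = []
    for pre in db.features_of_type("pre_miRNA"):
        arms: dict[str, tuple[int, int]] = {}
        for child in db.children(pre, featuretype="miRNA"):
            arm = child.attributes.get("arm", ["?"])[0]
            arms[arm] = (child.start - 1, child.end)
        if set(arms) != {"5p", "3p"}:
            raise ValueError(f"hairpin {pre.id} lacks annotated 5p/3p arms")
        loci.append(
            HairpinLocus(
                hairpin_id=pre.id,
                chrom=pre.seqid,
                strand=pre.strand,
                pre=(pre.start - 1, pre.end),
                arm5p=arms["5p"],
                arm3p=arms["3p"],
            )
        )
    return loci


def write_hairpin_annotation(loci: Iterable[HairpinLocus], path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for h in loci:
            out.write(
                f"{h.chrom}\tpaleotx\tpre_miRNA\t{h.pre[0] + 1}\t{h.pre[1]}\t.\t"
                f"{h.strand}\t.\tID={h.hairpin_id}\n"
            )
            for arm, iv in (("5p", h.arm5p), ("3p", h.arm3p)):
                out.write(
                    f"{h.chrom}\tpaleotx\tmiRNA\t{iv[0] + 1}\t{iv[1]}\t.\t{h.strand}\t.\t"
                    f"ID={h.hairpin_id}-{arm};Parent={h.hairpin_id};arm={arm}\n"
                )


__all__ = [
    "HairpinLocus",
    "HairpinModel",
    "CriteriaParams",
    "CriteriaReport",
    "ArmQuant",
    "build_pri_hairpin",
    "arm_complementarity",
    "evaluate_annotation_criteria",
    "quantify_arms",
    "arm_ratio",
    "project_to_pri",
    "parse_hairpin_annotation",
    "write_hairpin_annotation",
    "PRI_FLANK",
]
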