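"""Hairpin building, annotation criteria, arm quantification, arm ratios."""

import itertools

import numpy as np
import pytest

from paleotx import mirna_tools as mt
from paleotx.formats_io import AlignmentRecord, revcomp

ARM = 22


def _pri_read(hairpin_id, start, length, read_id="r", count=1):
    return AlignmentRecord(
        read_id=read_id,
        reference=hairpin_id,
        start=start,
        blocks=((start, start + length),),
        strand="+",
        mapq=30,
        read_length=length,
        count=count,
    )


def _make_hairpin(loop_len=20, complementary=True, hid="hp"):
    """Pri-hairpin model in local coordinates (flank 30 + arms + loop)."""
    rng = np.random.default_rng(loop_len + (1 if complementary else 0))
    arm5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ARM))
    if complementary:
        arm3 = revcomp(arm5)
    else:
        arm3 = "A" * ARM if arm5.count("T") < 16 else "C" * ARM
        assert mt.arm_complementarity(arm5, arm3) < 16
    loop = "".join("ACGT"[i] for i in rng.integers(0, 4, size=loop_len))
    flank = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    pre_len = 2 * ARM + loop_len
    pri = flank + arm5 + loop + arm3 + flank2
    return mt.HairpinModel(
        hairpin_id=hid,
        chrom="chr1",
        strand="+",
        pre_interval=(1000, 1000 + pre_len),
        pri_interval=(970, 1030 + pre_len),
        arm5p=(30, 30 + ARM),
        arm3p=(30 + ARM + loop_len, 30 + 2 * ARM + loop_len),
        loop=(30 + ARM, 30 + ARM + loop_len),
        pri_seq=pri,
    )


# ---------------------------------------------------------------------------
# pri-hairpin construction
# ---------------------------------------------------------------------------


def test_pri_extends_precursor_by_30nt_each_side():
    rng = np.random.default_rng(1)
    genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))}
    locus = mt.HairpinLocus("h", "chr1", "+", (500, 560), (500, 522), (538, 560))
    model = mt.build_pri_hairpin(locus, genome)
    assert model.pri_interval == (470, 590)
    assert len(model.pri_seq) == 120
    assert not model.clipped
    assert model.arm5p == (30, 52) and model.loop_length == 16


def test_minus_strand_pri_is_reverse_complement():
    rng = np.random.default_rng(2)
    genome = {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))}
    locus = mt.HairpinLocus("h", "chr1", "-", (500, 560), (538, 560), (500, 522))
    model = mt.build_pri_hairpin(locus, genome)
    assert model.pri_seq == revcomp(genome["chr1"][470:590])
    assert model.arm5p == (30, 52)  # 5p arm is 5'-most in pri coordinates
    assert model.arm5p_seq == revcomp(genome["chr1"][538:560])


def test_scaffold_edge_clips_flank_and_flags():
    genome = {"chr1": "ACGT" * 200}
    locus = mt.HairpinLocus("h", "chr1", "+", (10, 70), (10, 32), (48, 70))
    model = mt.build_pri_hairpin(locus, genome)
    assert model.clipped
    assert model.pri_interval == (0, 100)  # 5' flank clipped to 10 nt


# ---------------------------------------------------------------------------
# complementarity
# ---------------------------------------------------------------------------


def test_exact_reverse_complement_arms_score_full_length():
    arm5 = "ACGTACGTACGTACGTACGTAC"
    assert mt.arm_complementarity(arm5, revcomp(arm5)) == 22


def test_complementarity_matches_exhaustive_offset_scan():
    rng = np.random.default_rng(8)
    for _ in range(50):
        a5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ARM))
        a3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ARM))
        rc3 = revcomp(a3)
        brute = max(
            sum(
                1
                for i in range(ARM)
                if 0 <= i + off < ARM and a5[i] == rc3[i + off]
            )
            for off in range(-4, 5)
        )
        assert mt.arm_complementarity(a5, a3) == brute


def test_wobble_pairs_accepted_when_enabled():
    # arm5 all G pairs arm3 all T only through G:U wobble
    assert mt.arm_complementarity("G" * 22, "T" * 22, wobble=False) == 0
    assert mt.arm_complementarity("G" * 22, "T" * 22, wobble=True) == 22


# ---------------------------------------------------------------------------
# annotation criteria truth table
# ---------------------------------------------------------------------------


def _reads_for(hairpin, expr_ok, homog_ok):
    """Reads toggling expression (3p count) and homogeneity (5p starts)."""
    reads = []
    s5 = hairpin.arm5p[0]
    s3 = hairpin.arm3p[0]
    if homog_ok:
        starts5 = [s5, s5, s5]
    else:
        starts5 = [s5, s5 + 1, s5 + 2]  # modal fraction 1/3 < 0.5
    for i, s in enumerate(starts5):
        reads.append(_pri_read(hairpin.hairpin_id, s, ARM, read_id=f"r5_{i}"))
    n3 = 3 if expr_ok else 1
    for i in range(n3):
        reads.append(_pri_read(hairpin.hairpin_id, s3, ARM, read_id=f"r3_{i}"))
    return reads


@pytest.mark.parametrize(
    "expr_ok,homog_ok,comp_ok,loop_ok",
    list(itertools.product([True, False], repeat=4)),
)
def test_criteria_truth_table(expr_ok, homog_ok, comp_ok, loop_ok):
    """All 16 pass/fail combinations of the four criteria evaluate exactly
    as constructed."""
    hairpin = _make_hairpin(loop_len=20 if loop_ok else 7, complementary=comp_ok)
    reads = _reads_for(hairpin, expr_ok, homog_ok)
    report = mt.evaluate_annotation_criteria(hairpin, reads)
    assert report.pass_expression == expr_ok
    assert report.pass_homogeneity == homog_ok
    assert report.pass_complementarity == comp_ok
    assert report.pass_loop == loop_ok
    assert report.passes == (expr_ok and homog_ok and comp_ok and loop_ok)


def test_loop_bounds_inclusive():
    for loop_len, ok in ((7, False), (8, True), (40, True), (41, False)):
        hairpin = _make_hairpin(loop_len=loop_len)
        report = mt.evaluate_annotation_criteria(
            hairpin, _reads_for(hairpin, True, True)
        )
        assert report.pass_loop == ok


def test_criterion1_monotone_in_reads():
    """Adding arm reads never flips a passing expression criterion."""
    hairpin = _make_hairpin()
    reads = _reads_for(hairpin, True, True)
    base = mt.evaluate_annotation_criteria(hairpin, reads)
    assert base.pass_expression
    more = reads + [
        _pri_read(hairpin.hairpin_id, hairpin.arm5p[0], ARM, read_id=f"x{i}")
        for i in range(10)
    ]
    again = mt.evaluate_annotation_criteria(hairpin, more)
    assert again.pass_expression
    assert again.reads_5p >= base.reads_5p


def test_undefined_arms_raise():
    hairpin = _make_hairpin()
    hairpin.arm3p = (50, 50)
    with pytest.raises(ValueError, match="arms undefined"):
        mt.evaluate_annotation_criteria(hairpin, [])


# ---------------------------------------------------------------------------
# arm quantification and ratios
# ---------------------------------------------------------------------------


def test_exact_arm_read_counts_with_zero_offset():
    hairpin = _make_hairpin()
    quant = mt.quantify_arms([_pri_read("hp", hairpin.arm5p[0], 22)], hairpin)
    assert (quant.count_5p, quant.count_3p, quant.discarded) == (1, 0, 0)


def test_offset_filter_boundary_25_percent():
    hairpin = _make_hairpin()
    # 20-nt read with 5 nt outside the arm: 25%, inclusive -> counted
    ok = _pri_read("hp", hairpin.arm5p[0] - 5, 20, read_id="ok")
    # 6 nt outside: 30% > 25% -> discarded
    bad = _pri_read("hp", hairpin.arm5p[0] - 6, 20, read_id="bad")
    quant = mt.quantify_arms([ok, bad], hairpin)
    assert quant.count_5p == 1
    assert quant.discarded == 1
    assert quant.discard_reasons == {"offset_gt_max": 1}


def test_loop_only_read_discarded():
    hairpin = _make_hairpin(loop_len=30)
    read = _pri_read("hp", hairpin.loop[0] + 2, 20)
    quant = mt.quantify_arms([read], hairpin)
    assert quant.discarded == 1
    assert quant.discard_reasons == {"outside_arms": 1}


def test_partition_conservation(small_sim):
    """count_5p + count_3p + discarded equals the input alignments."""
    from paleotx.synthetic_data import simulate_library, true_alignments

    lib = simulate_library(small_sim, "muscle", 3000, seed=9, pcr_duplication=1.0)
    genome = small_sim.genome
    total_in = 0
    total_out = 0
    for locus in small_sim.hairpins:
        model = mt.build_pri_hairpin(locus, genome)
        projected = [
            p
            for p in (
                mt.project_to_pri(rec, model) for rec in true_alignments(lib)
            )
            if p is not None
        ]
        quant = mt.quantify_arms(projected, model)
        total_in += len(projected)
        total_out += quant.count_5p + quant.count_3p + quant.discarded
    assert total_in == total_out and total_in > 0


def test_planted_arm_ratio_recovered(small_sim):
    """A hairpin sampled with an 80/20 arm preference recovers a 5p-dominant
    ratio within the binomial envelope."""
    from paleotx.synthetic_data import simulate_library, true_alignments

    lib = simulate_library(small_sim, "muscle", 20_000, seed=10, pcr_duplication=1.0)
    recs = true_alignments(lib)
    for locus in small_sim.hairpins:
        if locus.hairpin_id not in small_sim.hairpin_5p_fraction:
            continue
        bias = small_sim.hairpin_5p_fraction[locus.hairpin_id]
        model = mt.build_pri_hairpin(locus, small_sim.genome)
        projected = [
            p for p in (mt.project_to_pri(r, model) for r in recs) if p is not None
        ]
        quant = mt.quantify_arms(projected, model)
        n = quant.count_5p + quant.count_3p
        if n < 30:
            continue
        p_hat = quant.count_5p / n
        sigma = np.sqrt(bias * (1 - bias) / n)
        assert abs(p_hat - bias) < 4 * sigma
        _, dominant = mt.arm_ratio(quant.count_5p, quant.count_3p)
        assert dominant == ("5p" if bias > 0.5 else "3p")


def test_arm_ratio_basic_and_degenerate():
    assert mt.arm_ratio(90, 10) == (9.0, "5p")
    ratio, dominant = mt.arm_ratio(0, 50)
    assert ratio == 0.0 and dominant == "3p"
    ratio, dominant = mt.arm_ratio(50, 0)
    assert ratio is None and dominant == "5p"
    assert mt.arm_ratio(5, 5)[1] == "co-dominant"
    with pytest.raises(ValueError):
        mt.arm_ratio(0, 0)


def test_hairpin_annotation_round_trip(tmp_path, small_sim):
    path = tmp_path / "hairpins.gff3"
    small_sim.write_hairpin_gff3(path)
    back = mt.parse_hairpin_annotation(path)
    assert {h.hairpin_id for h in back} == {h.hairpin_id for h in small_sim.hairpins}
    by_id = {h.hairpin_id: h for h in back}
    for h in small_sim.hairpins:
        assert by_id[h.hairpin_id] == h
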