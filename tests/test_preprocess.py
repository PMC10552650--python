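"""Adapter trimming, UMI handling, deduplication, and length classing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import adapter_scan, directional_dedup
from paleotx.formats_io import ConfigurationError, ReadRecord
from paleotx import preprocess as pp

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
CFG = pp.TrimConfig(adapter=ADAPTER)


def _read(seq: str) -> ReadRecord:
    return ReadRecord("r", seq)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------


def test_exact_adapter_recovers_insert():
    rng = np.random.default_rng(0)
    insert = "AAAA" + _random_seq(rng, 20) + "CCCC"  # UMIs + 20-nt payload
    read = pp.trim_adapter(_read(insert + ADAPTER), CFG)
    assert read.trim_status == "trimmed"
    assert read.sequence == insert


def test_insert_trimming_to_17nt_payload_is_discarded():
    rng = np.random.default_rng(1)
    insert = "AAAA" + _random_seq(rng, 17) + "CCCC"
    read = pp.trim_adapter(_read(insert + ADAPTER), CFG)
    assert read.trim_status == "discarded"
    assert read.discard_reason == "too_short_after_trim"
    # 18-nt payload survives
    insert18 = "AAAA" + _random_seq(rng, 18) + "CCCC"
    assert pp.trim_adapter(_read(insert18 + ADAPTER), CFG).trim_status == "trimmed"


def test_one_error_in_12nt_adapter_prefix_trims():
    """1 edit in a 12-nt visible adapter (rate 0.083 <= 0.10) is accepted at
    the position the exhaustive scan finds."""
    rng = np.random.default_rng(2)
    insert = "AAAA" + _random_seq(rng, 22) + "CCCC"
    visible = "A" + ADAPTER[1:12]  # 12-nt prefix with one substitution
    seq = insert + visible
    read = pp.trim_adapter(_read(seq), CFG)
    assert read.trim_status == "trimmed"
    assert len(read.sequence) == adapter_scan(seq, ADAPTER, 0.10)


def test_no_adapter_leaves_read_untrimmed():
    rng = np.random.default_rng(3)
    seq = _random_seq(rng, 40)
    if adapter_scan(seq, ADAPTER, 0.10) is not None:  # pragma: no cover
        pytest.skip("random sequence happened to contain the adapter")
    read = pp.trim_adapter(_read(seq), CFG)
    assert read.trim_status == "untrimmed"
    assert read.sequence == seq


def test_adapter_shorter_than_3nt_rejected():
    with pytest.raises(ConfigurationError):
        pp.TrimConfig(adapter="TG")


def test_trim_matches_bruteforce_scan_on_random_reads():
    """Oracle equivalence on random 40-nt reads with planted adapters."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        n_insert = int(rng.integers(10, 40))
        seq = _random_seq(rng, n_insert)
        if rng.random() < 0.8:
            n_ad = int(rng.integers(3, len(ADAPTER) + 1))
            ad = list(ADAPTER[:n_ad])
            for _ in range(int(rng.integers(0, 3))):  # up to 2 errors
                ad[int(rng.integers(0, n_ad))] = "ACGT"[int(rng.integers(0, 4))]
            seq = seq + "".join(ad)
        assert pp.find_adapter(seq, CFG) == adapter_scan(seq, ADAPTER, 0.10)


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------


def test_trimmed_read_yields_8mer_umi():
    payload = "ACGTACGTACGTACGTACGT"
    read = ReadRecord("r", "AAAA" + payload + "CCCC", trim_status="trimmed")
    out = pp.extract_umi(read, CFG)
    assert out.umi == "AAAACCCC"
    assert out.sequence == payload


def test_untrimmed_read_yields_4mer_umi_and_loses_3prime_bases():
    payload = "ACGTACGTACGTACGTACGT"
    read = ReadRecord("r", "GGGG" + payload + "TTTT", trim_status="untrimmed")
    out = pp.extract_umi(read, CFG)
    assert out.umi == "GGGG"
    assert out.sequence == payload  # last 4 nt removed, not joined to the UMI


def test_8nt_insert_discarded_for_umi():
    read = ReadRecord("r", "ACGTACGT", trim_status="trimmed")
    out = pp.extract_umi(read, CFG)
    assert out.trim_status == "discarded"
    assert out.discard_reason == "too_short_for_umi"


# ---------------------------------------------------------------------------
# PCR-duplicate collapsing
# ---------------------------------------------------------------------------


def test_identical_copies_collapse_with_rate():
    reads = [
        ReadRecord(f"r{i}", "ACGT" * 5, umi="AAAACCCC", trim_status="trimmed")
        for i in range(10)
    ]
    unique, rate = pp.collapse_pcr_duplicates(reads)
    assert len(unique) == 1 and unique[0].count == 10
    assert rate == 10.0


def test_distinct_umis_stay_separate():
    reads = [
        ReadRecord("r1", "ACGT" * 5, umi="AAAACCCC", trim_status="trimmed"),
        ReadRecord("r2", "ACGT" * 5, umi="AAAACCCT", trim_status="trimmed"),
    ]
    unique, rate = pp.collapse_pcr_duplicates(reads)
    assert len(unique) == 2 and rate == 1.0


def test_collapse_equals_bruteforce_grouping():
    rng = np.random.default_rng(7)
    reads = []
    for i in range(500):
        payload = _random_seq(rng, 3)  # tiny alphabet to force collisions
        umi = "".join("AC"[j] for j in rng.integers(0, 2, size=8))
        reads.append(ReadRecord(f"r{i}", payload, umi=umi, trim_status="trimmed"))
    unique, rate = pp.collapse_pcr_duplicates(reads)
    expect: dict[tuple[str, str], int] = {}
    for r in reads:
        expect[(r.sequence, r.umi)] = expect.get((r.sequence, r.umi), 0) + 1
    assert {(u.sequence, u.umi): u.count for u in unique} == expect
    assert rate == pytest.approx(len(reads) / len(expect))


# ---------------------------------------------------------------------------
# directional UMI deduplication
# ---------------------------------------------------------------------------

LOCUS = ("chr1", 100, "+")


def test_directional_merges_error_derived_umi():
    group = pp.UmiGroup(LOCUS, {"AAAA": 10, "AAAT": 4})
    assert pp.dedup_umi_directional(group) == {"AAAA"}  # 10 >= 2*4-1


def test_directional_keeps_distant_umis():
    group = pp.UmiGroup(LOCUS, {"AAAA": 5, "TTTT": 5})
    assert pp.dedup_umi_directional(group) == {"AAAA", "TTTT"}


def test_directional_singleton_identity():
    assert pp.dedup_umi_directional(pp.UmiGroup(LOCUS, {"CCCC": 1})) == {"CCCC"}


def test_directional_threshold_boundary():
    # count(a) == 2*count(b) - 1 merges; one less does not
    assert pp.dedup_umi_directional(pp.UmiGroup(LOCUS, {"AAAA": 7, "AAAT": 4})) == {"AAAA"}
    assert pp.dedup_umi_directional(pp.UmiGroup(LOCUS, {"AAAA": 6, "AAAT": 4})) == {
        "AAAA",
        "AAAT",
    }


def test_unequal_umi_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        pp.dedup_umi_directional(pp.UmiGroup(LOCUS, {"AAAA": 2, "AAA": 1}))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.dictionaries(
        st.text(alphabet="AC", min_size=3, max_size=3),
        st.integers(min_value=1, max_value=30),
        min_size=1,
        max_size=6,
    )
)
def test_directional_equals_exhaustive_enumeration(members):
    """Property: representatives match the exhaustive component search for
    every group of at most 6 UMIs."""
    group = pp.UmiGroup(LOCUS, dict(members))
    assert pp.dedup_umi_directional(group) == directional_dedup(members)


# ---------------------------------------------------------------------------
# length histogram
# ---------------------------------------------------------------------------


def test_length_classes_partition_boundaries():
    hist = pp.length_histogram([18, 25, 26, 30, 31])
    assert hist.classes == {"18-25": 2, "26-30": 2, ">30": 1}
    assert hist.total == 5


def test_42nt_reads_counted_in_long_class():
    hist = pp.length_histogram([42] * 7)
    assert hist.classes[">30"] == 7
    assert hist.count_42 == 7


def test_empty_histogram():
    hist = pp.length_histogram([])
    assert hist.total == 0 and hist.count_42 == 0


def test_histogram_weights_by_multiplicity():
    reads = [ReadRecord("r", "A" * 20, count=5), ReadRecord("q", "A" * 42, count=2)]
    hist = pp.length_histogram(reads)
    assert hist.classes == {"18-25": 5, "26-30": 0, ">30": 2}
    assert hist.count_42 == 2
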