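from collections import Counter

import pytest

from germmir.preprocess import (DropLog, RawRead, UniqueRead, clean_reads,
                                collapse_reads, find_adapter,
                                length_distribution)

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


def make_read(insert, read_len=44, qual=38):
    seq = (insert + ADAPTER + "A" * read_len)[:read_len]
    return RawRead(sequence=seq, quality=[qual] * read_len)


@pytest.mark.parametrize("insert_len,kept", [(17, False), (18, True),
                                             (30, True), (31, False)])
def test_length_window_boundaries(rng, insert_len, kept):
    insert = "".join("ACGU"[i] for i in rng.integers(0, 4, insert_len)).replace("U", "T")
    out = list(clean_reads([make_read(insert)], adapter3=ADAPTER))
    assert bool(out) is kept
    if kept:
        assert out[0].sequence == insert


def test_drop_reasons_are_counted(rng):
    log = DropLog()
    reads = [
        make_read("ACGTACGTACGTACGTACGT"),                    # kept
        make_read("A" * 24),                                  # polyA
        RawRead(sequence=make_read("ACGTACGTACGTACGTACGA").sequence,
                quality=[5] * 44),                            # low quality
        RawRead(sequence="CT" * 22, quality=[38] * 44),       # no adapter
    ]
    out = list(clean_reads(reads, adapter3=ADAPTER, log=log))
    assert len(out) == 1
    assert log.kept == 1
    assert log.reasons == Counter({"polyA": 1, "low_quality": 1, "no_adapter3": 1})


def test_adapter5_contaminants_dropped():
    a5 = "GTTCAGAGTTCTACAGTCCGACGATC"
    contaminated = RawRead(sequence=(a5 + ADAPTER + "A" * 44)[:44], quality=[38] * 44)
    log = DropLog()
    out = list(clean_reads([contaminated], adapter3=ADAPTER, adapter5=a5, log=log))
    assert not out and log.reasons["adapter5_contaminant"] == 1


def test_adapter_located_with_one_mismatch():
    insert = "ACGTACGTACGTACGTACGT"
    mutated = ADAPTER[:4] + "A" + ADAPTER[5:]
    read = RawRead(sequence=(insert + mutated + "A" * 44)[:44], quality=None)
    assert find_adapter(read.sequence, ADAPTER) == len(insert)
    out = list(clean_reads([read], adapter3=ADAPTER))
    assert out and out[0].sequence == insert


def test_survivors_match_length_oracle(rng):
    """Planted inserts of length 15-35: survivors are exactly those in [18, 30]."""
    inserts = []
    for i in range(200):
        n = int(rng.integers(15, 36))
        inserts.append("".join("ACGT"[j] for j in rng.integers(0, 4, n)))
    reads = [RawRead(sequence=(ins + ADAPTER + "A" * 60)[:60], quality=[38] * 60)
             for ins in inserts]
    survivors = {r.sequence for r in clean_reads(reads, adapter3=ADAPTER)}
    polya = {ins for ins in inserts if ins.count("A") / len(ins) >= 0.8}
    expected = {ins for ins in inserts if 18 <= len(ins) <= 30} - polya
    assert survivors == expected


def test_collapse_drops_singletons_and_sums_counts():
    reads = [RawRead(sequence="ACGUACGUACGUACGUAC")] * 3 + \
            [RawRead(sequence="UGGAAGCUUGGAAGCUUG")]
    out = collapse_reads(reads, drop_singletons=True)
    assert len(out) == 1
    assert out[0].sequence == "ACGUACGUACGUACGUAC" and out[0].count == 3
    assert collapse_reads([]) == []


def test_collapse_matches_hash_count_oracle(rng):
    distinct = ["".join("ACGU"[j] for j in rng.integers(0, 4, 21)) for _ in range(300)]
    multiplicities = rng.integers(1, 60, size=300)
    reads = []
    for seq, m in zip(distinct, multiplicities):
        reads.extend([RawRead(sequence=seq)] * int(m))
    oracle = Counter(r.sequence for r in reads)
    out = collapse_reads(reads, drop_singletons=False)
    assert {r.sequence: r.count for r in out} == dict(oracle)
    assert sum(r.count for r in out) == len(reads)


def test_collapse_roundtrip_is_stable():
    reads = [RawRead(sequence="ACGUACGUACGUACGUAC")] * 3 + \
            [RawRead(sequence="GGGGCCCCGGGGCCCCGG")] * 2
    once = collapse_reads(reads)
    again = collapse_reads([RawRead(sequence=r.sequence) for r in once
                            for _ in range(r.count)])
    assert [(r.sequence, r.count) for r in once] == [(r.sequence, r.count) for r in again]


def test_singleton_removal_never_increases_counts(rng):
    reads = [RawRead(sequence="".join("ACGU"[j] for j in rng.integers(0, 4, 20)))
             for _ in range(100)]
    with_s = collapse_reads(reads, drop_singletons=False)
    without = collapse_reads(reads, drop_singletons=True)
    assert len(without) <= len(with_s)
    assert sum(r.count for r in without) <= sum(r.count for r in with_s)


def test_length_distribution_fractions():
    reads = [UniqueRead(sequence="A" * 20 + "C", count=3, read_id="a"),
             UniqueRead(sequence="G" * 24, count=7, read_id="b")]
    table = length_distribution(reads)
    by_len = table.set_index("length")
    assert by_len.loc[21, "distinct_count"] == 1
    assert by_len.loc[24, "total_count"] == 7
    assert by_len.loc[21, "total_fraction"] == pytest.approx(0.3)
    assert by_len.loc[24, "total_fraction"] == pytest.approx(0.7)
    assert table["total_fraction"].sum() == pytest.approx(1.0)


def test_length_distribution_tracks_generator_weights(truth_set, sim_libraries):
    """Empirical insert-length fractions follow the simulation weights."""
    from germmir.preprocess import clean_reads, collapse_reads
    from germmir.simulate import LENGTH_WEIGHTS

    lib1, _ = sim_libraries
    cleaned = clean_reads(lib1.reads, adapter3=truth_set.manifest.params.adapter3)
    unique = collapse_reads(cleaned, drop_singletons=False)
    table = length_distribution(unique).set_index("length")
    # background dominates; 24-nt enrichment must be visible
    assert table["total_count"].idxmax() in (21, 22, 24)
    assert table.loc[24, "total_count"] > table.loc[18, "total_count"]
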