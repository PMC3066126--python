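import pytest
from hypothesis import given
from hypothesis import strategies as st

from germmir.sequence import PairClass, reverse_complement
from germmir.targets import (MISMATCH_SCORES, parse_alignment, passes_filters,
                             render_alignment, scan_transcripts, score_duplex)

MIR = "UGACAGAAGAGAGUGAGCACA"  # 21 nt

_NONPAIR = {"A": "C", "C": "A", "G": "A", "U": "C"}


def site_with_mismatches(mir, positions):
    """Perfect-complement site broken at the given miRNA positions (1-based)."""
    site = list(reverse_complement(mir, "RNA"))
    for i in positions:
        j = len(mir) - i
        site[j] = _NONPAIR[site[j]]
    return "".join(site)


def brute_force_hits(mirnas, transcripts, strict=True):
    """Naive all-window rescoring oracle (independent of the scanner)."""
    hits = set()
    for mid, mir in mirnas.items():
        L = len(mir)
        for tid, tx in transcripts.items():
            for p in range(len(tx) - L + 1):
                d = score_duplex(mir, tx[p:p + L])
                _rules, overall = passes_filters(d, strict=strict)
                if overall:
                    hits.add((mid, tid, p))
    return hits


def test_perfect_duplex():
    d = score_duplex(MIR, reverse_complement(MIR, "RNA"))
    assert d.mismatch_score == 0
    assert all(s is PairClass.WATSON_CRICK for s in d.states)
    assert d.perfect_mfe == d.duplex_mfe < 0


def test_single_wobble_scores_half():
    site = list(reverse_complement(MIR, "RNA"))
    # miRNA position 15 is G (pairs C); C -> U creates G:U
    i = MIR.index("G", 10) + 1
    j = len(MIR) - i
    assert site[j] == "C"
    site[j] = "U"
    d = score_duplex(MIR, "".join(site))
    assert d.mismatch_score == 0.5
    assert d.states[i - 1] is PairClass.WOBBLE


def test_states_indexed_from_mirna_5_prime():
    site = site_with_mismatches(MIR, [14, 15, 20])
    d = score_duplex(MIR, site)
    assert d.mismatch_score == 3.0
    assert d.states[13] is PairClass.MISMATCH
    assert d.states[14] is PairClass.MISMATCH
    assert d.states[19] is PairClass.MISMATCH
    # recount by hand from the states
    assert sum(MISMATCH_SCORES[s] for s in d.states) == d.mismatch_score


def test_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        score_duplex(MIR, "ACGU")


def test_perfect_duplex_passes_all_rules():
    d = score_duplex(MIR, reverse_complement(MIR, "RNA"))
    rules, overall = passes_filters(d, strict=True)
    assert overall and all(rules.values())


@pytest.mark.parametrize("positions,failing", [
    ([10], "rule4_center"),
    ([11], "rule4_center"),
    ([3, 7, 9], "rule5_seed_score"),          # 3 > 2.5 in positions 1-12
    ([14, 15, 16], "rule2_adjacent"),         # run of three mismatches
    ([5, 6], "rule3_seed_adjacent"),          # adjacent inside 2-12
    ([2, 5, 14, 17, 20], "rule1_total"),      # five mismatches > 4
])
def test_rule_failures(positions, failing):
    d = score_duplex(MIR, site_with_mismatches(MIR, positions))
    rules, overall = passes_filters(d, strict=False)
    assert not rules[failing]
    assert not overall


def test_strict_mode_caps_total_score():
    # placements in the AU-cheap 3' half keep the duplex above the 75%
    # energy bound, isolating the strict mismatch cap
    d3 = score_duplex(MIR, site_with_mismatches(MIR, [13, 14, 16]))
    assert d3.mismatch_score == 3.0
    assert passes_filters(d3, strict=True)[1]
    d4 = score_duplex(MIR, site_with_mismatches(MIR, [13, 14, 20, 21]))
    assert d4.mismatch_score == 4.0
    rules, overall = passes_filters(d4, strict=True)
    assert all(rules.values()) and not overall  # rules pass, strict cap fails


def test_scanner_finds_planted_site(rng):
    tx = "".join("ACGU"[i] for i in rng.integers(0, 4, 500))
    site = reverse_complement(MIR, "RNA")
    tx = tx[:200] + site + tx[200 + len(site):]
    hits = scan_transcripts({"m1": MIR}, {"t1": tx})
    assert [(h.mirna_id, h.transcript_id, h.start)
            for h in hits if h.start == 200] == [("m1", "t1", 200)]


def test_position10_mismatch_site_yields_no_hit(rng):
    tx = "".join("ACGU"[i] for i in rng.integers(0, 4, 300))
    bad = site_with_mismatches(MIR, [10])
    tx = tx[:100] + bad + tx[100 + len(bad):]
    assert all(h.start != 100 for h in scan_transcripts({"m1": MIR}, {"t1": tx}))


@pytest.mark.parametrize("strict", [True, False])
def test_scanner_equals_brute_force_oracle(rng, strict):
    mirnas = {f"m{i}": "".join("ACGU"[j] for j in rng.integers(0, 4, 21))
              for i in range(5)}
    transcripts = {}
    for t in range(20):
        tx = "".join("ACGU"[j] for j in rng.integers(0, 4, 300))
        if t < 5:  # plant some imperfect sites so the hit set is non-empty
            mir = mirnas[f"m{t}"]
            site = site_with_mismatches(mir, [15]) if t % 2 else \
                reverse_complement(mir, "RNA")
            tx = tx[:50] + site + tx[50 + len(site):]
        transcripts[f"t{t}"] = tx
    got = {(h.mirna_id, h.transcript_id, h.start)
           for h in scan_transcripts(mirnas, transcripts, strict=strict)}
    assert got == brute_force_hits(mirnas, transcripts, strict=strict)
    assert got  # sanity: planted sites were found


def test_strict_hits_subset_of_default(rng):
    mirnas = {f"m{i}": "".join("ACGU"[j] for j in rng.integers(0, 4, 21))
              for i in range(3)}
    transcripts = {}
    for t in range(6):
        mir = mirnas[f"m{t % 3}"]
        tx = "".join("ACGU"[j] for j in rng.integers(0, 4, 200))
        site = site_with_mismatches(mir, [13, 15, 17, 20][:t % 5])
        transcripts[f"t{t}"] = tx[:80] + site + tx[80 + len(site):]
    strict = {(h.mirna_id, h.transcript_id, h.start)
              for h in scan_transcripts(mirnas, transcripts, strict=True)}
    loose = {(h.mirna_id, h.transcript_id, h.start)
             for h in scan_transcripts(mirnas, transcripts, strict=False)}
    assert strict <= loose


def test_hits_sorted_least_mismatch_first(rng):
    """Two miRNAs targeting the same site: fewer mismatches listed first."""
    mir2 = site_with_mismatches(MIR, [])  # placeholder
    mir_imperfect = MIR[:14] + ("A" if MIR[14] != "A" else "C") + MIR[15:]
    tx = "".join("ACGU"[i] for i in rng.integers(0, 4, 200))
    site = reverse_complement(MIR, "RNA")
    tx = tx[:90] + site + tx[90 + len(site):]
    hits = scan_transcripts({"perfect": MIR, "close": mir_imperfect}, {"t": tx})
    at_site = [h for h in hits if h.start == 90]
    if len(at_site) == 2:
        assert at_site[0].alignment.mismatch_score <= at_site[1].alignment.mismatch_score


def test_render_and_parse_roundtrip():
    site = site_with_mismatches(MIR, [5, 14])
    d = score_duplex(MIR, site)
    block = render_alignment(d)
    lines = block.split("\n")
    assert len(lines) == 3
    assert lines[1].count("|") == sum(s is PairClass.WATSON_CRICK for s in d.states)
    assert parse_alignment(block) == d.states


def test_wobble_renders_as_space():
    site = list(reverse_complement(MIR, "RNA"))
    i = MIR.index("G", 10) + 1
    site[len(MIR) - i] = "U"
    d = score_duplex(MIR, "".join(site))
    glyphs = render_alignment(d).split("\n")[1][10:]
    assert glyphs.count("|") == len(MIR) - 1
    assert glyphs[i - 1] == " "


@given(st.lists(st.sampled_from("ACGU"), min_size=21, max_size=21))
def test_mismatch_score_additivity(letters):
    site = "".join(letters)
    d = score_duplex(MIR, site)
    left = score_duplex(MIR[:10], site[11:])  # site tail faces miRNA head
    right = score_duplex(MIR[10:], site[:11])
    assert d.mismatch_score == pytest.approx(
        left.mismatch_score + right.mismatch_score)
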