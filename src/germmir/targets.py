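"""Plant-style miRNA target scanning over a transcript set.

The duplex model is ungapped and antiparallel: a site of the miRNA's
length is read 5'->3' on the transcript and miRNA position ``i`` (1-based
from the miRNA 5' end) faces site position ``L-i``.  Per-position states
are Watson-Crick, G:U wobble or mismatch; a wobble scores half a
mismatch.  Six filters gate a hit:

1. total mismatch score <= 4;
2. no run of more than two adjacent (full) mismatches;
3. no two adjacent mismatches within miRNA positions 2-12;
4. no mismatch at positions 10-11;
5. mismatch score over positions 1-12 <= 2.5;
6. |duplex MFE| >= 75% of the MFE of the miRNA bound to its perfect
   complement.

Strict mode additionally caps the total mismatch score at 3 (wobble
halves included).  Wobbles count toward the numeric scores (1, 5, strict)
but never toward adjacency (2, 3) nor as mismatches at 10-11 (4); in the
rendered alignment they display as spaces, like mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence import PairClass, pair_class, reverse_complement, to_rna, validate
from .thermo import duplex_energy, perfect_duplex_energy

MISMATCH_SCORES = {PairClass.WATSON_CRICK: 0.0, PairClass.WOBBLE: 0.5, PairClass.MISMATCH: 1.0}

MAX_TOTAL_SCORE = 4.0
MAX_ADJACENT_RUN = 2
SEED_REGION = (2, 12)       # 1-based inclusive, rules 3 and 5
CENTER_POSITIONS = (10, 11)
MAX_SEED_SCORE = 2.5
ENERGY_RATIO = 0.75
STRICT_MAX_SCORE = 3.0

RULE_NAMES = ["rule1_total", "rule2_adjacent", "rule3_seed_adjacent",
              "rule4_center", "rule5_seed_score", "rule6_energy"]


@dataclass
class DuplexAlignment:
    """Position-indexed pairing states of an ungapped miRNA/site duplex."""

    mirna: str
    site: str
    states: list[PairClass]          # index 0 = miRNA position 1 (5' end)
    mismatch_score: float
    duplex_mfe: float
    perfect_mfe: float


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int                       # 0-based half-open on the transcript
    end: int
    alignment: DuplexAlignment
    passed_rules: dict[str, bool]
    strict_pass: bool


def score_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Score one miRNA against one equal-length site (both 5'->3' RNA)."""
    mirna, site = validate(to_rna(mirna), "RNA"), validate(to_rna(site), "RNA")
    if len(mirna) != len(site):
        raise ValueError("miRNA and site must have equal length (ungapped model)")
    L = len(mirna)
    states = [pair_class(mirna[i], site[L - 1 - i]) for i in range(L)]
    score = sum(MISMATCH_SCORES[s] for s in states)
    return DuplexAlignment(
        mirna=mirna, site=site, states=states, mismatch_score=score,
        duplex_mfe=duplex_energy(mirna, site),
        perfect_mfe=perfect_duplex_energy(mirna),
    )


def passes_filters(d: DuplexAlignment, strict: bool = True) -> tuple[dict[str, bool], bool]:
    """Per-rule verdicts and the overall pass for a scored duplex."""
    scores = [MISMATCH_SCORES[s] for s in d.states]
    mism = [s is PairClass.MISMATCH for s in d.states]
    L = len(d.states)

    def run_exceeds(flags: Sequence[bool], limit: int) -> bool:
        run = 0
        for f in flags:
            run = run + 1 if f else 0
            if run > limit:
                return True
        return False

    lo, hi = SEED_REGION
    seed_flags = mism[lo - 1:min(hi, L)]
    rules = {
        "rule1_total": d.mismatch_score <= MAX_TOTAL_SCORE,
        "rule2_adjacent": not run_exceeds(mism, MAX_ADJACENT_RUN),
        "rule3_seed_adjacent": not run_exceeds(seed_flags, 1),
        "rule4_center": not any(mism[p - 1] for p in CENTER_POSITIONS if p <= L),
        "rule5_seed_score": sum(scores[:min(12, L)]) <= MAX_SEED_SCORE,
        "rule6_energy": d.duplex_mfe <= 0.0 and abs(d.duplex_mfe) >= ENERGY_RATIO * abs(d.perfect_mfe),
    }
    overall = all(rules.values())
    if strict:
        overall = overall and d.mismatch_score <= STRICT_MAX_SCORE
    return rules, overall


# ---------------------------------------------------------------------------
# vectorised transcript scanning

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_CLASS_NUM = np.full((5, 5), 2, dtype=np.int8)  # 0 WC, 1 wobble, 2 mismatch
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1)):
    _CLASS_NUM[_a, _b] = 0
for _a, _b in ((2, 3), (3, 2)):
    _CLASS_NUM[_a, _b] = 1
_SCORE_NUM = np.array([0.0, 0.5, 1.0])
_CLASS_ENUM = [PairClass.WATSON_CRICK, PairClass.WOBBLE, PairClass.MISMATCH]


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def scan_transcripts(mirnas: dict[str, str], transcripts: dict[str, str],
                     strict: bool = True) -> list[TargetHit]:
    """Score every site of each miRNA's length on every transcript.

    Hits are windows passing all six rules (plus the strict cap when
    *strict*); they are sorted by (transcript, position) and, within one
    site, by ascending mismatch score so the least-mismatch miRNA leads
    its group.
    """
    hits: list[TargetHit] = []
    enc_tx = {tid: _encode(validate(to_rna(seq), "RNA")) for tid, seq in transcripts.items()}
    for mid in sorted(mirnas):
        mir = validate(to_rna(mirnas[mid]), "RNA")
        L = len(mir)
        mir_rev = _encode(mir[::-1])  # site index j faces miRNA position L-j
        for tid in sorted(enc_tx):
            tx = enc_tx[tid]
            if len(tx) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(tx, L)
            cls = _CLASS_NUM[mir_rev[None, :], windows]       # (n_windows, L), site order
            cls = cls[:, ::-1]                                 # column k = miRNA position k+1
            scores = _SCORE_NUM[cls]
            total = scores.sum(axis=1)
            ok = total <= MAX_TOTAL_SCORE
            if strict:
                ok &= total <= STRICT_MAX_SCORE
            mism = cls == 2
            run3 = mism[:, :-2] & mism[:, 1:-1] & mism[:, 2:]
            ok &= ~run3.any(axis=1)
            lo, hi = SEED_REGION
            seed = mism[:, lo - 1:min(hi, L)]
            ok &= ~(seed[:, :-1] & seed[:, 1:]).any(axis=1)
            for p in CENTER_POSITIONS:
                if p <= L:
                    ok &= ~mism[:, p - 1]
            ok &= scores[:, :min(12, L)].sum(axis=1) <= MAX_SEED_SCORE
            for p in np.nonzero(ok)[0]:
                site = to_rna("".join("ACGUN"[c] for c in tx[p:p + L]))
                d = score_duplex(mir, site)
                rules, overall = passes_filters(d, strict=strict)
                if overall:
                    hits.append(TargetHit(
                        mirna_id=mid, transcript_id=tid, start=int(p), end=int(p) + L,
                        alignment=d, passed_rules=rules,
                        strict_pass=d.mismatch_score <= STRICT_MAX_SCORE and all(rules.values())))
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.alignment.mismatch_score, h.mirna_id))
    return hits


def render_alignment(d: DuplexAlignment) -> str:
    """Three-line text rendering: miRNA 5'->3', glyphs, site 3'->5'.

    Vertical bars mark Watson-Crick pairs; wobbles and mismatches both
    display as spaces (display convention; wobbles still score 0.5 in the
    numeric rules).
    """
    glyphs = "".join("|" if s is PairClass.WATSON_CRICK else " " for s in d.states)
    return (f"miRNA  5' {d.mirna} 3'\n"
            f"          {glyphs}\n"
            f"target 3' {d.site[::-1]} 5'")


def parse_alignment(block: str) -> list[PairClass]:
    """Recover pairing states from a rendered block (round-trip helper)."""
    lines = block.split("\n")
    mirna = lines[0].split()[2]
    glyphs = lines[1][10:10 + len(mirna)]
    site_rev = lines[2].split()[2]
    states = []
    for i, g in enumerate(glyphs):
        if g == "|":
            states.append(PairClass.WATSON_CRICK)
        else:
            states.append(pair_class(mirna[i], site_rev[i]))
    return states


def write_hits(hits: Iterable[TargetHit], path: str) -> None:
    """TSV of hits with rendered alignments, grouped per target site."""
    with open(path, "w") as fh:
        fh.write("# miRNA targets; coordinates 0-based half-open on the transcript\n")
        fh.write("mirna_id\ttranscript_id\tstart\tend\tmismatch_score\tstrict_pass\talignment\n")
        for h in hits:
            aln = render_alignment(h.alignment).replace("\n", "\\n")
            fh.write(f"{h.mirna_id}\t{h.transcript_id}\t{h.start}\t{h.end}"
                     f"\t{h.alignment.mismatch_score}\t{h.strict_pass}\t{aln}\n")
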