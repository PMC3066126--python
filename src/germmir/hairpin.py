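"""Novel-miRNA prediction core: fold genomic flanks of unannotated reads
and evaluate hairpin candidate criteria.

A candidate read passes when (a) it folds into a stem-loop with the read
on (b) exactly one arm, (c) at most six unpaired nucleotides within the
miRNA/miRNA* duplex, (d) no terminal-loop residue or helix break inside
the miRNA or miRNA* spans, and (e) the numeric screens hold: MFE < 0 and
<= -20 kcal/mol, mature length 20-22 nt, miRNA-to-miRNA* distance
5-240 nt, and MFEI > 0.85 where

    MFEI = (|MFE| / precursor length x 100) / (G+C)%

The miRNA* span is derived from the predicted structure as the duplex
partner of the mature with 2-nt 3' overhangs on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .folding import FoldResult, fold, pair_table
from .mapping import GenomeIndex, GenomeLocus, MappedRead
from .sequence import gc_percent, to_rna
from .conserved import edit_distance, seed_identical

OVERHANG = 2       # nt of 3' overhang on each duplex strand
TRIM_PAD = 15      # nt of context kept around the duplex when trimming
WINDOW_PAD = 20    # nt upstream of the read in each anchored window
STAR_SLACK = 1     # +-nt tolerated when matching reads to the star locus


@dataclass(frozen=True)
class Thresholds:
    """Candidate screens; defaults are the published plant-miRNA values."""

    mfe_max: float = -20.0          # kcal/mol, precursor MFE must be <= this
    mfei_min: float = 0.85
    max_duplex_unpaired: int = 6
    min_loop_distance: int = 5      # nt between miRNA and miRNA*
    max_loop_distance: int = 240
    min_mature_len: int = 20
    max_mature_len: int = 22
    min_dominance: float = 0.5      # mature share of reads in the precursor
    # genomic context per anchored window; must exceed the maximal
    # mature-to-star separation (240 nt) plus a star and its overhang,
    # otherwise distal miRNA* partners can never be seen
    flank: int = 300


@dataclass
class MfeiInput:
    mfe: float
    length: int
    gc: float

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("length must be positive")
        if not 0.0 < self.gc <= 100.0:
            raise ValueError("MFEI undefined for G+C content of 0")


def mfei(x: MfeiInput) -> float:
    """Minimal folding free energy index: (|MFE|/length x 100)/(G+C)%."""
    return (abs(x.mfe) / x.length * 100.0) / x.gc


@dataclass
class HairpinCandidate:
    locus: GenomeLocus | None
    precursor: FoldResult
    mature_span: tuple[int, int]
    star_span: tuple[int, int] | None
    arm: str | None                      # "5p" | "3p"
    duplex_unpaired: int
    loop_distance: int
    mfe: float
    mfei: float
    au_percent: float
    criteria: dict[str, bool]
    accepted: bool
    read_id: str = ""
    star_read_count: int = 0
    reject_reason: str = ""

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_span
        return self.precursor.sequence[s:e]

    @property
    def star_sequence(self) -> str | None:
        if self.star_span is None:
            return None
        s, e = self.star_span
        return self.precursor.sequence[s:e]


@dataclass
class _StarDerivation:
    ok: bool
    reason: str = ""
    star_span: tuple[int, int] | None = None
    arm: str | None = None
    loop_distance: int = -1
    duplex_unpaired: int = 0
    clean: bool = True


def derive_star(partner: Sequence[int], mature_span: tuple[int, int]) -> _StarDerivation:
    """Locate the miRNA* span implied by a structure's pair table.

    Applies the duplex rule: the star 5' end faces mature position L-2 and
    the star 3' end extends two nucleotides past the partner of the mature
    5' end (2-nt 3' overhangs on both strands).
    """
    n = len(partner)
    s, e = mature_span
    paired = [i for i in range(s, e) if partner[i] >= 0]
    if not paired:
        return _StarDerivation(ok=False, reason="mature unpaired")
    if any(s <= partner[i] < e for i in paired):
        return _StarDerivation(ok=False, reason="loop overlap")
    below = [i for i in paired if partner[i] < s]
    above = [i for i in paired if partner[i] >= e]
    if below and above:
        return _StarDerivation(ok=False, reason="loop overlap")
    arm = "5p" if above else "3p"
    for i, j in zip(paired, paired[1:]):
        if partner[i] <= partner[j]:
            return _StarDerivation(ok=False, reason="helix break in mature")
    # multibranch between consecutive mature pairs
    clean = True
    for i, j in zip(paired, paired[1:]):
        for q in range(partner[j] + 1, partner[i]):
            if partner[q] >= 0 and not (i < partner[q] < j):
                clean = False
    p1 = paired[0]
    inner = [p for p in paired if p <= e - 1 - OVERHANG]
    p2 = inner[-1] if inner else paired[-1]
    star_left = partner[p2] - ((e - 1 - OVERHANG) - p2)
    star_right = partner[p1] + (p1 - s) + OVERHANG + 1
    star_left, star_right = max(0, star_left), min(n, star_right)
    if star_left >= star_right or (star_left < e and star_right > s):
        return _StarDerivation(ok=False, reason="loop overlap")
    # star residues must stay inside the duplex (no terminal loop, no
    # pairing out into other helices); the overhang regions are exempt
    for q in range(star_left, star_right):
        if partner[q] >= 0 and not (s - OVERHANG <= partner[q] < e + OVERHANG):
            clean = False
    unpaired = sum(1 for i in range(s, e) if partner[i] < 0)
    if arm == "5p":
        lm = paired[-1]
        loop_distance = partner[lm] - lm - 1
    else:
        lm = paired[0]
        loop_distance = lm - partner[lm] - 1
    return _StarDerivation(ok=True, star_span=(star_left, star_right), arm=arm,
                           loop_distance=loop_distance, duplex_unpaired=unpaired,
                           clean=clean)


def evaluate_candidate(window: FoldResult, read_span: tuple[int, int],
                       thresholds: Thresholds = Thresholds(),
                       locus: GenomeLocus | None = None,
                       read_id: str = "") -> HairpinCandidate:
    """Evaluate every candidate criterion for a read placed on a fold."""
    s, e = read_span
    if not (0 <= s < e <= len(window.sequence)):
        raise ValueError("read span outside the folded window")
    t = thresholds
    partner = pair_table(window.structure)
    d = derive_star(partner, read_span)
    gc = gc_percent(window.sequence)
    idx = mfei(MfeiInput(mfe=window.mfe, length=len(window.sequence), gc=gc)) if gc > 0 else 0.0
    mature_len = e - s
    # criteria that presuppose a located miRNA* are vacuously true when the
    # structural derivation itself failed; "stem"/"one_arm" carry that failure
    criteria = {
        "stem": d.ok,
        "one_arm": d.ok or d.reason != "loop overlap",
        "duplex_unpaired": not d.ok or d.duplex_unpaired <= t.max_duplex_unpaired,
        "clean_duplex": not d.ok or d.clean,
        "negative_mfe": window.mfe < 0.0 and window.mfe <= t.mfe_max,
        "mature_length": t.min_mature_len <= mature_len <= t.max_mature_len,
        "loop_distance": not d.ok or t.min_loop_distance <= d.loop_distance <= t.max_loop_distance,
        "mfei": idx > t.mfei_min,
    }
    accepted = all(criteria.values())
    return HairpinCandidate(
        locus=locus, precursor=window, mature_span=read_span,
        star_span=d.star_span, arm=d.arm, duplex_unpaired=d.duplex_unpaired,
        loop_distance=d.loop_distance, mfe=window.mfe, mfei=idx,
        au_percent=100.0 - gc, criteria=criteria, accepted=accepted,
        read_id=read_id, reject_reason="" if accepted else (d.reason or "criteria failed"),
    )


# ---------------------------------------------------------------------------
# genome-anchored candidate extraction

def extract_windows(locus: GenomeLocus, index: GenomeIndex,
                    flank: int = Thresholds.flank,
                    pad: int = WINDOW_PAD) -> list[tuple[str, tuple[int, int], GenomeLocus]]:
    """Candidate precursor windows around a mapped read.

    Two anchors: the read near the window 5' end (star expected downstream)
    and near the 3' end (star upstream), each with up to *flank* nt of
    genomic context, strand-adjusted and transcribed to RNA.  Returns
    ``(window_rna, read_span_in_window, window_locus)`` triples.
    """
    chrom_len = len(index.genome[locus.chrom])
    if locus.strand == "+":
        bounds = [(locus.start - pad, locus.end + flank),
                  (locus.start - flank, locus.end + pad)]
    else:
        bounds = [(locus.start - flank, locus.end + pad),
                  (locus.start - pad, locus.end + flank)]
    out, seen = [], set()
    for a, b in bounds:
        a, b = max(0, a), min(chrom_len, b)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        wlocus = GenomeLocus(locus.chrom, a, b, locus.strand)
        window = to_rna(index.fetch(wlocus))
        if locus.strand == "+":
            span = (locus.start - a, locus.end - a)
        else:
            span = (b - locus.end, b - locus.start)
        out.append((window, span, wlocus))
    return out


def _sub_locus(wlocus: GenomeLocus, lo: int, hi: int) -> GenomeLocus:
    if wlocus.strand == "+":
        return GenomeLocus(wlocus.chrom, wlocus.start + lo, wlocus.start + hi, "+")
    return GenomeLocus(wlocus.chrom, wlocus.end - hi, wlocus.end - lo, "-")


def candidates_for_read(mapped_read: MappedRead, index: GenomeIndex,
                        thresholds: Thresholds = Thresholds(),
                        engine=None) -> list[HairpinCandidate]:
    """All evaluated hairpin candidates for a read's mapped loci.

    Each anchored window is folded; when a miRNA* can be located, the
    precursor is trimmed to the duplex-enclosing region (plus a small
    pad), refolded, and all criteria are evaluated on the trimmed fold so
    the reported statistics describe the precursor itself rather than the
    scanning window.
    """
    out = []
    for locus in mapped_read.loci:
        for window, span, wlocus in extract_windows(locus, index, flank=thresholds.flank):
            wfold = fold(window, engine=engine)
            d = derive_star(pair_table(wfold.structure), span)
            if not d.ok:
                out.append(evaluate_candidate(wfold, span, thresholds,
                                              locus=wlocus, read_id=mapped_read.read.read_id))
                continue
            lo = max(0, min(span[0], d.star_span[0]) - TRIM_PAD)
            hi = min(len(window), max(span[1], d.star_span[1]) + TRIM_PAD)
            pfold = fold(window[lo:hi], engine=engine)
            cand = evaluate_candidate(pfold, (span[0] - lo, span[1] - lo), thresholds,
                                      locus=_sub_locus(wlocus, lo, hi),
                                      read_id=mapped_read.read.read_id)
            out.append(cand)
    return out


def best_candidate(candidates: Iterable[HairpinCandidate]) -> HairpinCandidate | None:
    """Highest-MFEI accepted candidate (ties: leftmost precursor start)."""
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        return None
    return min(accepted, key=lambda c: (-c.mfei, c.locus.start if c.locus else 0))


def star_genome_locus(candidate: HairpinCandidate) -> GenomeLocus | None:
    if candidate.star_span is None or candidate.locus is None:
        return None
    s, e = candidate.star_span
    loc = candidate.locus
    if loc.strand == "+":
        return GenomeLocus(loc.chrom, loc.start + s, loc.start + e, "+")
    return GenomeLocus(loc.chrom, loc.end - e, loc.end - s, "-")


def find_star_reads(candidate: HairpinCandidate, mapped: Iterable[MappedRead],
                    slack: int = STAR_SLACK) -> HairpinCandidate:
    """Count reads mapping at the star locus (+-*slack* nt at each end)."""
    star = star_genome_locus(candidate)
    if star is None:
        return candidate
    count = 0
    for m in mapped:
        for locus in m.loci:
            if (locus.chrom == star.chrom and locus.strand == star.strand
                    and abs(locus.start - star.start) <= slack
                    and abs(locus.end - star.end) <= slack):
                count += m.read.count
                break
    return replace(candidate, star_read_count=count)


def mature_dominance(candidate: HairpinCandidate, mapped: Iterable[MappedRead]) -> float:
    """Fraction of precursor-mapped read counts carried by the mature read."""
    loc = candidate.locus
    if loc is None:
        return 1.0
    total = 0
    mature = 0
    for m in mapped:
        for l in m.loci:
            if l.chrom == loc.chrom and l.start < loc.end and l.end > loc.start:
                total += m.read.count
                if m.read.read_id == candidate.read_id:
                    mature += m.read.count
                break
    return mature / total if total else 1.0


def apply_dominance(candidate: HairpinCandidate, mapped: Iterable[MappedRead],
                    thresholds: Thresholds = Thresholds()) -> HairpinCandidate:
    """Add the mature-dominance criterion and refresh the verdict."""
    frac = mature_dominance(candidate, mapped)
    criteria = dict(candidate.criteria)
    criteria["dominant"] = frac >= thresholds.min_dominance
    accepted = all(criteria.values())
    reason = candidate.reject_reason
    if not accepted and not reason:
        reason = "mature not dominant"
    return replace(candidate, criteria=criteria, accepted=accepted,
                   reject_reason="" if accepted else reason)


def resolve_overlaps(candidates: list[HairpinCandidate]) -> list[HairpinCandidate]:
    """Keep one accepted candidate per overlapping precursor locus cluster
    (highest MFEI; ties broken by the smaller start coordinate)."""
    accepted = sorted((c for c in candidates if c.accepted and c.locus is not None),
                      key=lambda c: (c.locus.chrom, c.locus.strand, c.locus.start))
    kept: list[HairpinCandidate] = []
    for cand in accepted:
        merged = False
        for i, prev in enumerate(kept):
            if (prev.locus.chrom == cand.locus.chrom
                    and prev.locus.strand == cand.locus.strand
                    and cand.locus.start < prev.locus.end
                    and cand.locus.end > prev.locus.start):
                if (cand.mfei, -cand.locus.start) > (prev.mfei, -prev.locus.start):
                    kept[i] = cand
                merged = True
                break
        if not merged:
            kept.append(cand)
    return kept


def group_families(matures: dict[str, str]) -> list[set[str]]:
    """Cluster mature sequences into families: identical seed (nt 2-8) and
    total edit distance <= 2 merges two matures."""
    ids = sorted(matures)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            sa, sb = matures[a], matures[b]
            if len(sa) >= 8 and len(sb) >= 8 and seed_identical(sa, sb) \
                    and 0 <= edit_distance(sa, sb, limit=2) <= 2:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: sorted(g)[0])
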