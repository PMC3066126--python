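"""Cross-library confirmation of hairpin candidates.

A candidate is confirmed when the other, independently processed library
contains a candidate with the identical precursor sequence, identical
mature sequence and identical genomic locus.  Confirmed pairs are
additionally flagged expression-consistent when their per-million
normalised mature counts differ by at most a configurable fold change
(an annotation, not a filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .hairpin import HairpinCandidate
from .mapping import GenomeLocus

EXPR_FOLD_LIMIT = 4.0


@dataclass
class LibraryCandidateSet:
    library_id: str
    candidates: list[HairpinCandidate]
    #: mature read count per candidate identity key
    counts: dict[tuple, int] = field(default_factory=dict)
    total_reads: int = 0

    def __post_init__(self):
        keys = [identity_key(c) for c in self.candidates]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate candidate loci within library {self.library_id}")


def identity_key(c: HairpinCandidate) -> tuple:
    loc = c.locus
    if loc is None:
        raise ValueError("candidate without a genomic locus cannot be compared")
    return (c.precursor.sequence, c.mature_sequence,
            loc.chrom, loc.start, loc.end, loc.strand)


@dataclass
class ConfirmedCandidate:
    candidate: HairpinCandidate
    count_a: int
    count_b: int
    expression_consistent: bool


def intersect_candidates(a: LibraryCandidateSet, b: LibraryCandidateSet,
                         expr_fold_limit: float = EXPR_FOLD_LIMIT) -> list[ConfirmedCandidate]:
    """Candidates identical between the two libraries (symmetric in a/b)."""
    chroms_a = {c.locus.chrom for c in a.candidates if c.locus}
    chroms_b = {c.locus.chrom for c in b.candidates if c.locus}
    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        raise ValueError("candidate sets share no chromosome names; "
                         "were they produced on the same genome build?")
    keys_b = {identity_key(c): c for c in b.candidates}
    confirmed = []
    for cand in a.candidates:
        key = identity_key(cand)
        if key not in keys_b:
            continue
        na = a.counts.get(key, 0)
        nb = b.counts.get(key, 0)
        consistent = True
        if na > 0 and nb > 0 and a.total_reads and b.total_reads:
            ra = na / a.total_reads
            rb = nb / b.total_reads
            fold = max(ra, rb) / min(ra, rb)
            consistent = fold <= expr_fold_limit
        confirmed.append(ConfirmedCandidate(candidate=cand, count_a=na, count_b=nb,
                                            expression_consistent=consistent))
    confirmed.sort(key=lambda c: (c.candidate.locus.chrom, c.candidate.locus.start))
    return confirmed


def write_confirmed_gff3(confirmed: Iterable[ConfirmedCandidate], path: str) -> None:
    from .report import write_candidates_gff3

    write_candidates_gff3([c.candidate for c in confirmed], path)
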