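"""Known/conserved miRNA identification against a miRBase-style reference.

A read is reported as a hit when its unit-cost edit distance
(substitutions and indels each costing 1, i.e. "gaps count as
mismatches") to a reference mature sequence is at most two.  It is called
*conserved* only when it matches the mature perfectly AND occurs exactly
within the mature's linked hairpin precursor.  Seed logic (nucleotides
2-8, 1-based from the miRNA 5' end) supports cross-species comparisons.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import edlib
from Bio import SeqIO

from .preprocess import UniqueRead
from .sequence import to_rna

logger = logging.getLogger(__name__)

MAX_MISMATCH_DEFAULT = 2
SEED_START, SEED_END = 2, 8  # 1-based inclusive


def edit_distance(a: str, b: str, limit: int | None = None) -> int:
    """Unit-cost Levenshtein distance (edlib); -1 if above *limit*."""
    k = -1 if limit is None else limit
    return edlib.align(a, b, task="distance", mode="NW", k=k)["editDistance"]


@dataclass
class KnownMiRNARef:
    """Mature and hairpin records with name-based mature->hairpin linkage."""

    matures: dict[str, str]
    hairpins: dict[str, str]
    links: dict[str, list[str]] = field(default_factory=dict)

    @staticmethod
    def _stem(name: str) -> str:
        # zma-miR156a-5p / zma-MIR156a -> zma-mir156a
        return re.sub(r"[-_.](5p|3p|star|\d+)$", "", name.lower().replace("mir", "mir"))

    @classmethod
    def from_records(cls, matures: dict[str, str], hairpins: dict[str, str]) -> "KnownMiRNARef":
        matures = {n: to_rna(s) for n, s in matures.items()}
        hairpins = {n: to_rna(s) for n, s in hairpins.items()}
        stems = {}
        for hname in hairpins:
            stems.setdefault(cls._stem(hname), []).append(hname)
        links: dict[str, list[str]] = {}
        for mname, mseq in matures.items():
            linked = stems.get(cls._stem(mname), [])
            links[mname] = sorted(linked)
            if not linked:
                logger.warning("mature %s has no linked hairpin record", mname)
                continue
            contained = any(
                edlib.align(mseq, hairpins[h], task="distance", mode="HW", k=2)["editDistance"] >= 0
                for h in linked)
            if not contained:
                logger.warning("mature %s not found (<=2 mismatches) in its linked hairpins", mname)
        return cls(matures=matures, hairpins=hairpins, links=links)

    @classmethod
    def from_fasta(cls, mature_path: str, hairpin_path: str) -> "KnownMiRNARef":
        matures = {r.id: str(r.seq) for r in SeqIO.parse(mature_path, "fasta")}
        hairpins = {r.id: str(r.seq) for r in SeqIO.parse(hairpin_path, "fasta")}
        return cls.from_records(matures, hairpins)


@dataclass(frozen=True)
class ConservedHit:
    read_id: str
    mature_name: str
    mismatches: int
    perfect_mature: bool
    perfect_hairpin: bool
    conserved_call: bool


def match_known(reads: Iterable[UniqueRead], ref: KnownMiRNARef,
                max_mismatch: int = MAX_MISMATCH_DEFAULT) -> list[ConservedHit]:
    """All read/mature pairs within *max_mismatch* edits.

    ``conserved_call`` requires distance 0 to the mature and exact
    substring occurrence of the read in a linked hairpin.
    """
    hits = []
    for read in reads:
        for mname in sorted(ref.matures):
            d = edit_distance(read.sequence, ref.matures[mname], limit=max_mismatch)
            if d < 0:
                continue
            perfect = d == 0
            in_hairpin = perfect and any(
                read.sequence in ref.hairpins[h] for h in ref.links.get(mname, ()))
            hits.append(ConservedHit(read_id=read.read_id, mature_name=mname,
                                     mismatches=d, perfect_mature=perfect,
                                     perfect_hairpin=in_hairpin,
                                     conserved_call=perfect and in_hairpin))
    return hits


def match_cross_species(reads: Iterable[UniqueRead], other_matures: dict[str, str],
                        max_mismatch: int = MAX_MISMATCH_DEFAULT) -> list[ConservedHit]:
    """Hits against a non-native mature set ("conserved in other species").

    No hairpin containment is required, so ``conserved_call`` stays False.
    """
    hits = []
    other = {n: to_rna(s) for n, s in other_matures.items()}
    for read in reads:
        for mname in sorted(other):
            d = edit_distance(read.sequence, other[mname], limit=max_mismatch)
            if d >= 0:
                hits.append(ConservedHit(read_id=read.read_id, mature_name=mname,
                                         mismatches=d, perfect_mature=d == 0,
                                         perfect_hairpin=False, conserved_call=False))
    return hits


def seed_region(seq: str) -> str:
    """Nucleotides 2-8 (1-based, inclusive) from the 5' end."""
    if len(seq) < SEED_END:
        raise ValueError(f"sequence shorter than {SEED_END} nt has no seed region")
    return seq[SEED_START - 1:SEED_END]


def seed_identical(a: str, b: str) -> bool:
    """True iff the two sequences share an identical seed (nt 2-8)."""
    return seed_region(a) == seed_region(b)
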