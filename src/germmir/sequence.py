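"""Nucleic-acid alphabet, complementarity and composition primitives.

Conventions used throughout the package:

* small-RNA reads, precursors and transcripts are stored as RNA (``U``);
* genomes are stored as DNA (``T``);
* conversion between the two is explicit (:func:`to_rna` / :func:`to_dna`);
* ``N`` never pairs and is excluded from composition statistics.
"""

from __future__ import annotations

from enum import Enum

DNA_BASES = frozenset("ACGTN")
RNA_BASES = frozenset("ACGUN")

_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """Sequence contains characters outside the expected alphabet."""


class CompositionError(ValueError):
    """Composition statistic undefined (e.g. all-N sequence)."""


class PairClass(Enum):
    """Classification of a single (RNA) base pair."""

    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def guess_moltype(seq: str) -> str:
    """Return ``"RNA"`` or ``"DNA"``; reject sequences mixing T and U."""
    has_t = "T" in seq
    has_u = "U" in seq
    if has_t and has_u:
        raise AlphabetError("sequence mixes T and U")
    return "DNA" if has_t else "RNA"


def validate(seq: str, moltype: str = "RNA") -> str:
    """Upper-case *seq* and check it against the DNA or RNA alphabet."""
    if not seq:
        raise AlphabetError("empty sequence")
    seq = seq.upper()
    alphabet = RNA_BASES if moltype == "RNA" else DNA_BASES
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(f"invalid {moltype} characters: {sorted(bad)}")
    return seq


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str, moltype: str | None = None) -> str:
    """Reverse complement preserving the molecule type.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if moltype is None:
        moltype = guess_moltype(seq.upper())
    seq = validate(seq, moltype)
    table = _RNA_COMPLEMENT if moltype == "RNA" else _DNA_COMPLEMENT
    return seq.translate(table)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content in percent, ignoring ``N`` residues entirely."""
    seq = seq.upper()
    denom = sum(1 for c in seq if c != "N")
    if denom == 0:
        raise CompositionError("composition undefined for all-N sequence")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / denom


def au_percent(seq: str) -> float:
    """A+U (or A+T) content in percent; complements :func:`gc_percent`."""
    return 100.0 - gc_percent(seq)


def pair_class(a: str, b: str) -> PairClass:
    """Classify the pair of RNA bases *a*, *b* (symmetric in its arguments).

    A:U and G:C are Watson-Crick, G:U/U:G is a wobble, everything else
    (including any pair involving N) is a mismatch.
    """
    a, b = a.upper(), b.upper()
    for base in (a, b):
        if base == "N":
            return PairClass.MISMATCH
        if base not in RNA_BASES:
            raise AlphabetError(f"not an RNA base: {base!r}")
    if (a, b) in _WC_PAIRS:
        return PairClass.WATSON_CRICK
    if (a, b) in _WOBBLE_PAIRS:
        return PairClass.WOBBLE
    return PairClass.MISMATCH
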