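"""Simplified nearest-neighbor energetics shared by duplex scoring and the
built-in fallback folding engine.

The model assigns every admissible base pair an intrinsic stacking
contribution (kcal/mol, negative = stabilising)::

    G:C  -1.70      A:U  -0.55      G:U (wobble)  -0.25

and scores a stack of two adjacent pairs as the sum of the two
contributions, so e.g. a GG/CC stack is -3.4 kcal/mol and an AA/UU stack
-1.1 kcal/mol, reproducing the ordering (and roughly the magnitude) of the
Turner nearest-neighbor parameters while staying fully symmetric and
dependency-free.  No dangling ends, no loop penalties for duplexes.

Energies from this module are only ever used (a) as a ratio between a
duplex and the perfect-complement duplex of the same miRNA, and (b) inside
the fallback secondary-structure engine; both uses are insensitive to the
absolute calibration.
"""

from __future__ import annotations

from .sequence import PairClass, pair_class, reverse_complement

#: intrinsic stacking contribution per admissible pair (kcal/mol)
PAIR_STACK = {
    PairClass.WATSON_CRICK: {"GC": -1.70, "CG": -1.70, "AU": -0.55, "UA": -0.55},
    PairClass.WOBBLE: {"GU": -0.25, "UG": -0.25},
}


def pair_contribution(a: str, b: str) -> float:
    """Stacking contribution of the pair (a, b); 0.0 for a mismatch."""
    cls = pair_class(a, b)
    if cls is PairClass.MISMATCH:
        return 0.0
    return PAIR_STACK[cls][a + b]


def duplex_energy(mirna: str, site: str) -> float:
    """Energy (kcal/mol) of the ungapped antiparallel miRNA/site duplex.

    *mirna* and *site* are both 5'->3' RNA strings of equal length; miRNA
    position ``i`` (0-based from the 5' end) faces site position
    ``L-1-i``.  Adjacent paired positions contribute one stack each;
    mismatched positions contribute nothing.  The result is always <= 0.
    """
    if len(mirna) != len(site):
        raise ValueError("duplex strands must have equal length")
    L = len(mirna)
    contrib = [pair_contribution(mirna[i], site[L - 1 - i]) for i in range(L)]
    paired = [c != 0.0 for c in contrib]
    energy = 0.0
    for i in range(L - 1):
        if paired[i] and paired[i + 1]:
            energy += contrib[i] + contrib[i + 1]
    return min(energy, 0.0)


def perfect_duplex_energy(mirna: str) -> float:
    """Energy of *mirna* bound to its exact reverse complement."""
    return duplex_energy(mirna, reverse_complement(mirna, "RNA"))
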