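"""RNA secondary-structure prediction behind a pluggable engine contract.

An engine takes an RNA string and returns ``(dot_bracket, mfe_kcal_mol)``.
The default engine binds to the ViennaRNA package when its python bindings
are importable; otherwise a built-in deterministic pair-energy dynamic
program (Nussinov-style recursion minimising the additive stack model of
:mod:`germmir.thermo`, hairpin loops >= 3 nt, no dangles) keeps the whole
pipeline runnable with zero external dependencies.  Absolute energies are
engine-dependent; all downstream criteria go through user-visible
thresholds (MFE <= -20 kcal/mol, MFEI > 0.85), never through
engine-specific constants.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

from .sequence import pair_class, PairClass, validate

logger = logging.getLogger(__name__)

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 2000


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its predicted minimum-free-energy structure."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self):
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure/sequence length mismatch")


def pair_table(structure: str) -> list[int]:
    """0-based partner index per position (-1 = unpaired) from dot-bracket."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return partner


class ViennaEngine:
    """Minimum-free-energy folding via the ViennaRNA python bindings."""

    name = "viennarna"

    def __init__(self):
        import RNA  # noqa: F401 -- fails here if bindings are absent

        self._rna = RNA

    def fold(self, seq: str) -> tuple[str, float]:
        structure, mfe = self._rna.fold(seq)
        return structure, float(mfe)

    def energy_of_structure(self, seq: str, structure: str) -> float:
        """Re-score a given structure from the engine's parameter table."""
        return float(self._rna.energy_of_struct(seq, structure))


class BuiltinEngine:
    """Deterministic pair-energy DP fallback (no external dependencies).

    Minimises the sum of pair energies (G:C -3.4, A:U -1.1, G:U -0.5
    kcal/mol, i.e. twice the per-pair contribution of
    :mod:`germmir.thermo`) over nested structures with hairpin loops of at
    least ``min_loop`` unpaired nucleotides.  Cubic time; intended for
    precursor-scale sequences, not genomes.
    """

    name = "builtin"
    min_loop = 3

    @staticmethod
    def _pair_energy(a: str, b: str) -> float:
        cls = pair_class(a, b)
        if cls is PairClass.WATSON_CRICK:
            return -3.4 if a in "GC" else -1.1
        if cls is PairClass.WOBBLE:
            return -0.5
        return 0.0

    def fold(self, seq: str) -> tuple[str, float]:
        n = len(seq)
        loop = self.min_loop
        E = [[0.0] * n for _ in range(n)]
        for span in range(loop + 1, n):
            for i in range(n - span):
                j = i + span
                best = E[i + 1][j]  # i unpaired
                e_ij = self._pair_energy(seq[i], seq[j])
                if e_ij < 0.0:
                    best = min(best, e_ij + (E[i + 1][j - 1] if j - i > 1 else 0.0))
                for k in range(i + loop + 1, j):  # bifurcation
                    best = min(best, E[i][k] + E[k + 1][j])
                E[i][j] = best
        structure = ["."] * n
        self._traceback(seq, E, 0, n - 1, structure)
        return "".join(structure), round(E[0][n - 1], 2)

    def _traceback(self, seq, E, i, j, structure):
        stack = [(i, j)]
        loop = self.min_loop
        while stack:
            i, j = stack.pop()
            if j - i <= loop:
                continue
            if E[i][j] == E[i + 1][j]:
                stack.append((i + 1, j))
                continue
            e_ij = self._pair_energy(seq[i], seq[j])
            inner = E[i + 1][j - 1] if j - i > 1 else 0.0
            if e_ij < 0.0 and abs(E[i][j] - (e_ij + inner)) < 1e-9:
                structure[i], structure[j] = "(", ")"
                stack.append((i + 1, j - 1))
                continue
            for k in range(i + loop + 1, j):
                if abs(E[i][j] - (E[i][k] + E[k + 1][j])) < 1e-9:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break


@functools.lru_cache(maxsize=1)
def default_engine():
    try:
        return ViennaEngine()
    except ImportError:  # pragma: no cover - exercised only without ViennaRNA
        logger.warning("ViennaRNA bindings unavailable; using built-in folding engine")
        return BuiltinEngine()


def fold(seq: str, engine=None) -> FoldResult:
    """Fold an RNA sequence into its minimum-free-energy structure."""
    seq = validate(seq, "RNA")
    if not MIN_FOLD_LEN <= len(seq) <= MAX_FOLD_LEN:
        raise ValueError(f"fold input length {len(seq)} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    engine = engine or default_engine()
    structure, mfe = engine.fold(seq)
    return FoldResult(sequence=seq, structure=structure, mfe=mfe)
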