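"""Perfect-match placement of unique reads on both genome strands.

Reads are 18-30 nt, so an exact k-mer prefix index over the forward genome
strand resolves every hit directly: a read maps at ``(chrom, p, +)`` when
the genome substring equals the read, and at ``(chrom, p, -)`` when it
equals the read's reverse complement.  Reads hitting more loci than
``max_loci`` are flagged as highly repetitive and excluded from downstream
hairpin prediction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .preprocess import UniqueRead
from .sequence import reverse_complement, to_dna

INDEX_K = 18  # reads are never shorter after length filtering
MAX_LOCI_DEFAULT = 20


@dataclass(frozen=True, order=True)
class GenomeLocus:
    """Strand-aware 0-based half-open interval on a named reference."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class MappedRead:
    read: UniqueRead
    loci: list[GenomeLocus]


@dataclass
class MappingResult:
    mapped: list[MappedRead] = field(default_factory=list)
    unmapped: list[UniqueRead] = field(default_factory=list)
    repetitive: list[MappedRead] = field(default_factory=list)


class GenomeIndex:
    """Exact k-mer prefix index over the forward strand of a genome."""

    def __init__(self, genome: dict[str, str], k: int = INDEX_K):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name in sorted(self.genome):
            seq = self.genome[name]
            for p in range(len(seq) - k + 1):
                self._index[seq[p:p + k]].append((name, p))

    def find(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand start positions of an exact full-length match."""
        if len(query) < self.k:
            raise ValueError(f"query shorter than index k={self.k}")
        hits = []
        for name, p in self._index.get(query[:self.k], ()):
            if self.genome[name][p:p + len(query)] == query:
                hits.append((name, p))
        return hits

    def fetch(self, locus: GenomeLocus) -> str:
        """Strand-adjusted genomic DNA for a locus (minus strand revcomped)."""
        seq = self.genome[locus.chrom][locus.start:locus.end]
        return reverse_complement(seq, "DNA") if locus.strand == "-" else seq


def map_reads(reads: Iterable[UniqueRead], genome: dict[str, str] | GenomeIndex,
              max_loci: int = MAX_LOCI_DEFAULT) -> MappingResult:
    """Map unique reads to all exact full-length loci on either strand.

    Loci are reported in deterministic (chrom, start, strand) order; the
    minus-strand locus of a read covers the interval whose reverse
    complement equals the read.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    result = MappingResult()
    for read in sorted(reads, key=lambda r: (r.read_id, r.sequence)):
        dna = to_dna(read.sequence)
        loci = [GenomeLocus(c, p, p + len(dna), "+") for c, p in index.find(dna)]
        rc = reverse_complement(dna, "DNA")
        loci += [GenomeLocus(c, p, p + len(dna), "-") for c, p in index.find(rc)]
        loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
        if not loci:
            result.unmapped.append(read)
        elif len(loci) > max_loci:
            result.repetitive.append(MappedRead(read=read, loci=loci))
        else:
            result.mapped.append(MappedRead(read=read, loci=loci))
    return result


def write_bed(mapped: Iterable[MappedRead], path: str) -> None:
    """BED6 output: name=read_id, score=read count."""
    with open(path, "w") as fh:
        for m in mapped:
            for locus in m.loci:
                fh.write(f"{locus.chrom}\t{locus.start}\t{locus.end}"
                         f"\t{m.read.read_id}\t{m.read.count}\t{locus.strand}\n")
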