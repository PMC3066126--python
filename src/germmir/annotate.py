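"""Partition genome-mapped reads into annotation classes.

Reproduces the structure of a small-RNA classification table: noncoding
RNA classes (rRNA, tRNA, snoRNA, snRNA, siRNA), protein-coding
exon/intron sense/antisense classes, known/novel miRNA and "other".
A read whose sequence occurs as an exact substring (either strand) of a
class reference FASTA gets that class; ties resolve by the fixed priority
rRNA > tRNA > snoRNA > snRNA > siRNA > gene-model classes.  miRNA classes
are assigned afterwards by the conserved/hairpin stages and override
"other".
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .mapping import MappedRead
from .preprocess import UniqueRead
from .sequence import reverse_complement, to_rna


class ReadClass(Enum):
    snoRNA = "snoRNA"
    snRNA = "snRNA"
    tRNA = "tRNA"
    rRNA = "rRNA"
    siRNA = "siRNA"
    exon_sense = "exon_sense"
    exon_antisense = "exon_antisense"
    intron_sense = "intron_sense"
    intron_antisense = "intron_antisense"
    miRNA_known = "miRNA_known"
    miRNA_novel = "miRNA_novel"
    other = "other"


NCRNA_PRIORITY = [ReadClass.rRNA, ReadClass.tRNA, ReadClass.snoRNA,
                  ReadClass.snRNA, ReadClass.siRNA]
GENE_PRIORITY = [ReadClass.exon_sense, ReadClass.exon_antisense,
                 ReadClass.intron_sense, ReadClass.intron_antisense]

#: Table row order for summaries
TABLE_ORDER = [ReadClass.snoRNA, ReadClass.snRNA, ReadClass.tRNA, ReadClass.rRNA,
               ReadClass.siRNA, ReadClass.exon_antisense, ReadClass.exon_sense,
               ReadClass.intron_antisense, ReadClass.intron_sense,
               ReadClass.miRNA_known, ReadClass.miRNA_novel, ReadClass.other]


class GeneModel:
    """Exon intervals and gene extents loaded from GFF3 (via gffutils)."""

    def __init__(self, exons: list[tuple[str, int, int, str]],
                 genes: list[tuple[str, int, int, str]]):
        # 0-based half-open internally
        self.exons = exons
        self.genes = genes

    @classmethod
    def from_gff3(cls, path: str) -> "GeneModel":
        import gffutils

        db = gffutils.create_db(path, dbfn=":memory:", force=True,
                                merge_strategy="create_unique", keep_order=True)
        exons, genes = [], []
        for f in db.features_of_type("exon"):
            exons.append((f.seqid, f.start - 1, f.end, f.strand))  # GFF is 1-based inclusive
        for f in db.features_of_type("gene"):
            genes.append((f.seqid, f.start - 1, f.end, f.strand))
        return cls(exons=exons, genes=genes)

    def classify_locus(self, chrom: str, start: int, end: int, strand: str) -> ReadClass | None:
        hit = None
        for c, s, e, gstrand in self.exons:
            if c == chrom and start < e and end > s:
                cls = ReadClass.exon_sense if strand == gstrand else ReadClass.exon_antisense
                hit = _higher_priority(hit, cls)
        if hit is not None:
            return hit
        for c, s, e, gstrand in self.genes:
            if c == chrom and start < e and end > s:
                cls = ReadClass.intron_sense if strand == gstrand else ReadClass.intron_antisense
                hit = _higher_priority(hit, cls)
        return hit


_PRIORITY_RANK = {cls: i for i, cls in enumerate(NCRNA_PRIORITY + GENE_PRIORITY)}


def _higher_priority(a: ReadClass | None, b: ReadClass | None) -> ReadClass | None:
    if a is None:
        return b
    if b is None:
        return a
    return a if _PRIORITY_RANK[a] <= _PRIORITY_RANK[b] else b


def _build_ncrna_lookup(ncrna_refs: Mapping[str, Iterable[str]]) -> list[tuple[ReadClass, list[str]]]:
    lookup = []
    refs = {k: [to_rna(s).upper() for s in v] for k, v in ncrna_refs.items()}
    valid = {c.value for c in NCRNA_PRIORITY}
    unknown = set(refs) - valid
    if unknown:
        raise ValueError(f"unknown ncRNA class keys: {sorted(unknown)}; expected {sorted(valid)}")
    for cls in NCRNA_PRIORITY:
        if cls.value in refs:
            lookup.append((cls, refs[cls.value]))
    return lookup


def classify_reads(mapped: Iterable[MappedRead],
                   ncrna_refs: Mapping[str, Iterable[str]],
                   gene_model: GeneModel | None = None) -> dict[str, ReadClass]:
    """Assign exactly one class to every mapped read.

    ``ncrna_refs`` maps a class name ("rRNA", "tRNA", "snoRNA", "snRNA",
    "siRNA") to an iterable of reference sequences.  Substring matching is
    strand-agnostic.  When no gene model is given, gene-model classes are
    skipped.  Reads matching nothing are "other" (miRNA calls come later).
    """
    lookup = _build_ncrna_lookup(ncrna_refs)
    classes: dict[str, ReadClass] = {}
    for m in mapped:
        seq = m.read.sequence
        rc = reverse_complement(seq, "RNA")
        assigned: ReadClass | None = None
        for cls, refseqs in lookup:
            if any(seq in ref or rc in ref for ref in refseqs):
                assigned = cls
                break
        if assigned is None and gene_model is not None:
            for locus in m.loci:
                assigned = _higher_priority(
                    assigned,
                    gene_model.classify_locus(locus.chrom, locus.start, locus.end, locus.strand))
        classes[m.read.read_id] = assigned or ReadClass.other
    return classes


def apply_mirna_calls(classes: dict[str, ReadClass], known_ids: Iterable[str] = (),
                      novel_ids: Iterable[str] = ()) -> dict[str, ReadClass]:
    """Override "other" with miRNA classes decided by downstream stages."""
    out = dict(classes)
    for rid in known_ids:
        if out.get(rid) is ReadClass.other:
            out[rid] = ReadClass.miRNA_known
    for rid in novel_ids:
        if out.get(rid) is ReadClass.other:
            out[rid] = ReadClass.miRNA_novel
    return out


def summarize_classes(classes: Mapping[str, ReadClass],
                      reads: Iterable[UniqueRead]) -> pd.DataFrame:
    """Distinct/total tallies per class, with fractions of the grand totals."""
    counts = {r.read_id: r.count for r in reads}
    missing = set(classes) - set(counts)
    if missing:
        raise ValueError(f"classified read ids missing from read set: {sorted(missing)[:3]}")
    distinct = {cls: 0 for cls in TABLE_ORDER}
    total = {cls: 0 for cls in TABLE_ORDER}
    for rid, cls in classes.items():
        distinct[cls] += 1
        total[cls] += counts[rid]
    grand_d = sum(distinct.values())
    grand_t = sum(total.values())
    rows = [
        {
            "class": cls.value,
            "distinct_count": distinct[cls],
            "total_count": total[cls],
            "distinct_fraction": distinct[cls] / grand_d if grand_d else 0.0,
            "total_fraction": total[cls] / grand_t if grand_t else 0.0,
        }
        for cls in TABLE_ORDER
    ]
    return pd.DataFrame(rows)
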