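"""Writers for the pipeline's human-facing outputs.

All genomic text formats use 1-based inclusive coordinates (GFF3) with a
header line saying so; internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from typing import Iterable

from .hairpin import HairpinCandidate, star_genome_locus


def write_candidates_gff3(candidates: Iterable[HairpinCandidate], path: str) -> None:
    """Precursor, mature and star features for accepted candidates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates are 1-based inclusive\n")
        for i, c in enumerate(sorted(candidates, key=lambda c: (c.locus.chrom, c.locus.start)), 1):
            loc = c.locus
            cid = f"cand{i:04d}"
            attrs = (f"ID={cid};read_id={c.read_id};mfe={c.mfe:.2f};"
                     f"mfei={c.mfei:.3f};au_percent={c.au_percent:.1f};"
                     f"star_reads={c.star_read_count}")
            fh.write(f"{loc.chrom}\tgermmir\tmiRNA_primary_transcript\t{loc.start + 1}"
                     f"\t{loc.end}\t.\t{loc.strand}\t.\t{attrs}\n")
            for feat, span in (("miRNA", c.mature_span), ("miRNA_star", c.star_span)):
                if span is None:
                    continue
                if loc.strand == "+":
                    g0, g1 = loc.start + span[0], loc.start + span[1]
                else:
                    g0, g1 = loc.end - span[1], loc.end - span[0]
                fh.write(f"{loc.chrom}\tgermmir\t{feat}\t{g0 + 1}\t{g1}\t.\t{loc.strand}\t.\t"
                         f"ID={cid}.{feat};Parent={cid}\n")


def write_candidate_stats(candidates: Iterable[HairpinCandidate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tmature\tstar\tmfe\tmfei"
                 "\tau_percent\tduplex_unpaired\tloop_distance\tstar_reads"
                 "\taccepted\tprecursor\n")
        for c in candidates:
            loc = c.locus
            fh.write(f"{c.read_id}\t{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.strand}"
                     f"\t{c.mature_sequence}\t{c.star_sequence or ''}\t{c.mfe:.2f}"
                     f"\t{c.mfei:.3f}\t{c.au_percent:.1f}\t{c.duplex_unpaired}"
                     f"\t{c.loop_distance}\t{c.star_read_count}\t{c.accepted}"
                     f"\t{c.precursor.sequence}\n")


def write_structures(candidates: Iterable[HairpinCandidate], path: str) -> None:
    """Dot-bracket dump with mature / star annotation lines."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.read_id} {c.locus.chrom}:{c.locus.start + 1}-{c.locus.end}"
                     f"({c.locus.strand}) mfe={c.mfe:.2f} mfei={c.mfei:.3f}\n")
            fh.write(c.precursor.sequence + "\n")
            fh.write(c.precursor.structure + "\n")
            marks = [" "] * len(c.precursor.sequence)
            for span, glyph in ((c.mature_span, "m"), (c.star_span, "*")):
                if span:
                    for i in range(span[0], min(span[1], len(marks))):
                        marks[i] = glyph
            fh.write("".join(marks).rstrip() + "\n")
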