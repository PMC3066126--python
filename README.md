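# germmir

Plant miRNA discovery from small-RNA sequencing reads: from raw
adapter-ligated reads to annotated conserved miRNAs, novel
hairpin-derived miRNA candidates screened by the minimal folding free
energy index (MFEI), cross-library confirmation, and plant-style miRNA
target prediction.

It is written for analysts working with bulk plant small-RNA libraries
(e.g. germinating-seed or tissue time-course experiments) who want a
transparent, fully testable re-implementation of the classic
hairpin-criteria discovery workflow rather than an opaque monolith.

## The method

Cleaned 18-30 nt reads are collapsed to unique sequences with counts,
singletons removed, and placed on both genome strands by exact
full-length matching. Reads matching rRNA/tRNA/snoRNA/snRNA/siRNA
references or a gene model are set aside; reads identical to a known
mature miRNA that also occur in its hairpin are called conserved. For
every remaining read, the genomic flanks are folded and the read is
evaluated as a candidate mature miRNA:

* the read sits on one arm of a stem-loop, with its miRNA* derived from
  the structure as the duplex partner with 2-nt 3' overhangs;
* at most 6 unpaired nucleotides in the miRNA/miRNA* duplex, no loop or
  helix break inside either, mature length 20-22 nt, miRNA-to-miRNA*
  separation 5-240 nt;
* MFE &le; -20 kcal/mol and

  MFEI = (|MFE| / L &times; 100) / (G+C)% &gt; 0.85

  computed on the trimmed precursor of length L;
* the mature read carries &ge; 50% of the reads mapped in the precursor.

Candidates are confirmed across two independently processed libraries
(identical precursor, mature and locus) and scanned against transcripts
with the six positional duplex rules (mismatch &le; 4 total with G:U
wobble = 0.5, adjacency and seed-region limits, no mismatch at positions
10-11, &le; 2.5 mismatches in positions 1-12, duplex energy &ge; 75% of
the perfect-complement energy), plus a strict &le; 3 total-mismatch cap.

See `docs/methods.md` for every default, tie-break and design decision.

## Worked example

Simulate a two-library experiment with a known ground truth, then run
the full pipeline on it:

```
germmir simulate --seed 1 --out simdir
germmir run --config run.yml      # paths to simdir files, outdir: rundir
```

The run prints the summary (here for seed 1):

```
{
 "confirmed_candidates": 30,
 "expression_consistent": 20,
 "families": 30,
 "star_supported": 7,
 "target_hits": 6,
 "targeted_mirnas": 6
}
```

which says: 30 hairpin candidates were accepted in each library and all
30 were confirmed across the two libraries (these are exactly the 30
planted miRNA loci of the simulation; none of the 10 planted decoy loci
that each violate one criterion was accepted); 7 candidates have miRNA*
read support; 20 of 30 confirmed pairs have per-library-normalised
counts within a 4x fold change; 6 confirmed miRNAs have predicted
target sites among the simulated transcripts. Per-library detail lands
in `rundir/summary.json`, e.g. for library 1: 8,030 raw reads, 8,000
cleaned (10 each dropped as low-quality / polyA / adapterless), 174
unique non-singleton reads, all mapped, 5 conserved known miRNAs, and a
class table whose distinct counts partition the mapped reads (rRNA 24,
tRNA 11, siRNA 12, ..., novel miRNA 30). `rundir/confirmed.gff3`
carries precursor/mature/star features, e.g.

```
chr1  germmir  miRNA_primary_transcript  7165  7248  .  +  .  ID=cand0001;read_id=t0000156;mfe=-40.90;mfei=1.136;au_percent=57.1;star_reads=0
```

Each subcommand (`preprocess`, `map`, `annotate`, `conserved`,
`predict`, `crosslib`, `targets`) also runs standalone on standard
FASTQ/FASTA/BED/GFF3 files.

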