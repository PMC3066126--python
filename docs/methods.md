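# Methods

germmir implements a plant miRNA discovery workflow for small-RNA
sequencing data: from raw adapter-ligated reads to annotated conserved
miRNAs, novel hairpin-derived candidates screened by the minimal folding
free energy index (MFEI), cross-library confirmation, and plant-style
target prediction. This note documents the models, the defaults and the
design choices where the published criteria leave the procedure open.

## Read cleaning and collapsing

Reads are cleaned in a fixed order: mean-quality filter (default Q20,
skipped for FASTA input), 5'-adapter contaminant removal, 3'-adapter
location and trimming, empty-insert and polyA removal, and the 18-30 nt
insert-length window. The 3' adapter is located as the leftmost ungapped
occurrence of the adapter prefix with a seed of >= 8 nt and at most one
mismatch; reads without a locatable 3' adapter are treated as
contaminants and dropped. polyA reads are those with >= 80% adenine
after trimming; the fraction is a package choice exposed in the
configuration, since published pipelines name polyA removal without a
threshold. Every removal is tallied under a named reason so attrition
across the pipeline is auditable.

Cleaned reads are collapsed to unique sequences with counts
("distinct" versus "total" signatures); sequences read only once are
removed by default, after collapsing and before mapping, matching the
conventional pipeline order.

## Genome mapping

Unique reads (18-30 nt) are placed on both strands of the reference by
exact full-length matching through an 18-mer prefix hash index of the
forward strand; a minus-strand hit is an interval whose reverse
complement equals the read. Reads hitting more than 20 loci (default)
are flagged as highly repetitive and excluded from hairpin prediction —
a package decision, since repeat-derived reads behave like siRNAs, not
miRNAs. Locus order is deterministic (chrom, start, strand). On
desk-scale genomes the mapper is verified against a naive all-window
scan (exact set equality).

## Annotation classes

A read whose sequence occurs as an exact substring (either strand) of a
class reference FASTA is assigned that class, with the fixed priority
rRNA > tRNA > snoRNA > snRNA > siRNA > exon/intron classes.
Exact-substring matching at 100% identity operationalises small-RNA vs
ncRNA database identification; no alignment thresholds are involved.
Gene-model classes (exon/intron x sense/antisense) come from a GFF3 gene
model when supplied. The siRNA class requires a user-supplied siRNA
reference. miRNA classes are assigned by the downstream stages and
override "other" only. The class table partitions the classified reads
exactly (distinct and count-weighted totals).

## Conserved miRNA identification

Reads are compared to a miRBase-style reference (mature + hairpin FASTA
with name-linked records) by unit-cost Levenshtein distance — "gaps
count as mismatches" — with a two-mismatch ceiling for reporting. At
18-30 nt a full dynamic program is exact and deterministic, and it
subsumes end-overhang variation, which alignment-based matching leaves
ambiguous. A read is called *conserved* only when it is identical to a
mature sequence and occurs exactly within a linked hairpin. A
cross-species mode applies the same matcher to a non-native mature set;
such hits are labelled but never called conserved. Seed logic uses
nucleotides 2-8, 1-based from the miRNA 5' end, everywhere.

## Hairpin candidate evaluation

For every unannotated mapped read, two anchored genomic windows are
extracted (read near the window 5' end and near the 3' end), each with
up to 300 nt of context, strand-adjusted and transcribed to RNA. The
window flank must exceed the maximal allowed mature-to-miRNA* separation
(240 nt) plus a star and its overhang — a smaller window could never
observe a distal star, silently converting the distance criterion into a
window artifact — hence the 300 nt default.

Windows are folded to a minimum-free-energy structure. The miRNA* span
is derived from the structure as the duplex partner of the mature with
2-nt 3' overhangs on both strands: the star 5' end faces mature position
L-2 and the star 3' end extends two nucleotides past the partner of the
mature 5' end. The precursor is then trimmed to the duplex-enclosing
region plus 15 nt of context and refolded, and all criteria are
evaluated on that trimmed fold, so the reported statistics (MFE, MFEI,
A+U content) describe the precursor, not the scanning window.

Criteria:

* **stem / one arm** — the mature pairs into a single helix (partners
  one-sided and monotonic); a read whose positions pair with each other
  spans the terminal loop and is rejected ("loop overlap");
* **duplex unpaired <= 6** — unpaired nucleotides counted on the mature
  strand within the duplex, covering both bulges and internal-loop
  residues; the two Results-style phrasings ("mismatches" and "unpaired
  nucleotides") are treated as the same quantity;
* **clean duplex** — no terminal-loop residue and no multi-branch helix
  break inside the mature or star spans (the star overhang is exempt);
  structure between mature and star is unrestricted, as large loops in
  real precursors fold internally;
* **numeric screens** — MFE < 0 and <= -20 kcal/mol; mature length
  20-22 nt; mature-to-star separation 5-240 nt, measured as nucleotides
  strictly between the loop-facing duplex ends; MFEI > 0.85 with
  MFEI = (|MFE| / length x 100) / (G+C)%, computed on the trimmed
  precursor (|MFE| in the numerator, since the published index is
  positive for negative folding energies);
* **dominance** — the mature read must carry >= 50% of the read counts
  mapped within the precursor (configurable); this is what rejects
  star-strand and degradation reads that otherwise sit on valid
  hairpins.

Criteria that presuppose a located star are reported vacuously true when
the structural derivation itself fails; the stem/one-arm flags carry
that failure, keeping each rejection attributable. Overlapping accepted
candidates at one locus are resolved by keeping the highest MFEI (ties:
smaller start). miRNA* read support is counted at the star locus with
+-1 nt slack per end. Accepted matures cluster into families when they
share an identical seed (nt 2-8) and are within overall edit distance 2;
the published family count has no stated rule, so this one is
documented and configurable.

### Folding engines

Folding is a pluggable contract (RNA string in; dot-bracket plus
kcal/mol out). The default engine binds to ViennaRNA when its python
bindings are importable and is cross-checked in the tests by re-scoring
returned structures with the engine's own parameter table. A built-in
deterministic pair-energy dynamic program (G:C -3.4, A:U -1.1, G:U -0.5
kcal/mol per pair; hairpin loops >= 3 nt; no dangles; cubic time) keeps
everything runnable with zero external dependencies. Absolute energies
are engine-dependent; no criterion depends on engine constants except
through the user-visible MFE/MFEI thresholds.

## Target prediction

The duplex model is ungapped and antiparallel: each transcript window of
the miRNA's length is scored per position as Watson-Crick, G:U wobble
(0.5 mismatches) or mismatch (1). Six rules gate a hit: total score
<= 4; no run of more than two adjacent mismatches; no adjacent
mismatches within positions 2-12; no mismatch at positions 10-11; score
over positions 1-12 <= 2.5; and duplex energy >= 75% of the energy of
the miRNA bound to its perfect complement. Strict mode (default)
additionally caps the total score at 3, wobble halves included. Wobbles
count toward the numeric scores but not toward adjacency and not as
mismatches at positions 10-11; in rendered alignments they display as
spaces, like mismatches — the published scoring (0.5) and display
("count as mismatches") conventions differ, and both are kept.
Bulged (gapped) sites are out of scope: all six rules are positional
over a fixed-length duplex.

Duplex energies use an additive nearest-neighbor stacking model shared
with the fallback folding engine: each admissible pair contributes
G:C -1.70, A:U -0.55, G:U -0.25 kcal/mol, and a stack of two adjacent
pairs scores the sum of its two contributions. This reproduces the
ordering and rough magnitude of the Turner stacking parameters while
remaining symmetric and dependency-free; rule 6 consumes only the
ratio of two such energies and is insensitive to the calibration.

The production scanner is numpy-vectorised over windows and is verified
against a naive per-window rescoring oracle (exact set equality) in the
tests.

## Cross-library confirmation

A candidate is confirmed when the second, independently processed
library contains a candidate with the identical precursor sequence,
identical mature sequence and identical genomic locus; the operation is
symmetric. "No significant expression difference" is unquantified in
the published analyses, so it is implemented as an annotation, not a
filter: confirmed pairs are flagged expression-consistent when their
per-library-normalised mature counts are within a 4x fold change
(configurable). Whether confirmation should tolerate +-1 nt mature end
variation is unstated; strict identity is used.

## Synthetic data generator

The generator emulates the structure of an imbibed-seed small-RNA
experiment at desk scale: a 100 kb random genome carrying 30 planted
canonical hairpin loci, 10 decoy loci, 5 "known" miRNA loci (which also
populate the miRBase-style reference), ncRNA reference blocks (planted
into the genome so decoy reads map), three protein-coding genes, and 20
transcripts of 1 kb with planted target sites designed to pass or fail a
designated rule. Two libraries of ~8,000 adapter-ligated reads are
simulated with log-normally skewed mature abundances (minimum 2 so the
signal survives singleton removal), miRNA* reads for 7 hairpins at
<= 10% of their mature's count, ncRNA/gene-region/background reads with
a 24-nt-enriched length distribution, deliberate singletons, and junk
reads (low-quality, polyA, adapterless) the cleaner must drop.

Canonical hairpins are built by inserting a mature, a loop and the
reverse complement of the mature plus a stem extension; each duplex
carries 1-3 designed mismatches — realistic, and necessary to keep a
hairpin from being quasi-palindromic (a perfect-duplex mature would also
map to its own star arm on the opposite strand). Each decoy violates
exactly one named criterion by construction (7 unpaired duplex
positions; a loop-spanning read; a 23-nt mature; a 244-nt separation
with a strong internal loop hairpin that keeps MFEI clear of its
threshold; a long weak-stem precursor with MFEI < 0.85). Every planted
element is verified against the package's own evaluation path at build
time and deterministically resampled until its designed label holds, so
manifest labels are guaranteed. All sampling is integer-based through a
single seeded generator: the same seed reproduces byte-identical
outputs.

What the generator does *not* emulate: sequencing errors beyond none at
all, quality-score realism, multi-chromosome genomes, repeat families,
isomiR end heterogeneity, and RNA degradation products. Passing the
recovery tests therefore shows that the pipeline logic is faithful to
its stated criteria on clean signals — not that the criteria themselves
separate real miRNAs from transcriptome noise at genome scale.

For bound-recovery scans (the <= 6 unpaired and 5-240 nt separation
windows) the generator also provides precursors constructed together
with their designed structure, since a thermodynamic engine will merge
or open designed internal loops unpredictably; the evaluation operation
consumes a fold result, so a designed instance exercises it exactly.

## Problem sizes and determinism

Default analysis problem sizes — 100 kb genome, two libraries of ~8,000
reads, 20 transcripts — were chosen so a complete two-library run takes
well under a minute on one core while every pipeline stage still has
non-trivial work. The oracle-equivalence checks run at 100 kb / 50
planted reads (mapper), 20 miRNAs x 100 kb of transcript (target
scanner) and 100 x 50 sequence pairs (edit distance). Identical
configurations and inputs reproduce identical outputs throughout; all
randomness flows from explicit integer seeds.

## Known limitations

* The exact-match mapper ignores mismatches and indels by design; reads
  crossing SNPs against the reference are lost, as in any
  perfect-match protocol.
* The ungapped duplex model cannot represent bulged target sites.
* MFEI is computed on the trimmed precursor; published analyses are
  ambiguous about whether the folding window or the trimmed precursor
  was used, and the two can differ for long-loop precursors.
* The built-in folding engine has no loop penalties or dangles and is a
  fallback, not a substitute thermodynamic model; with ViennaRNA
  installed it is used only where a designed structure is explicit.
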