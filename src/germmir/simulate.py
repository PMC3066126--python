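"""Deterministic synthetic truth sets for the whole pipeline.

Emulates the structure of an imbibed-seed small-RNA sequencing experiment:
a genome carrying planted miRNA hairpin loci (plus decoy loci violating
exactly one candidate criterion each), ncRNA blocks, protein-coding genes,
transcripts with planted target sites, and two libraries of adapter-ligated
18-30 nt reads with highly skewed abundances and rare miRNA* reads.  A
ground-truth manifest records every planted element and the true class of
every simulated insert.

Every planted hairpin is built by inserting a mature sequence, a loop and
the (designed-mismatch) reverse complement of the mature plus a stem
extension, then *verified* against the package's own evaluation path:
canonical hairpins must be accepted, each decoy must fail exactly its
designated criterion.  Constructions that fold differently than designed
are resampled deterministically until they verify, so manifest labels are
guaranteed.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np

from .hairpin import (Thresholds, best_candidate, candidates_for_read,
                      star_genome_locus)
from .mapping import GenomeIndex, GenomeLocus, MappedRead
from .preprocess import RawRead, UniqueRead
from .sequence import reverse_complement, to_dna, to_rna
from .targets import passes_filters, score_duplex

BASES = "ACGU"
ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"  # classic small-RNA 3' adapter
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
READ_LEN = 44

#: insert-length weights for background reads (24-nt enriched, as in
#: angiosperm small-RNA populations)
LENGTH_WEIGHTS = {18: 2, 19: 3, 20: 8, 21: 14, 22: 22, 23: 4, 24: 33, 25: 4,
                  26: 3, 27: 3, 28: 2, 29: 1, 30: 1}

DECOY_TYPES = ("duplex7", "duplex7", "duplex7", "loop_mature", "loop_mature",
               "long_mature", "long_mature", "distance", "distance", "low_mfei")

#: which criterion each decoy type is designed to violate
DECOY_CRITERION = {"duplex7": "duplex_unpaired", "loop_mature": "one_arm",
                   "long_mature": "mature_length", "distance": "loop_distance",
                   "low_mfei": "mfei"}


@dataclass
class GeneratorParams:
    genome_len: int = 100_000
    n_hairpins: int = 30
    n_decoys: int = 10
    n_known: int = 5
    n_star: int = 7             # canonical hairpins that get miRNA* reads
    n_private: int = 0          # canonical hairpins present in only one library
    n_transcripts: int = 20
    transcript_len: int = 1000
    n_genes: int = 3
    depth: int = 8000           # approximate reads per simulated library
    read_len: int = READ_LEN
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5


@dataclass
class PlantedHairpin:
    name: str
    kind: str                   # canonical | decoy | known
    decoy_type: str | None
    chrom: str
    strand: str
    precursor_start: int        # genome coordinates of the inserted construct
    precursor_end: int
    mature: str                 # RNA
    mature_start: int
    mature_end: int
    star: str | None = None    # RNA, from the verified candidate
    star_start: int | None = None
    star_end: int | None = None
    expected_accepted: bool = True
    violated_criterion: str | None = None
    has_star_reads: bool = False
    libraries: tuple[str, ...] = ("lib1", "lib2")
    # verified candidate identity (trimmed precursor), for cross-library checks
    candidate_precursor: str | None = None
    candidate_locus: tuple | None = None


@dataclass
class PlantedTarget:
    transcript_id: str
    position: int               # 0-based site start on the transcript
    mirna_name: str
    designed_pass: bool
    designed_rule: str | None   # rule the site is designed to fail, if any


@dataclass
class TruthManifest:
    seed: int
    params: GeneratorParams
    hairpins: list[PlantedHairpin]
    targets: list[PlantedTarget]
    ncrna_blocks: dict[str, list[tuple[int, int]]]  # genome spans per class
    gene_features: list[tuple[str, str, int, int, str]]  # (type, chrom, start0, end0, strand)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, default=str)


@dataclass
class TruthSet:
    genome: dict[str, str]
    ncrna_refs: dict[str, list[str]]
    transcripts: dict[str, str]
    known_matures: dict[str, str]
    known_hairpins: dict[str, str]
    gff3: str
    manifest: TruthManifest

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        _write_fasta(os.path.join(outdir, "genome.fa"), self.genome)
        for cls, seqs in self.ncrna_refs.items():
            _write_fasta(os.path.join(outdir, f"ncrna_{cls}.fa"),
                         {f"{cls}_{i}": s for i, s in enumerate(seqs)})
        _write_fasta(os.path.join(outdir, "transcripts.fa"), self.transcripts)
        _write_fasta(os.path.join(outdir, "known_mature.fa"), self.known_matures)
        _write_fasta(os.path.join(outdir, "known_hairpin.fa"), self.known_hairpins)
        with open(os.path.join(outdir, "genes.gff3"), "w") as fh:
            fh.write(self.gff3)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            fh.write(self.manifest.to_json())


def _write_fasta(path: str, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# sequence construction helpers

def _rand_seq(rng, n: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_au = (1.0 - gc) / 2.0
    probs = np.array([p_au, p_gc, p_gc, p_au])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=probs))


def _spacer(n: int) -> str:
    return ("CAA" * (n // 3 + 1))[:n]


# replacement for a paired base such that the new base neither Watson-Crick-
# nor wobble-pairs the partner (keyed by the current complementary base)
_NONPAIRING = {"A": "C", "C": "A", "G": "A", "U": "C"}


def _mutate_arm(arm: str, mature: str, positions: Iterable[int]) -> str:
    """Break pairing of *mature* positions (0-based) in the opposing arm."""
    arm = list(arm)
    L = len(mature)
    for q in positions:
        arm[L - 1 - q] = _NONPAIRING[reverse_complement(mature[q], "RNA")]
    return "".join(arm)


@dataclass
class _Construct:
    precursor: str              # RNA, 5'->3' in read orientation
    mature_span: tuple[int, int]


def _build_construct(rng, decoy_type: str | None) -> _Construct:
    """One hairpin construct in read orientation (RNA)."""
    if decoy_type == "long_mature":
        mat_len = 23
    else:
        mat_len = int(rng.choice([20, 21, 22], p=[0.2, 0.6, 0.2]))
    mature = _rand_seq(rng, mat_len, gc=0.5)
    pad5, pad3 = _rand_seq(rng, 8), _rand_seq(rng, 8)

    if decoy_type == "distance":
        # separation just over the 240-nt limit; a strong GC hairpin inside
        # the loop keeps the trimmed precursor's MFEI above threshold so the
        # distance criterion is the only one violated
        ext = _rand_seq(rng, 30, gc=0.7)
        arm5 = ext + mature
        inner_arm = _rand_seq(rng, 40, gc=0.9)
        inner = inner_arm + "CAAA" + reverse_complement(inner_arm, "RNA")
        d = 244
        fill = d - len(inner)
        loop = _spacer(fill // 2) + inner + _spacer(fill - fill // 2)
        prec = arm5 + loop + reverse_complement(arm5, "RNA") + pad3
        return _Construct(prec, (len(ext), len(ext) + mat_len))
    if decoy_type == "low_mfei":
        arm5 = mature
        loop = _spacer(120)
        prec = pad5 + arm5 + loop + reverse_complement(arm5, "RNA") + pad3
        return _Construct(prec, (len(pad5), len(pad5) + mat_len))
    # a GC-richer, longer stem extension keeps MFEI clear of the threshold
    # for decoys meant to fail a different criterion
    ext = _rand_seq(rng, 20 if decoy_type == "duplex7" else 10, gc=0.7)
    arm5 = ext + mature
    loop = "CAA" + _rand_seq(rng, 8, gc=0.3) + "A"
    arm3 = reverse_complement(arm5, "RNA")
    if decoy_type == "duplex7":
        # seven isolated broken pairs inside the mature region of the 3' arm
        qs = list(range(3, 3 + 14, 2))[:7]
        mat_part = _mutate_arm(arm3[:mat_len], mature, qs)
        arm3 = mat_part + arm3[mat_len:]
    elif decoy_type is None:
        # realistic duplexes carry a few mismatches; this also keeps the
        # hairpin from being quasi-palindromic (a perfect-duplex mature
        # would map to the star arm on the opposite strand as well)
        k = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
        qs = sorted(rng.choice(np.arange(4, mat_len - 4, 2), size=k, replace=False))
        arm3 = _mutate_arm(arm3[:mat_len], mature, qs) + arm3[mat_len:]
    prec = pad5 + arm5 + loop + arm3 + pad3
    span = (len(pad5) + len(ext), len(pad5) + len(ext) + mat_len)
    if decoy_type == "loop_mature":
        # designate a read straddling the terminal loop
        mid = len(pad5) + len(arm5) + len(loop) // 2
        span = (mid - 10, mid + 11)
    return _Construct(prec, span)


def designed_precursor(separation: int = 12, n_unpaired: int = 0,
                       mat_len: int = 21, seed: int = 7):
    """A precursor constructed together with its designed structure.

    The mature sits on the 5' arm behind a 60-nt GC-rich stem extension,
    fully paired to its star except for ``n_unpaired`` isolated broken
    pairs, with exactly ``separation`` unpaired loop-side nucleotides
    between mature and star.  Because the structure is built alongside the
    sequence (not predicted), every criterion quantity is exact by
    construction; the energy is the built-in pair-energy sum of the
    designed pairs.  Returns ``(FoldResult, mature_span)``.

    Intended for bound-recovery scans over single criteria (e.g. the
    duplex-unpaired <= 6 and the 5-240 nt separation windows).
    """
    from .folding import BuiltinEngine, FoldResult

    rng = np.random.default_rng(seed)
    mature = _rand_seq(rng, mat_len, gc=0.5)
    ext = _rand_seq(rng, 60, gc=0.85)
    arm5 = ext + mature
    broken = {3 + 2 * i for i in range(n_unpaired)}  # mature-local indices
    if broken and max(broken) > mat_len - 4:
        raise ValueError("too many broken pairs for this mature length")
    arm3 = list(reverse_complement(arm5, "RNA"))
    for q in broken:
        arm3[mat_len - 1 - q] = _NONPAIRING[reverse_complement(mature[q], "RNA")]
    pad5, pad3 = _rand_seq(rng, 8), "AA" + _rand_seq(rng, 6)
    loop = _spacer(separation)
    seq = pad5 + arm5 + loop + "".join(arm3) + pad3
    n = len(seq)
    structure = ["."] * n
    a0 = len(pad5)                      # arm5 start
    b0 = a0 + len(arm5) + len(loop)     # arm3 start
    mstart = a0 + len(ext)
    energy = 0.0
    eng = BuiltinEngine()
    for i in range(len(arm5)):
        mature_local = i - len(ext)
        if mature_local in broken:
            continue
        j = b0 + (len(arm5) - 1 - i)
        structure[a0 + i], structure[j] = "(", ")"
        energy += eng._pair_energy(seq[a0 + i], seq[j])
    fold_result = FoldResult(sequence=seq, structure="".join(structure),
                             mfe=round(energy, 2))
    return fold_result, (mstart, mstart + mat_len)


# ---------------------------------------------------------------------------
# truth-set generation

def generate_truth_set(seed: int, params: GeneratorParams | None = None) -> TruthSet:
    """Build the genome, references, transcripts and ground-truth manifest."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    thresholds = Thresholds()

    n_elements = params.n_hairpins + params.n_decoys + params.n_known
    if n_elements * 600 > params.genome_len:
        raise ValueError("genome too short for the requested number of hairpin loci")

    # --- ncRNA reference blocks (planted into the genome so reads map)
    ncrna_plan = {"rRNA": [800, 600], "tRNA": [75, 74, 76, 75],
                  "snoRNA": [110, 105, 120], "snRNA": [150, 140, 160],
                  "siRNA": [400]}
    ncrna_refs = {cls: [to_rna(_rand_seq(rng, n)) for n in lens]
                  for cls, lens in ncrna_plan.items()}

    # --- genes (random sequence; exon/intron structure recorded)
    gene_plan = [(200, 150, 200), (250, 120, 180), (220, 100, 240)]

    # --- hairpin constructs (read orientation)
    specs: list[tuple[str, str | None]] = (
        [("canonical", None)] * params.n_hairpins
        + [("decoy", DECOY_TYPES[i % len(DECOY_TYPES)]) for i in range(params.n_decoys)]
        + [("known", None)] * params.n_known)

    # --- assemble the genome: filler / element / filler / element ...
    chrom = "chr1"
    pieces: list[str] = []
    pos = 0
    placements: list[dict] = []  # genome slot for each element

    def filler(n):
        nonlocal pos
        pieces.append(to_dna(_rand_seq(rng, n)))
        pos += n

    order = list(range(n_elements))
    rng.shuffle(order)
    ncrna_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in ncrna_plan}
    gene_features: list[tuple[str, str, int, int, str]] = []

    filler(300)
    for cls, seqs in ncrna_refs.items():
        for s in seqs:
            ncrna_blocks[cls].append((pos, pos + len(s)))
            pieces.append(to_dna(s))
            pos += len(s)
            filler(120)
    for g, exons in enumerate(gene_plan):
        strand = "+" if g % 2 == 0 else "-"
        gstart = pos
        for i, ln in enumerate(exons):
            if i % 2 == 0:
                gene_features.append(("exon", chrom, pos, pos + ln, strand))
            filler(ln)
        gene_features.append(("gene", chrom, gstart, pos, strand))
        filler(150)
    slot_len = 700  # generous fixed slot; constructs are re-inserted in place
    for idx in order:
        kind, decoy_type = specs[idx]
        placements.append({"idx": idx, "kind": kind, "decoy_type": decoy_type,
                           "slot_start": pos})
        filler(slot_len)
    remaining = params.genome_len - pos
    if remaining > 0:
        filler(remaining)
    genome_seq = list("".join(pieces))

    def insert(slot_start: int, construct: _Construct, strand: str) -> tuple[int, int, int, int]:
        """Place a construct centered in its slot; return precursor and
        mature genome intervals."""
        plen = len(construct.precursor)
        gstart = slot_start + (slot_len - plen) // 2
        dna = to_dna(construct.precursor)
        if strand == "-":
            dna = reverse_complement(dna, "DNA")
        genome_seq[gstart:gstart + plen] = dna
        ms, me = construct.mature_span
        if strand == "+":
            m0, m1 = gstart + ms, gstart + me
        else:
            m0, m1 = gstart + plen - me, gstart + plen - ms
        return gstart, gstart + plen, m0, m1

    # failing-criterion sets tolerated per decoy design; the designated
    # criterion must fail, cascades beyond the allowed set force a resample
    allowed_failures = {
        "duplex7": {"duplex_unpaired"},
        "long_mature": {"mature_length"},
        "distance": {"loop_distance"},
        "low_mfei": {"mfei"},
        "loop_mature": {"one_arm", "stem", "mfei"},
    }

    hairpins: list[PlantedHairpin] = []
    known_matures: dict[str, str] = {}
    known_hairpins: dict[str, str] = {}
    n_canonical_seen = 0
    for place in sorted(placements, key=lambda p: p["idx"]):
        kind, decoy_type = place["kind"], place["decoy_type"]
        strand = "+" if rng.random() < 0.67 else "-"
        name = f"syn-{kind}-{place['idx']:03d}"
        target_criterion = DECOY_CRITERION.get(decoy_type)
        slot_filler = genome_seq[place["slot_start"]:place["slot_start"] + slot_len]
        for attempt in range(40):
            genome_seq[place["slot_start"]:place["slot_start"] + slot_len] = slot_filler
            construct = _build_construct(rng, decoy_type)
            p0, p1, m0, m1 = insert(place["slot_start"], construct, strand)
            index = GenomeIndex({chrom: "".join(genome_seq[max(0, p0 - 400):p1 + 400])})
            local = GenomeLocus(chrom, m0 - max(0, p0 - 400), m1 - max(0, p0 - 400), strand)
            read = UniqueRead(sequence=construct.precursor[slice(*construct.mature_span)],
                              count=10, read_id=name)
            cands = candidates_for_read(MappedRead(read=read, loci=[local]), index,
                                        thresholds=thresholds)
            best = best_candidate(cands)
            if kind in ("canonical", "known"):
                ok = best is not None
            else:
                allowed = allowed_failures[decoy_type]
                failing = [set(k for k, v in c.criteria.items() if not v) for c in cands]
                ok = best is None and any(
                    target_criterion in f and f <= allowed for f in failing)
            if ok:
                break
        else:
            raise RuntimeError(f"could not verify construct {name} ({decoy_type})")
        offset = max(0, p0 - 400)
        hp = PlantedHairpin(
            name=name, kind=kind, decoy_type=decoy_type, chrom=chrom, strand=strand,
            precursor_start=p0, precursor_end=p1,
            mature=read.sequence, mature_start=m0, mature_end=m1,
            expected_accepted=kind in ("canonical",),
            violated_criterion=target_criterion)
        if best is not None:
            star = star_genome_locus(best)
            hp.candidate_precursor = best.precursor.sequence
            loc = best.locus
            hp.candidate_locus = (loc.chrom, loc.start + offset, loc.end + offset, loc.strand)
            if star is not None:
                hp.star = best.star_sequence
                hp.star_start, hp.star_end = star.start + offset, star.end + offset
        if kind == "known":
            known_matures[f"syn-miR{place['idx']:03d}"] = hp.mature
            known_hairpins[f"syn-MIR{place['idx']:03d}"] = hp.candidate_precursor or construct.precursor
            hp.expected_accepted = False  # excluded from novel prediction as known
        if kind == "canonical":
            n_canonical_seen += 1
            if n_canonical_seen <= params.n_star:
                hp.has_star_reads = True
            if params.n_private and n_canonical_seen > params.n_hairpins - params.n_private:
                lib = "lib1" if n_canonical_seen % 2 else "lib2"
                hp.libraries = (lib,)
        hairpins.append(hp)

    genome = {chrom: "".join(genome_seq)}

    # --- transcripts with planted target sites
    transcripts: dict[str, str] = {}
    targets: list[PlantedTarget] = []
    canonical = [h for h in hairpins if h.kind == "canonical"]
    fail_rules = [None, None, "rule4_center", "rule1_total", "rule5_seed_score", None]
    for t in range(params.n_transcripts):
        tid = f"tx{t + 1:03d}"
        seq = _rand_seq(rng, params.transcript_len)
        if t < min(12, len(canonical)):
            hp = canonical[t]
            rule = fail_rules[t % len(fail_rules)]
            site, ok = _design_site(rng, hp.mature, rule)
            p = int(rng.integers(50, params.transcript_len - len(site) - 50))
            seq = seq[:p] + site + seq[p + len(site):]
            targets.append(PlantedTarget(transcript_id=tid, position=p,
                                         mirna_name=hp.name, designed_pass=ok,
                                         designed_rule=rule))
        transcripts[tid] = seq

    gff3 = _render_gff3(gene_features)
    manifest = TruthManifest(seed=seed, params=params, hairpins=hairpins,
                             targets=targets, ncrna_blocks=ncrna_blocks,
                             gene_features=gene_features)
    return TruthSet(genome=genome, ncrna_refs=ncrna_refs, transcripts=transcripts,
                    known_matures=known_matures, known_hairpins=known_hairpins,
                    gff3=gff3, manifest=manifest)


def _design_site(rng, mature: str, fail_rule: str | None) -> tuple[str, bool]:
    """A target site for *mature*, designed to pass all rules or fail one."""
    L = len(mature)
    site = list(reverse_complement(mature, "RNA"))

    def break_pos(i):  # miRNA position i (1-based) -> full mismatch
        j = L - i
        site[j] = _NONPAIRING[site[j]]

    if fail_rule is None:
        if rng.random() < 0.5:
            break_pos(int(rng.integers(14, L - 1)))
    elif fail_rule == "rule4_center":
        break_pos(10)
    elif fail_rule == "rule1_total":
        for i in (3, 6, 14, 17, 20):
            break_pos(i)
    elif fail_rule == "rule5_seed_score":
        for i in (2, 5, 8):
            break_pos(i)
    site_seq = "".join(site)
    d = score_duplex(mature, site_seq)
    rules, overall = passes_filters(d, strict=True)
    designed_ok = fail_rule is None
    if designed_ok != overall or (fail_rule and rules.get(fail_rule, True)):
        # rare: the mutation interacted with the energy rule; fall back to
        # a perfect site for pass designs
        if designed_ok:
            return reverse_complement(mature, "RNA"), True
        raise RuntimeError("designed-fail target site did not fail as designed")
    return site_seq, designed_ok


def _render_gff3(features) -> str:
    lines = ["##gff-version 3"]
    gid = 0
    for ftype, chrom, s, e, strand in features:
        gid += 1
        attrs = f"ID={ftype}{gid}"
        if ftype == "exon":
            attrs += f";Parent=gene{gid}"
        lines.append(f"{chrom}\tgermmir_sim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class SimulatedLibrary:
    library_id: str
    reads: list[RawRead]
    #: per-insert truth: insert (RNA) -> (class label, count)
    truth: dict[str, tuple[str, int]]

    def class_tallies(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cls, n in self.truth.values():
            out[cls] = out.get(cls, 0) + n
        return out


def _lognormal_count(rng, minimum: int = 2, mu: float = 2.2, sigma: float = 1.2) -> int:
    return max(minimum, int(round(float(rng.lognormal(mu, sigma)))))


def simulate_reads(truth: TruthSet, library_id: str, depth: int | None = None,
                   seed: int = 0) -> SimulatedLibrary:
    """Simulate one adapter-ligated library from a truth set.

    Reads are drawn from planted matures (log-skewed counts, never below
    2 so the hairpin signal survives singleton removal), miRNA* strands at
    <=10% of their mature's count, ncRNA decoys, gene-region and random
    background (singletons deliberately included), each with the 3'
    adapter appended and padded/truncated to the machine read length.
    """
    params = truth.manifest.params
    depth = depth or params.depth
    rng = np.random.default_rng(seed)
    genome = truth.genome
    inserts: list[tuple[str, str, int]] = []  # (insert RNA, class, count)
    reserved: set[str] = set()

    def add(insert: str, cls: str, count: int):
        inserts.append((insert, cls, count))
        reserved.add(insert)

    for hp in truth.manifest.hairpins:
        if library_id not in hp.libraries:
            continue
        cls = "miRNA_known" if hp.kind == "known" else (
            "decoy_mature" if hp.kind == "decoy" else "miRNA_novel")
        count = _lognormal_count(rng, minimum=2)
        if hp.has_star_reads:
            count = max(count, 25)
        add(hp.mature, cls, count)
        if hp.has_star_reads and hp.star:
            star_count = max(2, min(count // 10, 1 + int(rng.integers(0, 8))))
            add(hp.star, "miRNA_star", star_count)

    ncrna_sizes = {"rRNA": 25, "tRNA": 10, "snoRNA": 6, "snRNA": 6, "siRNA": 12}
    for cls, n in ncrna_sizes.items():
        refs = truth.ncrna_refs[cls]
        for _ in range(n):
            ref = refs[int(rng.integers(0, len(refs)))]
            ln = int(rng.integers(18, 25))
            p = int(rng.integers(0, len(ref) - ln))
            ins = ref[p:p + ln]
            if ins in reserved:
                continue
            add(ins, cls, int(rng.integers(1, 20)))

    exon_like = [(s, e, strand, ftype) for ftype, _c, s, e, strand in
                 truth.manifest.gene_features]
    for _ in range(40):
        s, e, strand, ftype = exon_like[int(rng.integers(0, len(exon_like)))]
        ln = int(rng.choice(list(LENGTH_WEIGHTS), p=np.array(list(LENGTH_WEIGHTS.values())) / 100))
        p = int(rng.integers(s, max(s + 1, e - ln)))
        frag = to_rna(genome["chr1"][p:p + ln])
        if rng.random() < 0.4:
            frag = reverse_complement(frag, "RNA")
        if frag not in reserved:
            add(frag, "gene_region", int(rng.integers(1, 6)))

    hp_spans = [(h.precursor_start, h.precursor_end) for h in truth.manifest.hairpins]
    chrom_seq = genome["chr1"]
    n_bg = 60
    made = 0
    while made < n_bg:
        ln = int(rng.choice(list(LENGTH_WEIGHTS), p=np.array(list(LENGTH_WEIGHTS.values())) / 100))
        p = int(rng.integers(0, len(chrom_seq) - ln))
        if any(p < e and p + ln > s for s, e in hp_spans):
            continue
        frag = to_rna(chrom_seq[p:p + ln])
        if frag in reserved or "N" in frag:
            continue
        add(frag, "background_genomic", int(rng.choice([1, 1, 1, 2, 2, 3, 4])))
        made += 1
    for _ in range(20):
        frag = _rand_seq(rng, int(rng.integers(18, 31)))
        if frag not in reserved:
            add(frag, "background_random", 1)

    total = sum(c for _, _, c in inserts)
    while total < depth:  # pad to the requested depth with singleton background
        ln = int(rng.choice(list(LENGTH_WEIGHTS), p=np.array(list(LENGTH_WEIGHTS.values())) / 100))
        p = int(rng.integers(0, len(chrom_seq) - ln))
        if any(p < e and p + ln > s for s, e in hp_spans):
            continue
        frag = to_rna(chrom_seq[p:p + ln])
        if frag in reserved:
            continue
        add(frag, "background_genomic", 1)
        total += 1

    truth_map = {ins: (cls, count) for ins, cls, count in inserts}
    reads: list[RawRead] = []
    i = 0
    for ins, cls, count in inserts:
        for _ in range(count):
            i += 1
            raw = to_dna(ins) + params.adapter3
            raw = (raw + "A" * params.read_len)[:params.read_len]
            qual = [int(q) for q in rng.integers(32, 41, params.read_len)]
            reads.append(RawRead(sequence=raw, quality=qual, library_id=library_id,
                                 name=f"{library_id}_r{i:06d}"))
    # junk the cleaner must drop: low quality, polyA, adapterless
    for kind in ("lowq", "polyA", "noadapter"):
        for _ in range(10):
            i += 1
            if kind == "lowq":
                seq = to_dna(_rand_seq(rng, 22)) + params.adapter3
                seq = (seq + "A" * params.read_len)[:params.read_len]
                qual = [8] * params.read_len
            elif kind == "polyA":
                seq = ("A" * 24 + params.adapter3 + "A" * params.read_len)[:params.read_len]
                qual = [int(q) for q in rng.integers(32, 41, params.read_len)]
            else:
                seq = to_dna(_rand_seq(rng, params.read_len))
                qual = [int(q) for q in rng.integers(32, 41, params.read_len)]
            reads.append(RawRead(sequence=seq, quality=qual, library_id=library_id,
                                 name=f"{library_id}_junk{i:06d}"))
    rng.shuffle(reads)
    return SimulatedLibrary(library_id=library_id, reads=reads, truth=truth_map)


def write_fastq(library: SimulatedLibrary, path: str) -> None:
    with open(path, "w") as fh:
        for r in library.reads:
            qual = "".join(chr(q + 33) for q in (r.quality or [40] * len(r.sequence)))
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")
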