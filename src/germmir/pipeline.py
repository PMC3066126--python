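"""End-to-end pipeline orchestration.

Stage order follows the discovery workflow: clean -> collapse -> map ->
annotate -> conserved -> hairpin prediction -> cross-library confirmation
-> target prediction, with per-stage attrition logged so pipeline
narratives (raw -> cleaned -> non-singleton -> mapped) are auditable on
any dataset.  Re-running with an identical configuration and inputs
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from . import annotate as ann
from .annotate import GeneModel, ReadClass
from .conserved import ConservedHit, KnownMiRNARef, match_known
from .crosslib import (ConfirmedCandidate, LibraryCandidateSet,
                       identity_key, intersect_candidates)
from .hairpin import (HairpinCandidate, Thresholds, apply_dominance,
                      best_candidate, candidates_for_read, find_star_reads,
                      group_families, resolve_overlaps)
from .mapping import GenomeIndex, MappingResult, map_reads
from .preprocess import (DropLog, RawRead, UniqueRead, clean_reads,
                         collapse_reads, length_distribution)
from .targets import TargetHit, scan_transcripts


@dataclass
class PipelineConfig:
    """All stage thresholds; defaults are the published values."""

    min_len: int = 18
    max_len: int = 30
    min_mean_quality: float = 20.0
    drop_singletons: bool = True
    max_loci: int = 20
    known_max_mismatch: int = 2
    thresholds: Thresholds = field(default_factory=Thresholds)
    expr_fold_limit: float = 4.0
    strict_targets: bool = True
    seed: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        thr = Thresholds(**d.pop("thresholds", {}))
        return cls(thresholds=thr, **d)


@dataclass
class Resources:
    """Shared reference inputs for one pipeline run."""

    genome_index: GenomeIndex
    ncrna_refs: dict[str, list[str]]
    known_ref: KnownMiRNARef | None = None
    gene_model: GeneModel | None = None
    transcripts: dict[str, str] | None = None


@dataclass
class LibraryResult:
    library_id: str
    drop_log: DropLog
    unique_reads: list[UniqueRead]
    total_cleaned: int
    mapping: MappingResult
    classes: dict[str, ReadClass]
    conserved_hits: list[ConservedHit]
    candidates: list[HairpinCandidate]
    accepted: list[HairpinCandidate]

    @property
    def candidate_set(self) -> LibraryCandidateSet:
        counts = {r.read_id: r.count for r in self.unique_reads}
        return LibraryCandidateSet(
            library_id=self.library_id, candidates=self.accepted,
            counts={identity_key(c): counts.get(c.read_id, 0) for c in self.accepted},
            total_reads=self.total_cleaned)


def run_library(raw_reads: Iterable[RawRead], adapter3: str, resources: Resources,
                config: PipelineConfig | None = None, adapter5: str | None = None,
                library_id: str = "lib1", engine=None) -> LibraryResult:
    """One library from raw reads to accepted hairpin candidates."""
    config = config or PipelineConfig()
    log = DropLog()
    cleaned = list(clean_reads(raw_reads, adapter3=adapter3, adapter5=adapter5,
                               min_len=config.min_len, max_len=config.max_len,
                               min_mean_quality=config.min_mean_quality, log=log))
    unique = collapse_reads(cleaned, drop_singletons=config.drop_singletons,
                            library_id=library_id)
    mapping = map_reads(unique, resources.genome_index, max_loci=config.max_loci)

    classes = ann.classify_reads(mapping.mapped, resources.ncrna_refs,
                                 gene_model=resources.gene_model)

    conserved_hits: list[ConservedHit] = []
    known_ids: set[str] = set()
    if resources.known_ref is not None:
        mapped_reads = [m.read for m in mapping.mapped]
        conserved_hits = match_known(mapped_reads, resources.known_ref,
                                     max_mismatch=config.known_max_mismatch)
        known_ids = {h.read_id for h in conserved_hits if h.conserved_call}

    thr = config.thresholds
    candidates: list[HairpinCandidate] = []
    best: list[HairpinCandidate] = []
    for m in mapping.mapped:
        if classes.get(m.read.read_id) is not ReadClass.other:
            continue
        if m.read.read_id in known_ids:
            continue
        cands = candidates_for_read(m, resources.genome_index, thresholds=thr,
                                    engine=engine)
        candidates.extend(cands)
        b = best_candidate(cands)
        if b is not None:
            b = apply_dominance(b, mapping.mapped, thresholds=thr)
            b = find_star_reads(b, mapping.mapped)
            if b.accepted:
                best.append(b)
    accepted = resolve_overlaps(best)

    classes = ann.apply_mirna_calls(classes, known_ids,
                                    [c.read_id for c in accepted])
    return LibraryResult(
        library_id=library_id, drop_log=log, unique_reads=unique,
        total_cleaned=log.kept, mapping=mapping, classes=classes,
        conserved_hits=conserved_hits, candidates=candidates, accepted=accepted)


@dataclass
class PipelineRun:
    libraries: list[LibraryResult]
    confirmed: list[ConfirmedCandidate]
    target_hits: list[TargetHit]
    families: list[set[str]]


def run_pipeline(libraries: dict[str, Iterable[RawRead]], adapter3: str,
                 resources: Resources, config: PipelineConfig | None = None,
                 adapter5: str | None = None, engine=None) -> PipelineRun:
    """Full two-library analysis over in-memory inputs.

    With a single library, cross-library confirmation is skipped and all
    accepted candidates proceed to target prediction.
    """
    config = config or PipelineConfig()
    results = [run_library(reads, adapter3, resources, config, adapter5=adapter5,
                           library_id=lib, engine=engine)
               for lib, reads in libraries.items()]
    if len(results) >= 2:
        confirmed = intersect_candidates(results[0].candidate_set,
                                         results[1].candidate_set,
                                         expr_fold_limit=config.expr_fold_limit)
        final = [c.candidate for c in confirmed]
    else:
        confirmed = []
        final = results[0].accepted
    matures = {c.read_id: c.mature_sequence for c in final}
    families = group_families(matures)
    hits: list[TargetHit] = []
    if resources.transcripts:
        mirna_seqs = {rid: seq for rid, seq in matures.items()}
        hits = scan_transcripts(mirna_seqs, resources.transcripts,
                                strict=config.strict_targets)
    return PipelineRun(libraries=results, confirmed=confirmed,
                       target_hits=hits, families=families)


def summary_report(run: PipelineRun) -> dict:
    """Every number here is recomputed from the stage outputs."""
    out: dict = {"libraries": {}}
    for lib in run.libraries:
        table = ann.summarize_classes(lib.classes, lib.unique_reads)
        lengths = length_distribution(lib.unique_reads)
        out["libraries"][lib.library_id] = {
            "raw_reads": lib.drop_log.kept + lib.drop_log.total_dropped,
            "cleaned_reads": lib.total_cleaned,
            "dropped": dict(lib.drop_log.reasons),
            "unique_reads": len(lib.unique_reads),
            "mapped_unique": len(lib.mapping.mapped),
            "unmapped_unique": len(lib.mapping.unmapped),
            "repetitive_unique": len(lib.mapping.repetitive),
            "conserved_mirnas": len({h.read_id for h in lib.conserved_hits
                                     if h.conserved_call}),
            "accepted_candidates": len(lib.accepted),
            "class_table": table.to_dict(orient="records"),
            "length_table": lengths.to_dict(orient="records"),
        }
    out["confirmed_candidates"] = len(run.confirmed)
    out["expression_consistent"] = sum(c.expression_consistent for c in run.confirmed)
    out["star_supported"] = sum(c.candidate.star_read_count > 0 for c in run.confirmed)
    out["families"] = len(run.families)
    out["family_sizes"] = sorted((len(f) for f in run.families), reverse=True)
    out["targeted_mirnas"] = len({h.mirna_id for h in run.target_hits})
    out["target_hits"] = len(run.target_hits)
    return out


def write_outputs(run: PipelineRun, outdir: str) -> None:
    from . import report as rep
    from .preprocess import write_collapsed
    from .mapping import write_bed
    from .targets import write_hits

    os.makedirs(outdir, exist_ok=True)
    for lib in run.libraries:
        prefix = os.path.join(outdir, lib.library_id)
        write_collapsed(lib.unique_reads, prefix + ".collapsed.fa")
        write_bed(lib.mapping.mapped, prefix + ".mapped.bed")
        rep.write_candidates_gff3(lib.accepted, prefix + ".candidates.gff3")
        rep.write_candidate_stats(lib.accepted, prefix + ".candidates.tsv")
        ann.summarize_classes(lib.classes, lib.unique_reads).to_csv(
            prefix + ".classes.tsv", sep="\t", index=False)
        length_distribution(lib.unique_reads).to_csv(
            prefix + ".lengths.tsv", sep="\t", index=False)
    confirmed = [c.candidate for c in run.confirmed]
    rep.write_candidates_gff3(confirmed, os.path.join(outdir, "confirmed.gff3"))
    rep.write_structures(confirmed, os.path.join(outdir, "confirmed.structures.txt"))
    write_hits(run.target_hits, os.path.join(outdir, "targets.tsv"))
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary_report(run), fh, indent=1, sort_keys=True)
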