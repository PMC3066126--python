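"""Raw small-RNA read cleaning and collapsing.

Mirrors the standard small-RNA preprocessing contract: locate and remove
the 3' adapter, drop 5'-adapter contaminants, low-quality reads, polyA
reads and inserts outside the 18-30 nt window, then collapse surviving
inserts to unique sequences with counts and (optionally) remove sequences
seen only once.  Every dropped read is tallied under a named reason so the
pipeline attrition is auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

from .sequence import to_rna, validate

MIN_LEN_DEFAULT = 18
MAX_LEN_DEFAULT = 30
ADAPTER_SEED = 8  # minimum matched adapter prefix
ADAPTER_MAX_MISMATCH = 1
POLYA_FRACTION = 0.80
MIN_MEAN_QUALITY = 20.0


@dataclass
class RawRead:
    """A single sequencing read, possibly still carrying adapter sequence."""

    sequence: str
    quality: list[int] | None = None
    library_id: str = "lib1"
    name: str = ""


@dataclass(frozen=True, order=True)
class UniqueRead:
    """A distinct insert sequence (RNA) with its per-library read count."""

    sequence: str
    count: int
    read_id: str = ""
    library_id: str = "lib1"


@dataclass
class DropLog:
    """Per-reason tally of removed reads."""

    reasons: Counter = field(default_factory=Counter)
    kept: int = 0

    def drop(self, reason: str) -> None:
        self.reasons[reason] += 1

    @property
    def total_dropped(self) -> int:
        return sum(self.reasons.values())


def find_adapter(insert: str, adapter: str, seed: int = ADAPTER_SEED,
                 max_mismatch: int = ADAPTER_MAX_MISMATCH) -> int:
    """Return the start of the best ungapped 3'-adapter occurrence, or -1.

    The leftmost position where at least ``seed`` nt of the adapter prefix
    align with at most ``max_mismatch`` mismatches wins; an adapter
    starting within the last ``seed-1`` nt cannot be located.
    """
    n, m = len(insert), len(adapter)
    for p in range(0, n - seed + 1):
        k = min(m, n - p)
        mism = sum(1 for i in range(k) if insert[p + i] != adapter[i])
        if mism <= max_mismatch:
            return p
    return -1


def _contains_approx(read: str, query: str, max_mismatch: int = ADAPTER_MAX_MISMATCH) -> bool:
    n, m = len(read), len(query)
    for p in range(0, n - m + 1):
        if sum(1 for i in range(m) if read[p + i] != query[i]) <= max_mismatch:
            return True
    return False


def clean_reads(reads: Iterable[RawRead], adapter3: str, adapter5: str | None = None,
                min_len: int = MIN_LEN_DEFAULT, max_len: int = MAX_LEN_DEFAULT,
                min_mean_quality: float = MIN_MEAN_QUALITY,
                log: DropLog | None = None) -> Iterator[RawRead]:
    """Yield adapter-free, quality- and length-filtered reads.

    Reads whose 3' adapter cannot be located are treated as contaminants
    and dropped; reads containing the 5' adapter are dropped; FASTA input
    (``quality is None``) skips the quality stage.
    """
    if not adapter3:
        raise ValueError("3' adapter must be non-empty")
    adapter3 = validate(adapter3, "DNA" if "T" in adapter3.upper() else "RNA")
    if log is None:
        log = DropLog()
    for read in reads:
        seq = read.sequence.upper()
        if read.quality is not None:
            if len(read.quality) != len(seq):
                raise ValueError(f"quality length mismatch for read {read.name!r}")
            if sum(read.quality) / len(read.quality) < min_mean_quality:
                log.drop("low_quality")
                continue
        if adapter5 and _contains_approx(seq, adapter5.upper()):
            log.drop("adapter5_contaminant")
            continue
        pos = find_adapter(seq, adapter3)
        if pos < 0:
            log.drop("no_adapter3")
            continue
        insert = seq[:pos]
        if not insert:
            log.drop("empty_insert")
            continue
        if insert.count("A") / len(insert) >= POLYA_FRACTION:
            log.drop("polyA")
            continue
        if len(insert) < min_len:
            log.drop("too_short")
            continue
        if len(insert) > max_len:
            log.drop("too_long")
            continue
        log.kept += 1
        yield RawRead(sequence=insert,
                      quality=read.quality[:len(insert)] if read.quality else None,
                      library_id=read.library_id, name=read.name)


def collapse_reads(reads: Iterable[RawRead], drop_singletons: bool = True,
                   library_id: str | None = None) -> list[UniqueRead]:
    """Collapse cleaned reads to unique RNA sequences with counts.

    Counts before singleton removal sum to the number of input reads.
    Read ids are assigned in decreasing-count (then lexicographic) order,
    so collapsing is deterministic and idempotent.
    """
    counts: Counter[str] = Counter()
    lib = library_id
    for read in reads:
        counts[to_rna(read.sequence)] += 1
        if lib is None:
            lib = read.library_id
    lib = lib or "lib1"
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for i, (seq, count) in enumerate(ordered, start=1):
        if drop_singletons and count < 2:
            continue
        out.append(UniqueRead(sequence=seq, count=count, read_id=f"t{i:07d}", library_id=lib))
    return out


def length_distribution(reads: Iterable[UniqueRead]):
    """Distinct/total tallies and total-count fractions per insert length."""
    import pandas as pd

    rows: dict[int, list[int]] = {}
    for r in reads:
        d = rows.setdefault(len(r.sequence), [0, 0])
        d[0] += 1
        d[1] += r.count
    table = pd.DataFrame(
        [(L, d[0], d[1]) for L, d in sorted(rows.items())],
        columns=["length", "distinct_count", "total_count"],
    )
    total = table["total_count"].sum()
    table["total_fraction"] = table["total_count"] / total if total else 0.0
    return table


# ---------------------------------------------------------------------------
# file I/O

def read_raw(path: str, library_id: str = "lib1") -> Iterator[RawRead]:
    """Stream reads from FASTQ (Sanger quality) or FASTA, sniffed by content."""
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(path, fmt):
        qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
        yield RawRead(sequence=str(rec.seq), quality=qual, library_id=library_id, name=rec.id)


def write_collapsed(reads: Iterable[UniqueRead], path: str) -> None:
    """Write collapsed reads as FASTA with ``readID_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}_x{r.count}\n{r.sequence}\n")


def read_collapsed(path: str, library_id: str = "lib1") -> list[UniqueRead]:
    """Read a ``readID_xCOUNT`` FASTA back into UniqueRead records."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        read_id, _, count = rec.id.rpartition("_x")
        out.append(UniqueRead(sequence=to_rna(str(rec.seq)), count=int(count),
                              read_id=read_id, library_id=library_id))
    return out
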