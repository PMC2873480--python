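"""Small-RNA read processing: adapter clipping, collapsing, contig QC,
exact genome mapping, multimapper exclusion and read-stack construction.

Reads are 3'-adapter-bearing sequencer output. The pipeline keeps only
inserts in a configurable length window (default 18-30 nt, matching a
20-30 nt gel size fraction with trimming tolerance), maps them perfectly
(no edits) to QC-passing contigs, discards reads hitting the genome five
times or more (repeat-derived), and merges the surviving hits into
overlap-connected stacks that guide hairpin excision.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from ._seq import VALID_ALPHABET, revcomp, to_dna

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence with its occurrence count."""

    id: str
    seq: str
    count: int

    def __post_init__(self) -> None:
        if not self.seq or set(self.seq) - VALID_ALPHABET:
            raise ValueError(f"invalid sequence for {self.id!r}: {self.seq!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class ContigRecord:
    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_fraction(self) -> float:
        return self.seq.upper().count("N") / len(self.seq) if self.seq else 0.0


@dataclass(frozen=True)
class GenomeHit:
    """A perfect occurrence of a read on a contig, 0-based half-open."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class ReadStack:
    """Overlap-connected hits on one contig strand; guides hairpin excision."""

    contig_id: str
    strand: str
    start: int
    end: int
    hits: list[GenomeHit] = field(default_factory=list)


@dataclass
class PreprocessConfig:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_adapter_overlap: int = 6
    insert_min: int = 18
    insert_max: int = 30
    contig_min_len: int = 200
    contig_max_n: float = 0.20
    max_hits_for_prediction: int = 4  # reads with more hits are repeat-derived

    def __post_init__(self) -> None:
        if self.insert_min > self.insert_max:
            raise ValueError("insert_min must be <= insert_max")


@dataclass
class ClipReport:
    kept: int = 0
    dropped_no_adapter: int = 0
    dropped_length: int = 0


def clip_adapter(
    raw_reads: list[str], config: PreprocessConfig
) -> tuple[list[str], ClipReport]:
    """Clip the 3' adapter off each raw read and keep size-selected inserts.

    The insert is the prefix before the leftmost position where at least
    ``min_adapter_overlap`` nucleotides of the adapter prefix match exactly.
    Reads with no such match are dropped (no evidence the insert ended);
    inserts outside [insert_min, insert_max] are dropped.
    """
    adapter = to_dna(config.adapter)
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < config.min_adapter_overlap:
        raise ValueError("adapter shorter than min_adapter_overlap")
    report = ClipReport()
    inserts: list[str] = []
    k = config.min_adapter_overlap
    for raw in raw_reads:
        read = to_dna(raw)
        pos = _leftmost_adapter_match(read, adapter, k)
        if pos is None:
            report.dropped_no_adapter += 1
            continue
        insert = read[:pos]
        if not (config.insert_min <= len(insert) <= config.insert_max):
            report.dropped_length += 1
            continue
        inserts.append(insert)
        report.kept += 1
    return inserts, report


def _leftmost_adapter_match(read: str, adapter: str, min_overlap: int) -> int | None:
    # a position matches iff at least min_overlap adapter-prefix nucleotides
    # start there; equivalently the first min_overlap characters match
    key = adapter[:min_overlap]
    pos = read.find(key)
    return pos if pos >= 0 else None


def collapse_reads(inserts: list[str]) -> list[CollapsedRead]:
    """Collapse identical inserts (U==T) into counted unique reads.

    Output is sorted by count descending, ties broken lexicographically, and
    the total count equals the number of input inserts exactly.
    """
    counts: dict[str, int] = defaultdict(int)
    for ins in inserts:
        counts[to_dna(ins)] += 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(id=f"seq_{i + 1}", seq=seq, count=c)
        for i, (seq, c) in enumerate(ordered)
    ]


def filter_contigs(
    contigs: list[ContigRecord], config: PreprocessConfig | None = None
) -> list[ContigRecord]:
    """Keep contigs that are long enough and have few enough uncalled bases.

    A contig passes iff length >= contig_min_len AND n_fraction < contig_max_n
    (both comparisons strict on the failing side).
    """
    config = config or PreprocessConfig()
    return [
        c
        for c in contigs
        if c.length >= config.contig_min_len and c.n_fraction < config.contig_max_n
    ]


def map_reads(
    collapsed: list[CollapsedRead], contigs: list[ContigRecord]
) -> list[GenomeHit]:
    """Report every perfect occurrence of every read on both contig strands.

    U is treated as T; N never matches. Hits come back sorted by
    (contig id, start, strand, read id) for determinism.
    """
    by_len: dict[int, dict[str, list[tuple[str, str]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for read in collapsed:
        seq = to_dna(read.seq)
        if set(seq) - VALID_ALPHABET or "N" in seq:
            log.warning("read %s skipped: unmappable sequence", read.id)
            continue
        by_len[len(seq)][seq].append((read.id, "+"))
        by_len[len(seq)][revcomp(seq)].append((read.id, "-"))

    hits: list[GenomeHit] = []
    for contig in contigs:
        cseq = to_dna(contig.seq)
        for length, lookup in by_len.items():
            for start in range(len(cseq) - length + 1):
                window = cseq[start : start + length]
                for read_id, strand in lookup.get(window, ()):
                    hits.append(
                        GenomeHit(read_id, contig.id, start, start + length, strand)
                    )
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand, h.read_id))
    return hits


def filter_multimappers(
    hits: list[GenomeHit], config: PreprocessConfig | None = None
) -> list[GenomeHit]:
    """Drop all hits of reads that map more often than allowed.

    Reads with >= max_hits_for_prediction + 1 total genome hits (both strands
    pooled) are repeat-derived and contribute nothing to hairpin discovery.
    """
    config = config or PreprocessConfig()
    n_hits: dict[str, int] = defaultdict(int)
    for h in hits:
        n_hits[h.read_id] += 1
    return [h for h in hits if n_hits[h.read_id] <= config.max_hits_for_prediction]


def build_stacks(hits: list[GenomeHit]) -> list[ReadStack]:
    """Merge hits on the same contig+strand transitively wherever they overlap."""
    grouped: dict[tuple[str, str], list[GenomeHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.contig_id, h.strand)].append(h)

    stacks: list[ReadStack] = []
    for (contig_id, strand), group in grouped.items():
        group.sort(key=lambda h: (h.start, h.end))
        current: ReadStack | None = None
        for h in group:
            if current is not None and h.start < current.end:
                current.end = max(current.end, h.end)
                current.hits.append(h)
            else:
                current = ReadStack(contig_id, strand, h.start, h.end, [h])
                stacks.append(current)
    stacks.sort(key=lambda s: (s.contig_id, s.start, s.strand))
    return stacks
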