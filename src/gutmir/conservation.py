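"""Conservation-based ortholog search, independent of genome mapping.

The genome assembly the discovery stage maps against has imperfect coverage,
so abundantly sequenced reads that match a known mammalian mature miRNA
(within a small edit distance) are rescued as low-confidence orthologs even
when they hit no contig. "Edits" are unit-cost Levenshtein operations
(substitution, insertion, deletion) under global alignment over the full
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from ._seq import to_dna, to_rna
from .reads import CollapsedRead, ContigRecord


@dataclass(frozen=True)
class CatalogEntry:
    """A known mature miRNA with species metadata (miRBase-like)."""

    name: str
    species: str
    mature: str  # RNA spelling preserved for output; matching uses U==T
    primate_specific: bool = False

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based) of the mature — the target-recognition anchor."""
        return to_rna(self.mature)[1:8]


@dataclass
class OrthologAssignment:
    catalog_name: str
    assigned_seq: str  # the most abundant matching read (DNA spelling)
    support_count: int
    edits: int
    maps_to_genome: bool = False
    primate_specific: bool = False


def edit_distance(a: str, b: str, max_edits: int | None = None) -> int:
    """Global (NW) Levenshtein distance; -1 if it exceeds ``max_edits``."""
    k = -1 if max_edits is None else max_edits
    return edlib.align(to_dna(a), to_dna(b), mode="NW", task="distance", k=k)[
        "editDistance"
    ]


def abundant_sequences(
    collapsed: list[CollapsedRead], min_count: int = 10
) -> list[CollapsedRead]:
    """Keep reads perfectly represented ``min_count`` or more times (inclusive)."""
    return [r for r in collapsed if r.count >= min_count]


def match_orthologs(
    abundant: list[CollapsedRead],
    catalog: list[CatalogEntry],
    max_edits: int = 2,
) -> list[OrthologAssignment]:
    """Assign each catalog entry the most abundant read within ``max_edits``.

    Ties on count break by smaller edit distance, then lexicographically
    smaller sequence. One assignment per catalog entry; several entries may
    claim the same read (paralogs).
    """
    assignments: list[OrthologAssignment] = []
    for entry in catalog:
        best: tuple[int, int, str] | None = None  # (-count, edits, seq)
        for read in abundant:
            d = edit_distance(read.seq, entry.mature, max_edits=max_edits)
            if d < 0:
                continue
            key = (-read.count, d, read.seq)
            if best is None or key < best:
                best = key
        if best is not None:
            assignments.append(
                OrthologAssignment(
                    catalog_name=entry.name,
                    assigned_seq=best[2],
                    support_count=-best[0],
                    edits=best[1],
                    primate_specific=entry.primate_specific,
                )
            )
    return assignments


def partition_by_genome(
    assignments: list[OrthologAssignment], contigs: list[ContigRecord]
) -> tuple[list[OrthologAssignment], list[OrthologAssignment]]:
    """Split assignments into (mapped, unmapped) by perfect both-strand search."""
    from ._seq import revcomp

    mapped: list[OrthologAssignment] = []
    unmapped: list[OrthologAssignment] = []
    for a in assignments:
        seq = to_dna(a.assigned_seq)
        rc = revcomp(seq)
        found = any(seq in to_dna(c.seq) or rc in to_dna(c.seq) for c in contigs)
        a.maps_to_genome = found
        (mapped if found else unmapped).append(a)
    return mapped, unmapped


@dataclass
class ContaminationReport:
    clean: bool
    warnings: list[str] = field(default_factory=list)


def contamination_check(assignments: list[OrthologAssignment]) -> ContaminationReport:
    """Flag any primate-specific ortholog assignment.

    Pig RNA should not yield primate-specific miRNAs; any such match suggests
    sample or library contamination.
    """
    warnings = [
        f"primate-specific catalog entry {a.catalog_name!r} matched read "
        f"{a.assigned_seq} (count {a.support_count}, {a.edits} edits)"
        for a in assignments
        if a.primate_specific
    ]
    return ContaminationReport(clean=not warnings, warnings=warnings)
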