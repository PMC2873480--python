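"""Genomic organization of validated precursors: placement on subject
sequences, chromosomal duplications, clusters with bp spans, alternative
precursors for the same mature, and per-chromosome distribution.

Placement is an exact both-strand search over user-supplied subject FASTA
(chromosome labels are read from a ``chr=`` header token); a relaxed mode
(up to 2 mismatches, no gaps) is available for conserved precursors and off
by default. Printed coordinates follow the 1-based inclusive convention with
start > end encoding minus orientation; internally everything is 0-based
half-open plus a strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from ._seq import revcomp, to_dna


@dataclass(frozen=True)
class Subject:
    id: str
    seq: str
    chromosome: str | None = None

    @classmethod
    def from_fasta_record(cls, rec_id: str, description: str, seq: str) -> "Subject":
        chrom = None
        for token in description.split():
            if token.startswith("chr="):
                chrom = token[4:]
        return cls(id=rec_id, seq=seq, chromosome=chrom)


@dataclass(frozen=True)
class PrecursorLocus:
    precursor_id: str
    subject_id: str
    chromosome: str | None
    start: int  # internal 0-based half-open, plus-strand coordinates
    end: int
    strand: str

    @property
    def printed(self) -> tuple[int, int]:
        """1-based inclusive convention; start > end encodes minus orientation."""
        if self.strand == "+":
            return self.start + 1, self.end
        return self.end, self.start + 1

    @classmethod
    def from_printed(
        cls, precursor_id: str, subject_id: str, chromosome: str | None, s: int, e: int
    ) -> "PrecursorLocus":
        if s <= e:
            return cls(precursor_id, subject_id, chromosome, s - 1, e, "+")
        return cls(precursor_id, subject_id, chromosome, e - 1, s, "-")

    @property
    def inclusive_interval(self) -> tuple[int, int]:
        """Orientation-free 1-based inclusive interval [lo, hi]."""
        s, e = self.printed
        return (s, e) if s <= e else (e, s)


@dataclass
class DuplicationReport:
    precursor_id: str
    loci: list[PrecursorLocus]
    identity_percent: float


@dataclass
class ClusterReport:
    member_ids: list[str]
    subject_id: str
    span: int  # max printed coordinate - min printed coordinate over members


@dataclass
class AlternativePrecursorReport:
    mature: str
    precursor_ids: list[str]
    overlap: int  # 1-based inclusive intersection length


@dataclass
class ChromosomeSummary:
    counts: dict[str, int]
    percents: dict[str, int]
    nd_count: int
    nd_percent: int


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def locate(
    precursors: dict[str, str],
    subjects: list[Subject],
    max_mismatches: int = 0,
) -> list[PrecursorLocus]:
    """Report every perfect (or, in relaxed mode, near-perfect ungapped)
    occurrence of each precursor on both strands of the subjects."""
    loci: list[PrecursorLocus] = []
    for pid in sorted(precursors):
        pseq = to_dna(precursors[pid])
        for subj in subjects:
            sseq = to_dna(subj.seq)
            for strand, query in (("+", pseq), ("-", revcomp(pseq))):
                for start in _occurrences(sseq, query, max_mismatches):
                    loci.append(
                        PrecursorLocus(
                            precursor_id=pid,
                            subject_id=subj.id,
                            chromosome=subj.chromosome,
                            start=start,
                            end=start + len(query),
                            strand=strand,
                        )
                    )
    loci.sort(key=lambda l: (l.precursor_id, l.subject_id, l.start, l.strand))
    return loci


def _occurrences(haystack: str, needle: str, max_mismatches: int) -> list[int]:
    if not needle or len(needle) > len(haystack):
        return []
    if max_mismatches == 0:
        out = []
        pos = haystack.find(needle)
        while pos >= 0:
            out.append(pos)
            pos = haystack.find(needle, pos + 1)
        return out
    out = []
    n = len(needle)
    for pos in range(len(haystack) - n + 1):
        mism = 0
        window = haystack[pos : pos + n]
        for a, b in zip(window, needle):
            if a != b or a == "N":
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            out.append(pos)
    return out


def find_duplications(
    loci: list[PrecursorLocus], subjects: list[Subject]
) -> list[DuplicationReport]:
    """One report per precursor placed at two or more genomic loci.

    Identity is the percent of matching positions between the oriented
    genomic slices (100% under perfect-match placement by construction).
    """
    subj_by_id = {s.id: to_dna(s.seq) for s in subjects}
    by_precursor: dict[str, list[PrecursorLocus]] = {}
    for l in loci:
        by_precursor.setdefault(l.precursor_id, []).append(l)
    reports = []
    for pid, group in sorted(by_precursor.items()):
        if len(group) < 2:
            continue
        slices = []
        for l in group:
            s = subj_by_id[l.subject_id][l.start : l.end]
            slices.append(revcomp(s) if l.strand == "-" else s)
        ref = slices[0]
        matches = [
            sum(a == b for a, b in zip(ref, s)) / max(len(ref), len(s)) for s in slices[1:]
        ]
        reports.append(
            DuplicationReport(
                precursor_id=pid,
                loci=group,
                identity_percent=round(100 * min(matches), 1),
            )
        )
    return reports


def find_clusters(
    loci: list[PrecursorLocus], max_gap: int = 10_000
) -> list[ClusterReport]:
    """Single-linkage grouping of loci on the same subject with gap <= max_gap.

    The span is the difference of the extreme printed coordinates over the
    cluster's members (not the inclusive length).
    """
    by_subject: dict[str, list[PrecursorLocus]] = {}
    for l in loci:
        by_subject.setdefault(l.subject_id, []).append(l)
    reports = []
    for subject_id, group in sorted(by_subject.items()):
        group.sort(key=lambda l: l.start)
        cluster: list[PrecursorLocus] = []
        clusters: list[list[PrecursorLocus]] = []
        for l in group:
            if cluster and l.start - max(m.end for m in cluster) <= max_gap:
                cluster.append(l)
            else:
                cluster = [l]
                clusters.append(cluster)
        for members in clusters:
            if len(members) < 2:
                continue
            coords = [c for m in members for c in m.printed]
            reports.append(
                ClusterReport(
                    member_ids=[m.precursor_id for m in members],
                    subject_id=subject_id,
                    span=max(coords) - min(coords),
                )
            )
    return reports


def find_alternatives(
    loci: list[PrecursorLocus], mature_by_precursor: dict[str, str]
) -> list[AlternativePrecursorReport]:
    """Alternative precursors: two hairpins housing the identical mature whose
    genomic intervals overlap; the overlap is the 1-based inclusive
    intersection length."""
    by_mature: dict[str, list[PrecursorLocus]] = {}
    for l in loci:
        mature = mature_by_precursor.get(l.precursor_id)
        if mature is not None:
            by_mature.setdefault(to_dna(mature), []).append(l)
    reports = []
    for mature, group in sorted(by_mature.items()):
        for a, b in combinations(group, 2):
            if a.precursor_id == b.precursor_id or a.subject_id != b.subject_id:
                continue
            (alo, ahi), (blo, bhi) = a.inclusive_interval, b.inclusive_interval
            overlap = min(ahi, bhi) - max(alo, blo) + 1
            if overlap >= 1:
                reports.append(
                    AlternativePrecursorReport(
                        mature=mature,
                        precursor_ids=sorted([a.precursor_id, b.precursor_id]),
                        overlap=overlap,
                    )
                )
    return reports


def chromosome_summary(
    loci: list[PrecursorLocus], all_precursor_ids: list[str]
) -> ChromosomeSummary:
    """Per-chromosome precursor counts and percentages over all validated
    precursors; unplaced precursors (and placements on unlabeled subjects)
    count as ND."""
    total = len(set(all_precursor_ids))
    if total == 0:
        raise ValueError("no validated precursors to summarize")
    placed: dict[str, set[str]] = {}
    located_ids = set()
    for l in loci:
        if l.chromosome is None:
            continue
        placed.setdefault(l.chromosome, set()).add(l.precursor_id)
        located_ids.add(l.precursor_id)
    counts = {chrom: len(ids) for chrom, ids in sorted(placed.items())}
    percents = {c: _round_half_up(100 * n / total) for c, n in counts.items()}
    nd = total - len(located_ids & set(all_precursor_ids))
    return ChromosomeSummary(
        counts=counts,
        percents=percents,
        nd_count=nd,
        nd_percent=_round_half_up(100 * nd / total),
    )
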