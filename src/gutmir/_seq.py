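"""Shared sequence helpers (DNA/RNA normalization, reverse complement, FASTA IO)."""

from __future__ import annotations

from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTUN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def to_dna(seq: str) -> str:
    """Uppercase and collapse U onto T so RNA and DNA spellings compare equal."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT)[::-1]


def is_valid(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= VALID_ALPHABET


def read_fasta(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, description, sequence) triples from a FASTA file."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, rec.description, str(rec.seq).upper()


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (header, sequence) pairs; header may contain spaces (id = first token)."""
    recs = []
    for header, seq in records:
        parts = header.split(None, 1)
        rec = SeqRecord(Seq(seq), id=parts[0], description=parts[1] if len(parts) > 1 else "")
        recs.append(rec)
    SeqIO.write(recs, str(path), "fasta-2line")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq).upper()


def write_fastq(path, records: Iterable[tuple[str, str]]) -> None:
    recs = []
    for name, seq in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")
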