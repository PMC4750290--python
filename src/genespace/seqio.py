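"""Sequence records, read pairs, contig sets, and FASTA/FASTQ I/O.

Every stage of the pipeline passes sequence data through the three small
containers defined here.  Parsing is delegated to Biopython's low-level
iterators; this module adds the strict validation the downstream mapper and
assembler rely on (5-letter uppercase alphabet, Sanger Phred+33 qualities,
unique contig ids, positional mate pairing).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "ContigSet",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_FASTA_WIDTH = 80
_MAX_PHRED = 60


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed or contract-violating sequence files."""


@dataclass
class SequenceRecord:
    """A read or contig: id, uppercase ACGTN sequence, optional Phred scores."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be non-empty and whitespace-free: {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        if self.quality is not None:
            if len(self.quality) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.quality)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if any(q < 0 or q > _MAX_PHRED for q in self.quality):
                raise ValueError(f"record {self.id!r}: Phred scores must be in [0, {_MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """Two mates of one sequenced fragment, matched positionally."""

    pair_id: str
    r1: SequenceRecord
    r2: SequenceRecord


@dataclass
class ContigSet:
    """An ordered, id-unique collection of quality-free records."""

    label: str = ""
    contigs: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.contigs:
            if rec.id in seen:
                raise ValueError(f"duplicate contig id {rec.id!r} in set {self.label!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.contigs)

    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _clean_sequence(raw: str, where: str) -> str:
    seq = raw.upper().replace(" ", "")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ParseError(f"{where}: characters outside ACGTN: {sorted(bad)}")
    if not seq:
        raise ParseError(f"{where}: empty sequence")
    return seq


def read_fasta(path: str | Path, label: str | None = None) -> ContigSet:
    """Read a (possibly gzipped) FASTA file into a ContigSet.

    Order is preserved, sequences are uppercased, duplicate ids and empty
    sequences are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for i, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            rec_id = title.split()[0] if title.split() else ""
            where = f"{path}: record {i} ({rec_id or 'no id'})"
            if not rec_id:
                raise ParseError(f"{where}: missing id in header")
            if rec_id in seen:
                raise ParseError(f"{where}: duplicate id")
            seen.add(rec_id)
            records.append(SequenceRecord(rec_id, _clean_sequence(seq, where)))
    return ContigSet(label=label if label is not None else Path(path).name, contigs=records)


def write_fasta(contigs: ContigSet | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 80 columns; round-trips with read_fasta."""
    with _open_text(path, "wt") as fh:
        for rec in contigs:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), _FASTA_WIDTH):
                fh.write(rec.sequence[i : i + _FASTA_WIDTH] + "\n")


def _decode_phred(qual: str, where: str) -> list[int]:
    scores = [ord(c) - 33 for c in qual]
    if any(q < 0 or q > _MAX_PHRED for q in scores):
        raise ParseError(
            f"{where}: quality characters outside the Sanger Phred+33 range "
            "(only offset-33 encoding is accepted)"
        )
    return scores


def _fastq_records(path: str | Path) -> Iterator[SequenceRecord]:
    with _open_text(path) as fh:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh), start=1):
            rec_id = title.split()[0] if title.split() else ""
            where = f"{path}: record {i} ({rec_id or 'no id'})"
            if not rec_id:
                raise ParseError(f"{where}: missing id")
            sequence = _clean_sequence(seq, where)
            if len(qual) != len(sequence):
                raise ParseError(f"{where}: quality/sequence length mismatch")
            yield SequenceRecord(rec_id, sequence, _decode_phred(qual, where))


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream single-end FASTQ records (Sanger Phred+33)."""
    return _fastq_records(path)


def _strip_mate_suffix(rid: str) -> str:
    if len(rid) > 2 and rid[-2] == "/" and rid[-1] in "12":
        return rid[:-2]
    return rid


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files, matched positionally.

    Record i of R1 is paired with record i of R2 regardless of id decoration;
    a count mismatch between the files is an error.  Memory use is one pair.
    """
    it1, it2 = _fastq_records(path_r1), _fastq_records(path_r2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            longer = path_r2 if r1 is None else path_r1
            raise ParseError(
                f"mate-count mismatch after {n} pairs: {longer} has more records"
            )
        n += 1
        yield ReadPair(_strip_mate_suffix(r1.id), r1, r2)


def _encode_phred(rec: SequenceRecord) -> str:
    qual = rec.quality if rec.quality is not None else [40] * len(rec)
    return "".join(chr(q + 33) for q in qual)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], path_r1: str | Path, path_r2: str | Path
) -> int:
    """Write pairs to two Sanger-FASTQ files; returns the number of pairs."""
    n = 0
    with _open_text(path_r1, "wt") as f1, _open_text(path_r2, "wt") as f2:
        for pair in pairs:
            f1.write(f"@{pair.r1.id}\n{pair.r1.sequence}\n+\n{_encode_phred(pair.r1)}\n")
            f2.write(f"@{pair.r2.id}\n{pair.r2.sequence}\n+\n{_encode_phred(pair.r2)}\n")
            n += 1
    return n
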