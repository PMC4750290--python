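"""Quality trimming of paired-end reads.

A base is kept only if its Phred score is at least ``min_phred`` (default 30)
and it is unambiguous; a read is reduced to its single longest contiguous run
of such bases and rejected if that run is shorter than ``min_length``
(default 30 nt).  Interior deletion of low-quality bases would fabricate
chimeric sequence, so only one contiguous run ever survives; equal-length
runs break to the leftmost.  A pair is kept only when both mates survive,
because downstream recruitment relies on intact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .seqio import ReadPair, SequenceRecord

__all__ = ["TrimParams", "TrimReport", "trim_record", "trim_pairs"]


@dataclass(frozen=True)
class TrimParams:
    min_phred: int = 30
    min_length: int = 30
    forbid_ambiguous: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_phred <= 60:
            raise ValueError("min_phred must be in [0, 60]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class TrimReport:
    pairs_in: int = 0
    pairs_kept: int = 0

    @property
    def retention_fraction(self) -> float:
        # degenerate empty input reports full retention
        return self.pairs_kept / self.pairs_in if self.pairs_in > 0 else 1.0

    def as_tsv(self) -> str:
        return (
            "pairs_in\tpairs_kept\tretention_fraction\n"
            f"{self.pairs_in}\t{self.pairs_kept}\t{self.retention_fraction:.4f}\n"
        )


def trim_record(read: SequenceRecord, params: TrimParams = TrimParams()) -> SequenceRecord | None:
    """Longest-clean-run trimming; returns None when the read is rejected."""
    if read.quality is None:
        raise ValueError(f"read {read.id!r} has no qualities; trimming needs Phred scores")
    seq, qual = read.sequence, read.quality
    best_start, best_len = 0, 0
    run_start = 0
    i = 0
    n = len(seq)
    while i <= n:
        clean = i < n and qual[i] >= params.min_phred and not (
            params.forbid_ambiguous and seq[i] == "N"
        )
        if not clean:
            run_len = i - run_start
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = i + 1
        i += 1
    if best_len < params.min_length:
        return None
    if best_len == n:
        return read
    return SequenceRecord(
        read.id,
        seq[best_start : best_start + best_len],
        qual[best_start : best_start + best_len],
    )


def trim_pairs(
    pairs: Iterable[ReadPair], params: TrimParams = TrimParams(), report: TrimReport | None = None
) -> Iterator[ReadPair]:
    """Trim a stream of pairs, keeping a pair only if both mates survive.

    The report, when supplied, is updated in place as the stream is consumed
    (streams cannot return a summary before exhaustion).
    """
    for pair in pairs:
        if report is not None:
            report.pairs_in += 1
        t1 = trim_record(pair.r1, params)
        if t1 is None:
            continue
        t2 = trim_record(pair.r2, params)
        if t2 is None:
            continue
        if report is not None:
            report.pairs_kept += 1
        yield ReadPair(pair.pair_id, t1, t2)


def trim_pair_list(
    pairs: Iterable[ReadPair], params: TrimParams = TrimParams()
) -> tuple[list[ReadPair], TrimReport]:
    """Eager convenience wrapper: trimmed pairs plus the final report."""
    report = TrimReport()
    kept = list(trim_pairs(pairs, params, report))
    return kept, report
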