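"""The outer iterative extraction-and-assembly loop.

Each iteration maps the full trimmed read set against the current reference
(the transcript set on iteration 1, the previous iteration's contigs after
that), extracts every pair with a mapped mate, and assembles the recruited
short reads together with trusted long input (raw long reads on iteration 1,
previous contigs thereafter).  Because the reference gains the intronic and
flanking sequence assembled in earlier rounds, each pass recruits reads a
little deeper into the gene space, until contig count and total bases stop
changing and the run plateaus.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .assemble import AssemblyParams, assemble
from .assess import compute_n50
from .qc import TrimParams
from .recruit import RecruitParams, build_index, recruit_pairs
from .seqio import ContigSet, ReadPair, SequenceRecord, write_fasta

__all__ = [
    "ProtocolParams",
    "IterationStats",
    "classify_by_length",
    "run_iteration",
    "run_protocol",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProtocolParams:
    max_iterations: int = 6
    plateau_tolerance: float = 0.01
    short_long_boundary: int = 128
    recruit: RecruitParams = field(default_factory=RecruitParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    trim: TrimParams = field(default_factory=TrimParams)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.plateau_tolerance < 1:
            raise ValueError("plateau_tolerance must be in (0, 1)")


@dataclass
class IterationStats:
    iteration: int
    n_contigs: int
    total_bases: int
    mean_length: float
    min_length: int
    max_length: int
    n50: int
    pairs_recruited: int
    pct_reads_mapped: float
    pct_multi_hit: float

    TSV_HEADER = (
        "iteration\tn_contigs\ttotal_bases\tmean_length\tmin_length\tmax_length\t"
        "n50\tpairs_recruited\tpct_reads_mapped\tpct_multi_hit"
    )

    def as_tsv_row(self) -> str:
        return (
            f"{self.iteration}\t{self.n_contigs}\t{self.total_bases}\t"
            f"{self.mean_length:.1f}\t{self.min_length}\t{self.max_length}\t{self.n50}\t"
            f"{self.pairs_recruited}\t{self.pct_reads_mapped:.2f}\t{self.pct_multi_hit:.2f}"
        )


def classify_by_length(
    reads: Iterable[SequenceRecord], boundary: int = 128
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split reads at the short/long boundary (boundary length inclusive short)."""
    short: list[SequenceRecord] = []
    long: list[SequenceRecord] = []
    for rec in reads:
        (short if len(rec) <= boundary else long).append(rec)
    return short, long


def run_iteration(
    reference: ContigSet,
    all_pairs: Sequence[ReadPair],
    long_input: ContigSet,
    params: ProtocolParams = ProtocolParams(),
    label: str = "iter",
) -> tuple[ContigSet, IterationStats, int]:
    """One recruit-then-assemble pass; returns (contigs, stats, pairs_recruited)."""
    if len(reference) == 0:
        raise ValueError("reference must be non-empty")
    index = build_index(reference, params.recruit)
    result = recruit_pairs(all_pairs, index, params.recruit)
    if not result.recruited:
        logger.warning("no pairs recruited against reference %r", reference.label)
        contigs = ContigSet(label=label)
    else:
        reads = [r for pair in result.recruited for r in (pair.r1, pair.r2)]
        short, long_extra = classify_by_length(reads, params.short_long_boundary)
        long_all = list(long_input) + long_extra
        contigs = assemble(short, long_all, params.assembly, label=label)
    lengths = [len(c) for c in contigs]
    stats = IterationStats(
        iteration=0,  # caller assigns
        n_contigs=len(lengths),
        total_bases=sum(lengths),
        mean_length=round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
        min_length=min(lengths) if lengths else 0,
        max_length=max(lengths) if lengths else 0,
        n50=compute_n50(contigs) if lengths else 0,
        pairs_recruited=result.stats.pairs_recruited,
        pct_reads_mapped=result.stats.pct_mapped,
        pct_multi_hit=result.stats.pct_multi_hit,
    )
    return contigs, stats, result.stats.pairs_recruited


def _rel_change(new: int, old: int) -> float:
    return abs(new - old) / old if old else float("inf")


def _sha1(contigs: ContigSet) -> str:
    h = hashlib.sha1()
    for c in contigs:
        h.update(c.id.encode())
        h.update(c.sequence.encode())
    return h.hexdigest()


def run_protocol(
    unigene: ContigSet,
    pairs: Sequence[ReadPair],
    raw_long_reads: ContigSet | None = None,
    params: ProtocolParams = ProtocolParams(),
    out_dir: str | Path | None = None,
) -> tuple[ContigSet, list[IterationStats]]:
    """Run the full iterative protocol to plateau or ``max_iterations``.

    Iteration 1 maps against the transcript set and assembles with the raw
    long reads as trusted input; every later iteration maps against — and
    trusts — the previous iteration's contigs.  The loop stops early when the
    relative changes of both contig count and total bases fall below
    ``plateau_tolerance``.
    """
    if len(unigene) == 0:
        raise ValueError("unigene reference must be non-empty")
    if raw_long_reads is None:
        raw_long_reads = ContigSet(label="long_reads")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    reference = unigene
    long_input = raw_long_reads
    history: list[IterationStats] = []
    contigs = ContigSet(label="final")
    manifest: dict = {"params": asdict(params), "iterations": []}
    for j in range(1, params.max_iterations + 1):
        contigs, stats, _ = run_iteration(
            reference, pairs, long_input, params, label=f"iter{j}"
        )
        stats.iteration = j
        history.append(stats)
        logger.info(
            "iteration %d: %d contigs, %d bases, N50 %d, %d pairs recruited",
            j, stats.n_contigs, stats.total_bases, stats.n50, stats.pairs_recruited,
        )
        if out is not None:
            iter_dir = out / f"iter_{j}"
            iter_dir.mkdir(exist_ok=True)
            write_fasta(contigs, iter_dir / "contigs.fasta")
            (iter_dir / "stats.tsv").write_text(
                IterationStats.TSV_HEADER + "\n" + stats.as_tsv_row() + "\n"
            )
            manifest["iterations"].append(
                {"iteration": j, "sha1": _sha1(contigs), **asdict(stats)}
            )
        if stats.n_contigs == 0:
            logger.warning("iteration %d produced no contigs; stopping", j)
            break
        if len(history) >= 2:
            prev = history[-2]
            if (
                _rel_change(stats.n_contigs, prev.n_contigs) < params.plateau_tolerance
                and _rel_change(stats.total_bases, prev.total_bases) < params.plateau_tolerance
            ):
                logger.info("plateau reached at iteration %d", j)
                break
        reference = contigs
        long_input = contigs
    if out is not None:
        write_fasta(contigs, out / "genespace.fasta")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "stats.tsv").write_text(
            IterationStats.TSV_HEADER + "\n"
            + "\n".join(s.as_tsv_row() for s in history) + "\n"
        )
    return contigs, history


def plateau_reached(history: Sequence[IterationStats], tolerance: float = 0.01) -> bool:
    """True when the last two iterations differ by less than the tolerance in
    both contig count and total bases."""
    if len(history) < 2:
        return False
    a, b = history[-2], history[-1]
    return (
        _rel_change(b.n_contigs, a.n_contigs) < tolerance
        and _rel_change(b.total_bases, a.total_bases) < tolerance
    )
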