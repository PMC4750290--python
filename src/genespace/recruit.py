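"""Read-pair recruitment against a growing reference (the "filtration" step).

Pairs are mapped to the current reference with an exact-seed, gapless-extension
mapper at high identity (default 95 %): every pair with at least one mapped
mate is extracted for assembly.  Insert-distance parameters only classify
proper pairs for statistics — they never exclude a pair from recruitment,
because a broken pair (one mate in an exon, the other in an intron not yet
in the reference) is precisely the signal that drives gene-space growth.

Seed placement uses non-overlapping seeds when the pigeonhole bound
guarantees that every alignment within the identity threshold retains at
least one exact seed; reads too short for that guarantee fall back to an
exhaustive gapless scan.  The mapper is therefore exactly equivalent to
exhaustive gapless alignment of each read at every reference offset and
strand.
"""

from __future__ import annotations

import logging

import numpy as np
from dataclasses import dataclass, field
from typing import Iterable

from .seqio import ContigSet, ReadPair, SequenceRecord, reverse_complement

__all__ = [
    "RecruitParams",
    "ReferenceIndex",
    "MappingHit",
    "MappingStats",
    "RecruitResult",
    "build_index",
    "map_record",
    "recruit_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecruitParams:
    min_identity: float = 0.95
    seed_length: int = 15
    insert_min: int = 100
    insert_max: int = 400
    max_hits_reported: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if self.insert_min >= self.insert_max:
            raise ValueError("insert_min must be < insert_max")


@dataclass
class MappingHit:
    read_id: str
    contig_id: str
    start: int  # 0-based half-open, contig forward strand
    end: int
    strand: str  # '+' or '-'
    identity: float


@dataclass
class MappingStats:
    reads_total: int = 0
    reads_mapped: int = 0
    multi_hit_reads: int = 0
    pairs_total: int = 0
    pairs_recruited: int = 0
    pairs_both_mapped_proper: int = 0
    pairs_broken: int = 0

    @property
    def pct_mapped(self) -> float:
        return 100.0 * self.reads_mapped / self.reads_total if self.reads_total else 0.0

    @property
    def pct_multi_hit(self) -> float:
        return 100.0 * self.multi_hit_reads / self.reads_total if self.reads_total else 0.0

    def as_tsv(self) -> str:
        head = (
            "reads_total\treads_mapped\tpct_mapped\tpct_multi_hit\t"
            "pairs_total\tpairs_recruited\tpairs_both_mapped_proper\tpairs_broken\n"
        )
        return head + (
            f"{self.reads_total}\t{self.reads_mapped}\t{self.pct_mapped:.2f}\t"
            f"{self.pct_multi_hit:.2f}\t{self.pairs_total}\t{self.pairs_recruited}\t"
            f"{self.pairs_both_mapped_proper}\t{self.pairs_broken}\n"
        )


@dataclass
class RecruitResult:
    recruited: list[ReadPair] = field(default_factory=list)
    stats: MappingStats = field(default_factory=MappingStats)


class ReferenceIndex:
    """Exact seed index over the reference.

    Postings are stored for the forward strand; reverse-strand hits are found
    by probing the reverse-complemented read, which covers both strands
    completely while keeping placement arithmetic on forward coordinates.
    """

    def __init__(self, reference: ContigSet, params: RecruitParams) -> None:
        if len(reference) == 0:
            raise ValueError("cannot index an empty reference")
        self.seed_length = params.seed_length
        self.sequences: dict[str, str] = {}
        self.lengths: dict[str, int] = {}
        self.postings: dict[str, list[tuple[str, int]]] = {}
        s = self.seed_length
        for contig in reference:
            if len(contig) < s:
                logger.warning(
                    "contig %s (%d nt) shorter than seed length %d; skipped",
                    contig.id, len(contig), s,
                )
                continue
            seq = contig.sequence
            self.sequences[contig.id] = seq
            self.lengths[contig.id] = len(seq)
            post = self.postings
            for off in range(len(seq) - s + 1):
                seed = seq[off : off + s]
                if "N" in seed:
                    continue
                post.setdefault(seed, []).append((contig.id, off))


def build_index(reference: ContigSet, params: RecruitParams = RecruitParams()) -> ReferenceIndex:
    return ReferenceIndex(reference, params)


def _seed_positions(n: int, s: int) -> range:
    """Non-overlapping seed probes (plus a clamped final window).

    Only used when floor(n/s) exceeds the mismatch budget, in which case any
    qualifying placement leaves at least one of the disjoint seeds exact.
    """
    last = n - s
    return range(0, last + 1, s) if last % s == 0 else range(0, last + s, s)


def _probe(
    query: str,
    strand: str,
    index: ReferenceIndex,
    max_mm: int,
    candidates_seen: set[tuple[str, int, str]],
    hits: list[MappingHit],
    read_id: str,
) -> None:
    n = len(query)
    s = index.seed_length
    positions = _seed_positions(n, s)
    for qpos in positions:
        if qpos > n - s:
            qpos = n - s
        seed = query[qpos : qpos + s]
        for cid, off in index.postings.get(seed, ()):
            start = off - qpos
            key = (cid, start, strand)
            if key in candidates_seen:
                continue
            candidates_seen.add(key)
            if start < 0 or start + n > index.lengths[cid]:
                continue
            ref = index.sequences[cid]
            mm = 0
            for a, b in zip(query, ref[start : start + n]):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                hits.append(
                    MappingHit(read_id, cid, start, start + n, strand, (n - mm) / n)
                )


def _scan_all_offsets(
    query: str, strand: str, index: ReferenceIndex, max_mm: int,
    hits: list[MappingHit], read_id: str,
) -> None:
    """Exhaustive gapless scan; completeness fallback for reads too short for
    the disjoint-seed guarantee (a lone mismatch can break every seed)."""
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    n = len(qa)
    for cid in index.sequences:
        seq = index.sequences[cid]
        if len(seq) < n:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, n)
        mismatches = (windows != qa).sum(axis=1)
        for start in np.nonzero(mismatches <= max_mm)[0]:
            start = int(start)
            mm = int(mismatches[start])
            hits.append(MappingHit(read_id, cid, start, start + n, strand, (n - mm) / n))


def map_record(
    read: SequenceRecord, index: ReferenceIndex, params: RecruitParams = RecruitParams()
) -> list[MappingHit]:
    """All qualifying gapless full-length placements of a read, best first."""
    n = len(read)
    if n < index.seed_length or "N" in read.sequence:
        return []
    max_mm = int((1.0 - params.min_identity) * n + 1e-9)
    hits: list[MappingHit] = []
    if n // index.seed_length > max_mm:
        seen: set[tuple[str, int, str]] = set()
        _probe(read.sequence, "+", index, max_mm, seen, hits, read.id)
        _probe(reverse_complement(read.sequence), "-", index, max_mm, seen, hits, read.id)
    else:
        _scan_all_offsets(read.sequence, "+", index, max_mm, hits, read.id)
        _scan_all_offsets(reverse_complement(read.sequence), "-", index, max_mm, hits, read.id)
        deduped: dict[tuple[str, int, str], MappingHit] = {}
        for h in hits:
            deduped.setdefault((h.contig_id, h.start, h.strand), h)
        hits = list(deduped.values())
    hits.sort(key=lambda h: (-h.identity, h.contig_id, h.start, h.strand))
    return hits[: params.max_hits_reported]


def _any_proper(h1: list[MappingHit], h2: list[MappingHit], params: RecruitParams) -> bool:
    for a in h1:
        for b in h2:
            if a.contig_id != b.contig_id or a.strand == b.strand:
                continue
            outer = max(a.end, b.end) - min(a.start, b.start)
            if params.insert_min <= outer <= params.insert_max:
                return True
    return False


def recruit_pairs(
    pairs: Iterable[ReadPair],
    index: ReferenceIndex,
    params: RecruitParams = RecruitParams(),
) -> RecruitResult:
    """Extract every pair with at least one mapped mate, with mapping stats."""
    result = RecruitResult()
    stats = result.stats
    for pair in pairs:
        stats.pairs_total += 1
        stats.reads_total += 2
        h1 = map_record(pair.r1, index, params)
        h2 = map_record(pair.r2, index, params)
        m1, m2 = bool(h1), bool(h2)
        stats.reads_mapped += m1 + m2
        stats.multi_hit_reads += (len(h1) > 1) + (len(h2) > 1)
        if m1 and m2:
            if _any_proper(h1, h2, params):
                stats.pairs_both_mapped_proper += 1
        elif m1 or m2:
            stats.pairs_broken += 1
        if m1 or m2:
            stats.pairs_recruited += 1
            result.recruited.append(pair)
    return result
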