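"""Multi-k De Bruijn graph assembly with trusted long-read feedback.

The assembler runs a De Bruijn graph over a ladder of k-mer sizes
(k = kmin, kmin+step, ..., kmax).  At each k the graph is built from the
short reads plus "trusted" sequence — long reads on the first rung, and the
contigs of the previous rung afterwards.  Trusted k-mers are exempt from the
coverage and tip filters, so assembly established at a smaller k (or in an
earlier pipeline iteration) is never eroded by a later rung; this is the
mechanism that lets small k provide sensitivity and large k resolve repeats.

Graph representation: nodes are canonical k-mers (the lexicographic minimum
of a k-mer and its reverse complement) with multiplicities; edges are the
implicit (k-1)-overlaps.  Contigs are maximal unambiguous paths, emitted in
canonical orientation.  Simplification removes low-multiplicity untrusted
k-mers (sequencing errors), short dead-end tips, and simple bubbles
(equal-length parallel paths, resolved to the higher-multiplicity side).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import ContigSet, SequenceRecord, reverse_complement

__all__ = [
    "AssemblyParams",
    "DeBruijnGraph",
    "build_graph",
    "simplify_graph",
    "extract_contigs",
    "assemble",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP_PAIRS = tuple(zip("ACGT", "TGCA"))


@dataclass(frozen=True)
class AssemblyParams:
    kmin: int = 20
    kmax: int = 100
    step: int = 5
    min_contig: int = 200
    min_kmer_count: int = 2
    tip_length_factor: int = 2

    def __post_init__(self) -> None:
        if self.kmin < 11:
            raise ValueError("kmin must be >= 11")
        if self.kmin > self.kmax:
            raise ValueError("kmin must be <= kmax")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def k_values(self) -> list[int]:
        return list(range(self.kmin, self.kmax + 1, self.step))


class DeBruijnGraph:
    """Canonical k-mer multiset with a trusted subset; edges are implicit."""

    def __init__(self, k: int) -> None:
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.counts: dict[str, int] = {}
        self.trusted: set[str] = set()

    def __len__(self) -> int:
        return len(self.counts)

    def _add_sequence(self, seq: str, trusted: bool) -> None:
        k = self.k
        n = len(seq)
        if n < k:
            return
        rc = reverse_complement(seq)
        counts = self.counts
        for i in range(n - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            km_rc = rc[n - k - i : n - i]
            canon = km if km <= km_rc else km_rc
            counts[canon] = counts.get(canon, 0) + 1
            if trusted:
                self.trusted.add(canon)

    # --- implicit adjacency -------------------------------------------------

    def _succ(self, node: str) -> list[str]:
        """Oriented successors of an oriented k-mer present in the graph."""
        counts = self.counts
        core = node[1:]
        rc_core = reverse_complement(core)
        out = []
        for b, cb in _COMP_PAIRS:
            nxt = core + b
            rc = cb + rc_core  # reverse_complement(core + b)
            if (nxt if nxt <= rc else rc) in counts:
                out.append(nxt)
        return out

    def _pred(self, node: str) -> list[str]:
        counts = self.counts
        core = node[:-1]
        rc_core = reverse_complement(core)
        out = []
        for b, cb in _COMP_PAIRS:
            prv = b + core
            rc = rc_core + cb  # reverse_complement(b + core)
            if (prv if prv <= rc else rc) in counts:
                out.append(prv)
        return out


def build_graph(
    short_reads: Iterable[SequenceRecord],
    long_reads: Iterable[SequenceRecord],
    k: int,
) -> DeBruijnGraph:
    """Insert short-read k-mers with counts; long-read k-mers are trusted too."""
    g = DeBruijnGraph(k)
    skipped = 0
    for rec in short_reads:
        if len(rec) < k:
            skipped += 1
            continue
        g._add_sequence(rec.sequence, trusted=False)
    for rec in long_reads:
        if len(rec) < k:
            skipped += 1
            continue
        g._add_sequence(rec.sequence, trusted=True)
    if skipped:
        logger.warning("build_graph(k=%d): %d reads shorter than k skipped", k, skipped)
    return g


def _canon(seq: str) -> str:
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def _walk_unitig(g: DeBruijnGraph, start: str) -> tuple[list[str], bool, bool]:
    """Maximal unambiguous oriented path through `start`.

    Returns (oriented k-mer path, left_dead, right_dead) where the dead flags
    mark ends with no continuation at all (degree zero on that side).
    """
    in_path = {_canon(start)}
    path = [start]
    # forward
    cur = start
    while True:
        ss = g._succ(cur)
        if len(ss) != 1:
            right_dead = len(ss) == 0
            break
        nxt = ss[0]
        if len(g._pred(nxt)) != 1 or _canon(nxt) in in_path:
            right_dead = False
            break
        path.append(nxt)
        in_path.add(_canon(nxt))
        cur = nxt
    # backward
    cur = start
    back: list[str] = []
    while True:
        pp = g._pred(cur)
        if len(pp) != 1:
            left_dead = len(pp) == 0
            break
        prv = pp[0]
        if len(g._succ(prv)) != 1 or _canon(prv) in in_path:
            left_dead = False
            break
        back.append(prv)
        in_path.add(_canon(prv))
        cur = prv
    back.reverse()
    return back + path, left_dead, right_dead


def _unitigs(g: DeBruijnGraph) -> list[tuple[list[str], bool, bool]]:
    """All unitigs, each reported once (deterministic insertion order)."""
    visited: set[str] = set()
    out = []
    for canon in g.counts:  # dict preserves deterministic insertion order
        if canon in visited:
            continue
        path, ld, rd = _walk_unitig(g, canon)
        for node in path:
            visited.add(_canon(node))
        out.append((path, ld, rd))
    return out


def _remove_path(g: DeBruijnGraph, path: Sequence[str]) -> None:
    for node in path:
        canon = _canon(node)
        g.counts.pop(canon, None)
        g.trusted.discard(canon)


def simplify_graph(g: DeBruijnGraph, params: AssemblyParams = AssemblyParams()) -> DeBruijnGraph:
    """Error-filter, tip-clip and bubble-pop the graph in place."""
    # (a) low-multiplicity untrusted k-mers
    if params.min_kmer_count > 1:
        doomed = [
            km for km, c in g.counts.items()
            if c < params.min_kmer_count and km not in g.trusted
        ]
        for km in doomed:
            del g.counts[km]

    # (b) tips: short dead-end unitigs attached to the rest of the graph
    max_tip = params.tip_length_factor * g.k
    for _round in range(5):
        clipped = 0
        for path, left_dead, right_dead in _unitigs(g):
            if left_dead == right_dead:  # interior unitig or isolated island
                continue
            seq_len = g.k + len(path) - 1
            if seq_len >= max_tip:
                continue
            if any(_canon(n) in g.trusted for n in path):
                continue
            _remove_path(g, path)
            clipped += 1
        if clipped == 0:
            break

    # (c) simple bubbles: two equal-length parallel unambiguous paths between
    # the same branch nodes; keep the higher-multiplicity side
    _pop_bubbles(g)
    return g


def _bubble_arm(g: DeBruijnGraph, first: str, limit: int) -> tuple[list[str], str] | None:
    """Unambiguous path starting at `first`; returns (arm, join node after it)."""
    arm = [first]
    cur = first
    for _ in range(limit):
        ss = g._succ(cur)
        if len(ss) != 1:
            return None
        nxt = ss[0]
        if len(g._pred(nxt)) != 1:
            return arm, nxt
        arm.append(nxt)
        cur = nxt
    return None


def _pop_bubbles(g: DeBruijnGraph) -> None:
    limit = 3 * g.k + 16
    branch_nodes: list[str] = []
    for canon in list(g.counts):
        for node in (canon, reverse_complement(canon)):
            if len(g._succ(node)) >= 2:
                branch_nodes.append(node)
            if node == reverse_complement(node):
                break  # palindromic k-mer: one orientation only
    for node in branch_nodes:
        succs = g._succ(node)
        if len(succs) < 2:
            continue  # graph changed since collection
        arms = []
        for s in succs:
            walked = _bubble_arm(g, s, limit)
            if walked is not None:
                arms.append(walked)
        # compare arms pairwise; pop the weaker of any equal-length pair
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                arm_i, join_i = arms[i]
                arm_j, join_j = arms[j]
                if join_i != join_j or len(arm_i) != len(arm_j) or arm_i == arm_j:
                    continue
                mult_i = sum(g.counts.get(_canon(n), 0) for n in arm_i)
                mult_j = sum(g.counts.get(_canon(n), 0) for n in arm_j)
                seq_i = arm_i[0] + "".join(n[-1] for n in arm_i[1:])
                seq_j = arm_j[0] + "".join(n[-1] for n in arm_j[1:])
                if (mult_i, seq_j) > (mult_j, seq_i):  # ties keep lexicographically smaller
                    loser = arm_j
                else:
                    loser = arm_i
                if all(g.counts.get(_canon(n)) is not None for n in loser):
                    _remove_path(g, loser)


def extract_contigs(g: DeBruijnGraph, label: str = "assembly") -> ContigSet:
    """Maximal unambiguous paths as canonically oriented, deduplicated contigs."""
    seqs: set[str] = set()
    for path, _ld, _rd in _unitigs(g):
        seq = path[0] + "".join(node[-1] for node in path[1:])
        seqs.add(_canon(seq))
    ordered = sorted(seqs, key=lambda s: (-len(s), s))
    contigs = [
        SequenceRecord(f"{label}_c{i}", s) for i, s in enumerate(ordered, start=1)
    ]
    return ContigSet(label=label, contigs=contigs)


def assemble(
    short_reads: Sequence[SequenceRecord],
    long_reads: Sequence[SequenceRecord],
    params: AssemblyParams = AssemblyParams(),
    label: str = "assembly",
) -> ContigSet:
    """Iterative-k assembly: contigs from each rung feed the next as trusted input.

    Only after the final rung are contigs shorter than ``min_contig`` dropped.
    """
    max_len = max((len(r) for r in short_reads), default=0)
    max_len = max(max_len, max((len(r) for r in long_reads), default=0))
    if max_len < params.kmin:
        logger.warning("all input reads shorter than kmin=%d; empty assembly", params.kmin)
        return ContigSet(label=label)

    carry: list[SequenceRecord] = list(long_reads)
    contigs = ContigSet(label=label)
    for k in params.k_values:
        if k > max_len and all(len(c) < k for c in carry):
            break  # no sequence can contribute k-mers at this or larger k
        g = build_graph(short_reads, carry, k)
        simplify_graph(g, params)
        contigs = extract_contigs(g, label=label)
        carry = list(long_reads) + list(contigs)
    kept = [c for c in contigs if len(c) >= params.min_contig]
    return ContigSet(label=label, contigs=kept)
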