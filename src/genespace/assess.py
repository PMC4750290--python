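"""Assembly assessment: contig statistics, N50, and reconstruction rate.

The reconstruction analysis mirrors a standalone nucleotide BLAST of the
transcript (Unigene) set against the de novo assembly: seed-detected local
alignments with affine gaps are scored, assigned an expectation value from
the ungapped Karlin–Altschul formula E = K*m*n*exp(-lambda*S), and filtered
at a stringent cutoff (default 1e-60).  Each transcript is then categorised
by how much of its length is covered by qualifying alignments to its single
best-matching contig: complete (>= 95 %), half-to-complete (>= 50 %),
less-than-half (> 0) or not found.

Alignment scores come from a full Gotoh local dynamic program run over a
window around each cluster of exact seed matches, so multiple alignments per
transcript/contig pair (one per exon block, when introns interrupt the
match) are recovered as separate segment pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .seqio import ContigSet, SequenceRecord, reverse_complement

__all__ = [
    "AlignScoring",
    "Hsp",
    "ReconstructionRecord",
    "ReconstructionSummary",
    "compute_n50",
    "contig_stats",
    "local_align",
    "reconstruction_report",
]


# --- contig statistics ------------------------------------------------------


def compute_n50(contigs: ContigSet | Sequence[SequenceRecord]) -> int:
    """Smallest contig length such that contigs at least that long hold >= 50 %
    of the total assembled bases."""
    lengths = sorted((len(c) for c in contigs), reverse=True)
    if not lengths:
        raise ValueError("N50 of an empty contig set is undefined")
    half = sum(lengths) / 2
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


@dataclass
class ContigStats:
    n: int
    total: int
    mean: float
    min: int
    max: int
    n50: int

    def as_tsv(self) -> str:
        return (
            "n\ttotal\tmean\tmin\tmax\tn50\n"
            f"{self.n}\t{self.total}\t{self.mean:.1f}\t{self.min}\t{self.max}\t{self.n50}\n"
        )


def contig_stats(contigs: ContigSet | Sequence[SequenceRecord]) -> ContigStats:
    lengths = [len(c) for c in contigs]
    if not lengths:
        return ContigStats(0, 0, 0.0, 0, 0, 0)
    total = sum(lengths)
    return ContigStats(
        n=len(lengths),
        total=total,
        mean=round(total / len(lengths), 1),
        min=min(lengths),
        max=max(lengths),
        n50=compute_n50(contigs),
    )


# --- local alignment --------------------------------------------------------


@dataclass(frozen=True)
class AlignScoring:
    """Megablast-like scoring; a gap of length g costs open + g * extend."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    seed_length: int = 11

    def karlin_lambda(self) -> float:
        """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for uniform base frequencies."""
        p_match, p_mis = 0.25, 0.75

        def f(lam: float) -> float:
            return p_match * math.exp(lam * self.match) + p_mis * math.exp(
                lam * self.mismatch
            ) - 1.0

        lo, hi = 1e-6, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    # K for the ungapped regime is expensive to compute exactly; a fixed
    # conservative constant suffices for an e-value used purely as a filter.
    karlin_k: float = 0.1


@dataclass
class Hsp:
    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    matches: int
    length: int
    score: int
    evalue: float


_ENCODE = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=False)
def _gotoh_local(q, s, match, mismatch, open_cost, ext_cost):  # pragma: no cover
    """Gotoh local DP with pointer matrices for traceback.

    Returns (best score, best i, best j, ptrH, ptrE, ptrF) where ptrH codes
    0=stop, 1=diagonal, 2=from E (gap in query), 3=from F (gap in subject).
    """
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int32)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.uint8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0=open from H, 1=extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - open_cost - ext_cost
            e_ext = E[i, j - 1] - ext_cost
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - open_cost - ext_cost
            f_ext = F[i - 1, j] - ext_cost
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            sub = match if (qi == s[j - 1] and qi != 4) else mismatch
            diag = H[i - 1, j - 1] + sub
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    return best, bi, bj, ptrH, ptrE, ptrF


def _traceback(q, s, bi, bj, ptrH, ptrE, ptrF):
    """Walk pointers back from (bi, bj); returns (qs, qe, ss, se, matches, length)."""
    i, j = bi, bj
    matches = 0
    length = 0
    state = "H"
    while True:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if q[i - 1] == s[j - 1] and q[i - 1] != 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            length += 1
            if ptrE[i, j] == 0:
                state = "H"
            j -= 1
        else:
            length += 1
            if ptrF[i, j] == 0:
                state = "H"
            i -= 1
    return i, bi, j, bj, matches, length


def _seed_clusters(
    query: str, subject: str, seed_length: int, band: int = 64
) -> list[tuple[int, int]]:
    """Cluster exact seed matches by diagonal; returns subject-window spans."""
    seeds: dict[str, list[int]] = {}
    for i in range(len(query) - seed_length + 1):
        seeds.setdefault(query[i : i + seed_length], []).append(i)
    matches: list[tuple[int, int]] = []  # (diagonal, subject pos)
    for j in range(len(subject) - seed_length + 1):
        kmer = subject[j : j + seed_length]
        if kmer in seeds:
            for qi in seeds[kmer]:
                matches.append((j - qi, j))
    if not matches:
        return []
    matches.sort()
    clusters: list[tuple[int, int]] = []
    cur_diag, cur_lo, cur_hi = matches[0][0], matches[0][1], matches[0][1]
    for diag, j in matches[1:]:
        if diag - cur_diag <= band:
            cur_diag = diag
            cur_lo = min(cur_lo, j)
            cur_hi = max(cur_hi, j)
        else:
            clusters.append((cur_lo, cur_hi))
            cur_diag, cur_lo, cur_hi = diag, j, j
    clusters.append((cur_lo, cur_hi))
    return clusters


def _align_oriented(
    query: SequenceRecord,
    oriented: str,
    strand: str,
    subject: SequenceRecord,
    scoring: AlignScoring,
    lam: float,
    search_space: float,
    max_evalue: float,
) -> list[Hsp]:
    clusters = _seed_clusters(oriented, subject.sequence, scoring.seed_length)
    if not clusters:
        return []
    hsps: list[Hsp] = []
    qlen = len(oriented)
    pad = qlen + 100
    w_lo = max(0, min(lo for lo, _ in clusters) - pad)
    w_hi = min(len(subject), max(hi for _, hi in clusters) + scoring.seed_length + pad)
    q_arr = _encode(oriented)
    s_arr = _encode(subject.sequence[w_lo:w_hi])
    # iterative masking: the first pass yields the optimal local alignment in
    # the window; masking its query span then exposes the next segment (e.g.
    # the next exon block when an intron interrupts the match)
    for _round in range(32):
        score, bi, bj, ptrH, ptrE, ptrF = _gotoh_local(
            q_arr, s_arr, scoring.match, scoring.mismatch,
            scoring.gap_open, scoring.gap_extend,
        )
        if score <= 0:
            break
        evalue = scoring.karlin_k * search_space * math.exp(-lam * score)
        if evalue > max_evalue:
            break
        qs, qe, ss, se, matches, length = _traceback(q_arr, s_arr, bi, bj, ptrH, ptrE, ptrF)
        q_arr = q_arr.copy()
        q_arr[qs:qe] = 4  # mask so later rounds find the remaining segments
        ss, se = ss + w_lo, se + w_lo
        if strand == "-":
            qs, qe = qlen - qe, qlen - qs
        hsps.append(
            Hsp(query.id, subject.id, qs, qe, ss, se, strand, matches, length, int(score), evalue)
        )
    return hsps


def local_align(
    query: SequenceRecord,
    subjects: ContigSet | Sequence[SequenceRecord],
    max_evalue: float = 1e-60,
    scoring: AlignScoring = AlignScoring(),
    search_space: float | None = None,
) -> list[Hsp]:
    """Seed-detected local alignments of a query against a set of subjects.

    Both strands are searched.  ``search_space`` overrides the m*n product in
    the e-value formula (used when aligning within a larger database context).
    """
    subject_list = list(subjects)
    if search_space is None:
        search_space = float(len(query)) * float(sum(len(s) for s in subject_list))
    lam = scoring.karlin_lambda()
    hsps: list[Hsp] = []
    rc_query = reverse_complement(query.sequence)
    for subject in subject_list:
        hsps.extend(
            _align_oriented(query, query.sequence, "+", subject, scoring, lam,
                            search_space, max_evalue)
        )
        hsps.extend(
            _align_oriented(query, rc_query, "-", subject, scoring, lam,
                            search_space, max_evalue)
        )
    # deduplicate identical placements arising from adjacent seed clusters
    seen: set[tuple] = set()
    unique = []
    for h in hsps:
        key = (h.subject_id, h.query_start, h.query_end, h.subject_start, h.subject_end, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    unique.sort(key=lambda h: (-h.score, h.subject_id, h.query_start, h.subject_start))
    return unique


# --- reconstruction rate ----------------------------------------------------


@dataclass
class ReconstructionRecord:
    unigene_id: str
    found: bool
    coverage: float
    category: str  # complete | half_to_complete | less_than_half | not_found
    best_contig: str | None = None


@dataclass
class ReconstructionSummary:
    n_unigene: int = 0
    n_found: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def pct_found(self) -> float:
        return 100.0 * self.n_found / self.n_unigene if self.n_unigene else 0.0

    def pct(self, category: str) -> float:
        return 100.0 * self.counts.get(category, 0) / self.n_unigene if self.n_unigene else 0.0


CATEGORIES = ("complete", "half_to_complete", "less_than_half", "not_found")


def _covered_fraction(intervals: list[tuple[int, int]], length: int) -> float:
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return covered / length


def reconstruction_report(
    unigene: ContigSet,
    denovo: ContigSet,
    max_evalue: float = 1e-60,
    complete_threshold: float = 0.95,
    half_threshold: float = 0.5,
    scoring: AlignScoring = AlignScoring(),
) -> tuple[list[ReconstructionRecord], ReconstructionSummary]:
    """Categorise each transcript by coverage on its best-matching contig.

    Coverage is the fraction of transcript positions inside the union of
    qualifying alignment intervals against the single contig with the highest
    total alignment score — one reconstructed gene region, not a paralog union.
    """
    if len(unigene) == 0 or len(denovo) == 0:
        raise ValueError("reconstruction_report requires non-empty contig sets")
    search_space = float(sum(len(u) for u in unigene)) * float(sum(len(d) for d in denovo))
    records: list[ReconstructionRecord] = []
    summary = ReconstructionSummary(n_unigene=len(unigene), counts={c: 0 for c in CATEGORIES})
    for uni in unigene:
        hsps = local_align(uni, denovo, max_evalue, scoring, search_space=search_space)
        if not hsps:
            records.append(ReconstructionRecord(uni.id, False, 0.0, "not_found"))
            summary.counts["not_found"] += 1
            continue
        totals: dict[str, int] = {}
        for h in hsps:
            totals[h.subject_id] = totals.get(h.subject_id, 0) + h.score
        best = max(sorted(totals), key=lambda cid: totals[cid])
        ivals = [(h.query_start, h.query_end) for h in hsps if h.subject_id == best]
        cov = _covered_fraction(ivals, len(uni))
        if cov >= complete_threshold:
            cat = "complete"
        elif cov >= half_threshold:
            cat = "half_to_complete"
        else:
            cat = "less_than_half"
        records.append(ReconstructionRecord(uni.id, True, cov, cat, best))
        summary.counts[cat] += 1
        summary.n_found += 1
    return records, summary


def report_tsv(records: list[ReconstructionRecord], summary: ReconstructionSummary) -> str:
    lines = ["unigene_id\tfound\tcoverage\tcategory\tbest_contig"]
    for r in records:
        lines.append(
            f"{r.unigene_id}\t{int(r.found)}\t{r.coverage:.4f}\t{r.category}\t{r.best_contig or '-'}"
        )
    lines.append(
        f"# n={summary.n_unigene} found={summary.n_found} ({summary.pct_found:.1f}%) "
        + " ".join(f"{c}={summary.counts.get(c, 0)}" for c in CATEGORIES)
    )
    return "\n".join(lines) + "\n"
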