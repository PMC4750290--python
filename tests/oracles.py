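"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle is a direct, unoptimised transcription of a definition, kept
deliberately separate from the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np

from genespace.seqio import reverse_complement


def oracle_longest_run(seq: str, qual: list[int], min_phred: int) -> tuple[int, int]:
    """Longest clean substring by scanning every start position."""
    ok = np.array([q >= min_phred and b != "N" for b, q in zip(seq, qual)])
    fail_at = np.flatnonzero(~ok)
    best = (0, 0)
    for start in range(len(seq)):
        if not ok[start]:
            continue
        nxt = fail_at[fail_at >= start]
        end = int(nxt[0]) if nxt.size else len(seq)
        if end - start > best[1] - best[0]:
            best = (start, end)
    return best


def oracle_read_maps(read: str, contigs, min_identity: float) -> bool:
    """Exhaustive gapless alignment of the read at every offset and strand."""
    n = len(read)
    if "N" in read:
        return False
    for _cid, seq in contigs:
        if len(seq) < n:
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for q in (read, reverse_complement(read)):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, n)
            mismatches = (windows != qa).sum(axis=1)
            if (mismatches <= int((1 - min_identity) * n + 1e-9)).any():
                return True
    return False


def brute_force_n50(lengths) -> int:
    """The contig size for which all larger-or-equal contigs cover half the
    assembly, found by trying every candidate length."""
    total = sum(lengths)
    for candidate in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= candidate) >= total / 2:
            return candidate
    raise AssertionError


def sw_score_oracle(q: str, s: str, match=1, mismatch=-2, open_=5, ext=2) -> int:
    """Affine-gap Smith-Waterman score, row-wise numpy formulation.

    Horizontal gaps use a prefix-max scan: with gap cost open + g*ext the
    best source for column j is max over j' < j of H[j'] + ext*j'.
    """
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    m = len(sa)
    NEG = -(10**9)
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG, dtype=np.int64)
    jj = np.arange(1, m + 1, dtype=np.int64)
    best = 0
    for i in range(1, len(qa) + 1):
        sub = np.where(sa == qa[i - 1], match, mismatch).astype(np.int64)
        F = np.maximum(F - ext, H - open_ - ext)
        cand = np.maximum(np.maximum(H[:-1] + sub, F[1:]), 0)
        G = np.maximum.accumulate(cand + ext * jj)
        E = np.empty(m, dtype=np.int64)
        E[0] = NEG
        E[1:] = G[:-1] - open_ - ext * jj[1:]
        Hn = np.empty(m + 1, dtype=np.int64)
        Hn[0] = 0
        Hn[1:] = np.maximum(cand, E)
        best = max(best, int(Hn.max()))
        H = Hn
    return best


def mutated_copy(rng, s: str, sub_rate=0.03, indel_rate=0.01) -> str:
    """A diverged copy of s with substitutions and short indels."""
    out = []
    for ch in s:
        if rng.random() < indel_rate / 2:
            continue
        out.append("ACGT"[int(rng.integers(4))] if rng.random() < sub_rate else ch)
        if rng.random() < indel_rate / 2:
            out.append("ACGT"[int(rng.integers(4))])
    return "".join(out)
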