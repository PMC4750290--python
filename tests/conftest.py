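"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from genespace.seqio import ContigSet, ReadPair, SequenceRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def mutate_subs(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct random positions."""
    arr = list(seq)
    for pos in rng.choice(len(arr), size=n_subs, replace=False):
        old = arr[pos]
        choices = [b for b in "ACGT" if b != old]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)


def tiling_reads(
    src: str, read_len: int = 100, step: int = 10, rng: np.random.Generator | None = None
) -> list[SequenceRecord]:
    """Error-free reads tiling src end to end (random strand when rng given)."""
    starts = list(range(0, len(src) - read_len + 1, step))
    if starts[-1] != len(src) - read_len:
        starts.append(len(src) - read_len)
    reads = []
    for i, s in enumerate(starts):
        seq = src[s : s + read_len]
        if rng is not None and rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(SequenceRecord(f"t{i}", seq))
    return reads


def paired_reads(
    rng: np.random.Generator,
    src: str,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
) -> list[ReadPair]:
    """Error-free paired-end fragments drawn uniformly from src."""
    pairs = []
    for i in range(n_pairs):
        frag = int(round(rng.normal(insert_mean, insert_sd)))
        frag = max(read_len, min(frag, len(src)))
        s = int(rng.integers(0, len(src) - frag + 1))
        r1 = src[s : s + read_len]
        r2 = reverse_complement(src[s + frag - read_len : s + frag])
        pairs.append(
            ReadPair(
                f"p{i}",
                SequenceRecord(f"p{i}/1", r1, [40] * read_len),
                SequenceRecord(f"p{i}/2", r2, [40] * read_len),
            )
        )
    return pairs


def contig_set(*seqs: str, label: str = "ref") -> ContigSet:
    return ContigSet(
        label=label,
        contigs=[SequenceRecord(f"{label}{i}", s) for i, s in enumerate(seqs, 1)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260918)
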