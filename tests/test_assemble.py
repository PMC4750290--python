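"""De Bruijn graph construction, simplification, contig extraction, multi-k loop."""

import pytest

from genespace.assemble import (
    AssemblyParams,
    DeBruijnGraph,
    assemble,
    build_graph,
    extract_contigs,
    simplify_graph,
)
from genespace.seqio import SequenceRecord, reverse_complement

from conftest import paired_reads, random_seq, tiling_reads


def canon(s: str) -> str:
    r = reverse_complement(s)
    return s if s <= r else r


class TestBuildGraph:
    def test_kmer_enumeration(self):
        seq = "ACGTACGTACGTACG"  # 15 nt, k=12 -> 4 canonical k-mers
        g = build_graph([SequenceRecord("r", seq)], [], k=12)
        expected = {canon(seq[i : i + 12]) for i in range(4)}
        assert set(g.counts) == expected

    def test_trusted_union_semantics(self):
        rec = SequenceRecord("r", "ACGTACGTACGTACG")
        g = build_graph([rec], [SequenceRecord("l", rec.sequence)], k=12)
        km = canon(rec.sequence[:12])
        assert g.counts[km] == 2
        assert km in g.trusted

    def test_empty_inputs(self):
        assert len(build_graph([], [], k=21)) == 0

    def test_k_floor(self):
        with pytest.raises(ValueError):
            DeBruijnGraph(10)

    def test_n_kmers_skipped(self):
        g = build_graph([SequenceRecord("r", "ACGTNACGTACGTAC")], [], k=12)
        assert len(g) == 0 or all("N" not in km for km in g.counts)


class TestSimplify:
    def test_low_multiplicity_untrusted_removed(self, rng):
        src = random_seq(rng, 200)
        reads = [SequenceRecord(f"r{i}", src) for i in range(3)]
        err = SequenceRecord("e", random_seq(rng, 40))
        g = build_graph(reads + [err], [], k=21)
        simplify_graph(g, AssemblyParams(kmin=21, kmax=21, min_kmer_count=2))
        assert all(g.counts[km] >= 2 for km in g.counts)

    def test_tip_clipped_unless_trusted(self, rng):
        src = random_seq(rng, 300)
        # side branch: diverges from src at position 150 with 20 novel bases
        branch = src[120:150] + random_seq(rng, 20)
        reads = [SequenceRecord(f"r{i}", src) for i in range(3)]
        tip = [SequenceRecord("tip", branch)]

        g = build_graph(reads + tip + tip, [], k=21)  # tip count 2, passes (a)
        simplify_graph(g, AssemblyParams(kmin=21, kmax=21))
        tip_kmer = canon(branch[-21:])
        assert tip_kmer not in g.counts  # clipped as a short dead end

        g2 = build_graph(reads + tip, tip, k=21)  # same branch but trusted
        simplify_graph(g2, AssemblyParams(kmin=21, kmax=21))
        assert canon(branch[-21:]) in g2.counts

    def test_bubble_keeps_higher_multiplicity_path(self, rng):
        left = random_seq(rng, 40)
        right = random_seq(rng, 40)
        mid_hi = random_seq(rng, 15)
        mid_lo = mutate_middle(mid_hi)
        hi = left + mid_hi + right
        lo = left + mid_lo + right
        reads = [SequenceRecord(f"h{i}", hi) for i in range(5)] + [
            SequenceRecord(f"l{i}", lo) for i in range(2)
        ]
        g = build_graph(reads, [], k=21)
        simplify_graph(g, AssemblyParams(kmin=21, kmax=21))
        contigs = extract_contigs(g)
        seqs = [c.sequence for c in contigs]
        assert canon(hi) in seqs
        assert canon(lo) not in seqs


def mutate_middle(s: str) -> str:
    mid = len(s) // 2
    repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[mid]]
    return s[:mid] + repl + s[mid + 1 :]


class TestExtractContigs:
    def test_single_clean_contig(self, rng):
        src = random_seq(rng, 300)
        g = build_graph(tiling_reads(src, read_len=60, step=5), [], k=21)
        simplify_graph(g, AssemblyParams(min_kmer_count=1))
        contigs = extract_contigs(g)
        assert len(contigs) == 1
        assert contigs.contigs[0].sequence == canon(src)

    def test_repeat_splits_contigs(self, rng):
        # internal exact repeat longer than k collapses the graph
        rep = random_seq(rng, 40)
        src = random_seq(rng, 150) + rep + random_seq(rng, 150) + rep + random_seq(rng, 150)
        g = build_graph(tiling_reads(src, read_len=60, step=1), [], k=21)
        simplify_graph(g, AssemblyParams(min_kmer_count=1))
        assert len(extract_contigs(g)) >= 2

    def test_empty_graph(self):
        assert len(extract_contigs(DeBruijnGraph(21))) == 0


class TestAssemble:
    def test_defaults_match_published_run_configuration(self):
        p = AssemblyParams()
        assert (p.kmin, p.kmax, p.step, p.min_contig) == (20, 100, 5, 200)

    def test_single_k_degenerate(self, rng):
        src = random_seq(rng, 400)
        contigs = assemble(
            tiling_reads(src, step=5), [],
            AssemblyParams(kmin=21, kmax=21, min_contig=200, min_kmer_count=1),
        )
        assert [c.sequence for c in contigs] == [canon(src)]

    def test_paired_reads_reconstruct_source(self, rng):
        # error-free 2x100 pairs at ~30x over 300 nt: near-complete contig
        src = random_seq(rng, 300)
        pairs = paired_reads(rng, src, n_pairs=45, insert_mean=250, insert_sd=20)
        reads = [r for p in pairs for r in (p.r1, p.r2)]
        contigs = assemble(reads, [], AssemblyParams(kmin=21, kmax=41, step=10))
        assert len(contigs) == 1
        out = contigs.contigs[0].sequence
        assert len(out) >= 280
        assert out in src or reverse_complement(out) in src

    def test_trust_preservation(self, rng):
        """A previous-iteration contig fed as long-read input survives."""
        src = random_seq(rng, 500)
        prev = SequenceRecord("prev", src[50:350])
        # short reads only cover an overlapping, shifted window
        reads = tiling_reads(src[200:500], step=5)
        contigs = assemble(
            reads, [prev], AssemblyParams(kmin=21, kmax=41, step=10, min_kmer_count=1)
        )
        joined = [c.sequence for c in contigs]
        assert any(
            prev.sequence in s or reverse_complement(prev.sequence) in s for s in joined
        )

    def test_all_reads_below_kmin(self):
        contigs = assemble([SequenceRecord("r", "ACGTACGTAC")], [], AssemblyParams(kmin=21, kmax=21))
        assert len(contigs) == 0

    def test_min_contig_filter_applies_only_to_output(self, rng):
        src = random_seq(rng, 150)
        contigs = assemble(
            tiling_reads(src, read_len=60, step=5), [],
            AssemblyParams(kmin=21, kmax=21, min_contig=200, min_kmer_count=1),
        )
        assert len(contigs) == 0  # 150 nt contig exists internally but is dropped

    def test_byte_identical_determinism(self, rng):
        src = random_seq(rng, 2000)
        pairs = paired_reads(rng, src, n_pairs=300)
        reads = [r for p in pairs for r in (p.r1, p.r2)]
        params = AssemblyParams(kmin=21, kmax=41, step=10)
        a = assemble(reads, [], params)
        b = assemble(reads, [], params)
        assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]

    def test_outputs_clean_of_n_and_short_contigs(self, rng):
        src = random_seq(rng, 1500)
        pairs = paired_reads(rng, src, n_pairs=250)
        reads = [r for p in pairs for r in (p.r1, p.r2)]
        contigs = assemble(reads, [], AssemblyParams(kmin=21, kmax=41, step=10))
        for c in contigs:
            assert len(c) >= 200
            assert "N" not in c.sequence
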