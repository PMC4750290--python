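"""Read mapping and pair recruitment: exhaustive-alignment equivalence."""

import pytest

from genespace.recruit import (
    MappingStats,
    RecruitParams,
    build_index,
    map_record,
    recruit_pairs,
)
from genespace.seqio import ContigSet, ReadPair, SequenceRecord, reverse_complement

from conftest import contig_set, mutate_subs, random_seq
from oracles import oracle_read_maps


class TestBuildIndex:
    def test_posting_enumeration(self):
        ref = contig_set("ACGTACGTACGTACGT")  # 16 nt, seed 15 -> offsets 0 and 1
        idx = build_index(ref, RecruitParams())
        offs = sorted(off for posts in idx.postings.values() for _cid, off in posts)
        assert offs == [0, 1]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_index(ContigSet(label="empty"), RecruitParams())

    def test_short_contig_skipped(self):
        ref = contig_set("ACGTACGTACGTACGT", "ACGT")
        idx = build_index(ref, RecruitParams())
        assert "ref2" not in idx.sequences


class TestMapRecord:
    def test_exact_match(self, rng):
        ref_seq = random_seq(rng, 500)
        idx = build_index(contig_set(ref_seq), RecruitParams())
        read = SequenceRecord("r", ref_seq[100:200])
        hits = map_record(read, idx)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (100, 200, "+")
        assert hits[0].identity == 1.0

    def test_identity_threshold_boundary(self, rng):
        # 5 substitutions in a 100 nt read: identity 0.95 qualifies; 6 do not
        ref_seq = random_seq(rng, 400)
        idx = build_index(contig_set(ref_seq), RecruitParams())
        sub5 = mutate_subs(rng, ref_seq[50:150], 5)
        sub6 = mutate_subs(rng, ref_seq[50:150], 6)
        assert map_record(SequenceRecord("r5", sub5), idx)
        assert not map_record(SequenceRecord("r6", sub6), idx)

    def test_reverse_strand(self, rng):
        ref_seq = random_seq(rng, 300)
        idx = build_index(contig_set(ref_seq), RecruitParams())
        hits = map_record(SequenceRecord("r", reverse_complement(ref_seq[40:140])), idx)
        assert hits and hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (40, 140)

    def test_read_with_n_unmapped(self, rng):
        ref_seq = random_seq(rng, 300)
        idx = build_index(contig_set(ref_seq), RecruitParams())
        read = SequenceRecord("r", "N" + ref_seq[50:149])
        assert map_record(read, idx) == []

    def test_short_read_unmapped(self, rng):
        idx = build_index(contig_set(random_seq(rng, 300)), RecruitParams())
        assert map_record(SequenceRecord("r", "ACGTACGTAC"), idx) == []


class TestRecruitPairs:
    def _pairs_and_ref(self, rng, n_pairs=20):
        contigs = [(f"c{i}", random_seq(rng, int(rng.integers(150, 1200)))) for i in range(3)]
        refset = ContigSet(
            label="ref", contigs=[SequenceRecord(cid, s) for cid, s in contigs]
        )
        pairs = []
        for i in range(n_pairs):
            def mk(mate):
                if rng.random() < 0.4:  # planted read with some substitutions
                    cid, seq = contigs[int(rng.integers(len(contigs)))]
                    ln = int(rng.integers(30, min(120, len(seq)) + 1))
                    s = int(rng.integers(0, len(seq) - ln + 1))
                    r = mutate_subs(rng, seq[s : s + ln], int(rng.integers(0, max(1, ln // 12))))
                    return reverse_complement(r) if rng.random() < 0.5 else r
                return random_seq(rng, int(rng.integers(30, 121)))
            pairs.append(
                ReadPair(f"p{i}", SequenceRecord(f"p{i}/1", mk(1)), SequenceRecord(f"p{i}/2", mk(2)))
            )
        return pairs, refset, contigs

    def test_matches_exhaustive_oracle(self, rng):
        """Recruited pair set equals exhaustive-alignment ground truth."""
        params = RecruitParams()
        for _ in range(30):
            pairs, refset, contigs = self._pairs_and_ref(rng)
            idx = build_index(refset, params)
            got = {p.pair_id for p in recruit_pairs(pairs, idx, params).recruited}
            expected = set()
            for p in pairs:
                def maps(r):
                    return len(r.sequence) >= params.seed_length and oracle_read_maps(
                        r.sequence, contigs, params.min_identity
                    )
                if maps(p.r1) or maps(p.r2):
                    expected.add(p.pair_id)
            assert got == expected

    def test_broken_pair_recruited_and_counted(self, rng):
        ref_seq = random_seq(rng, 500)
        idx = build_index(contig_set(ref_seq), RecruitParams())
        pair = ReadPair(
            "p",
            SequenceRecord("p/1", ref_seq[100:200]),  # maps
            SequenceRecord("p/2", random_seq(rng, 100)),  # does not
        )
        res = recruit_pairs([pair], idx)
        assert [p.pair_id for p in res.recruited] == ["p"]
        assert res.stats.pairs_broken == 1
        assert res.stats.pairs_both_mapped_proper == 0

    def test_proper_pair_classification(self, rng):
        ref_seq = random_seq(rng, 1000)
        idx = build_index(contig_set(ref_seq), RecruitParams(insert_min=100, insert_max=400))
        # outer distance 300: r1 at [100,200), r2 = rc of [300,400)
        pair = ReadPair(
            "p",
            SequenceRecord("p/1", ref_seq[100:200]),
            SequenceRecord("p/2", reverse_complement(ref_seq[300:400])),
        )
        res = recruit_pairs([pair], idx)
        assert res.stats.pairs_both_mapped_proper == 1
        assert res.stats.pairs_broken == 0

    def test_monotone_in_reference(self, rng):
        """Adding contigs to the reference never shrinks the recruited set."""
        params = RecruitParams()
        pairs, small_ref, _ = self._pairs_and_ref(rng, n_pairs=30)
        bigger = ContigSet(
            label="big",
            contigs=list(small_ref) + [SequenceRecord("extra", random_seq(rng, 800))],
        )
        got_small = {p.pair_id for p in recruit_pairs(pairs, build_index(small_ref, params), params).recruited}
        got_big = {p.pair_id for p in recruit_pairs(pairs, build_index(bigger, params), params).recruited}
        assert got_small <= got_big

    def test_deterministic(self, rng):
        params = RecruitParams()
        pairs, refset, _ = self._pairs_and_ref(rng)
        idx = build_index(refset, params)
        r1 = recruit_pairs(pairs, idx, params)
        r2 = recruit_pairs(pairs, idx, params)
        assert [p.pair_id for p in r1.recruited] == [p.pair_id for p in r2.recruited]
        assert r1.stats == r2.stats

    def test_mapped_fraction_tracks_contained_coding_fraction(self):
        """Against a transcript-only reference, the mapped-read percentage
        approximates the genome fraction where a read fits inside an exon."""
        from genespace.simulate import SimParams, derive_unigene, simulate_genome, simulate_pairs

        p = SimParams(
            genome_length=40_000, n_genes=8, exon_length_mean=400.0, exon_length_sd=50.0,
            repeat_fraction=0.5, depth=20, substitution_error_rate=0.0,
            bad_read_fraction=0.0, tail_fraction=0.0, rng_seed=5,
        )
        truth = simulate_genome(p)
        pairs = list(simulate_pairs(truth))
        idx = build_index(derive_unigene(truth), RecruitParams())
        stats = recruit_pairs(pairs, idx).stats
        # genome positions where a full read fits within one exon
        contained = sum(
            max(0, (e - s) - p.read_length + 1)
            for g in truth.genes for s, e in g.exons
        )
        expected_pct = 100.0 * contained / p.genome_length
        assert expected_pct / 3 <= stats.pct_mapped <= expected_pct * 3


def test_mapping_stats_percentages():
    s = MappingStats(reads_total=200, reads_mapped=20, multi_hit_reads=5)
    assert s.pct_mapped == 10.0
    assert s.pct_multi_hit == 2.5
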