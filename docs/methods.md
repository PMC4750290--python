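# Methods

## The problem and the model

Large plant genomes are dominated by repeated sequence (transposon families
at various ages and divergences); the genes — exons, introns, promoters and
UTRs, collectively the *gene space* — are a small minority.  When a
non-redundant spliced transcript set (a Unigene) exists for the genotype,
the gene space can be reconstructed from ordinary paired-end whole-genome
reads without assembling the whole genome, by iterating two steps:

* **Recruitment.**  Map every read pair against the current reference and
  extract each pair with at least one mapped mate.  Because mates are
  physically linked ends of one fragment, the unmapped mate of a broken
  pair lies within roughly one insert length of the reference — i.e. in an
  intron or flank not yet assembled.  Insert-distance bounds are used only
  to classify "proper" pairs in the statistics; they never gate extraction.
* **Assembly.**  Assemble the recruited reads de novo and use the output
  contigs (all contigs at or above a minimum length) as both the next
  mapping reference and trusted assembly input, so each pass can only add
  sequence.

Termination is by plateau: the run stops when the relative changes of both
contig count and total assembled bases fall below `plateau_tolerance`
(default 1 %, both quantities must settle) or at `max_iterations`
(default 6).  The 1 % figure is this package's choice — plateau behaviour
is described qualitatively in the literature this method follows, never
quantified — and is exposed as a parameter.

## Mapper (recruit module)

Exact-seed (default 15-mer), gapless full-read extension, identity =
matching bases / read length, threshold 0.95.  Seeds are probed at
non-overlapping positions: if a read of length n tolerates m =
floor(0.05·n) mismatches and floor(n/15) > m, the pigeonhole principle
guarantees a qualifying placement leaves at least one probe seed exact, so
the mapper is *exactly* equivalent to exhaustive gapless alignment at every
offset and strand.  Reads too short for the guarantee (n such that
floor(n/15) ≤ m; with default trimming these are shorter than any read the
pipeline produces) fall back to a vectorised exhaustive scan rather than
silently losing sensitivity.  Reads containing N return no hits.  Gapped
(banded) extension is a documented extension point, deliberately off: at
95 % identity on same-genotype data, substitutions dominate and the gapless
model keeps the oracle equivalence testable.

A hit must fit entirely within a reference contig.  This containment rule
has a consequence worth stating: against an exon-only reference, a read
maps only if it sits wholly inside one exon, so the iteration-1 mapping
percentage reflects the *contained* exonic fraction (positions where a full
read fits in an exon), not the raw coding fraction.  With exons near the
read length the two differ severalfold.

## Assembler (assemble module)

Canonical k-mer De Bruijn graph (node = lexicographic minimum of k-mer and
reverse complement; edges are implicit (k−1)-overlaps), iterated over
k = kmin…kmax in steps (defaults 20→100 step 5, minimum contig 200 nt —
the published run configuration of the protocol this package re-implements).
Per k: (a) untrusted k-mers with multiplicity < `min_kmer_count` (default
2) are removed — this is purely an error filter, and callers assembling
error-free data should set it to 1; (b) dead-end unitigs shorter than
`tip_length_factor`·k are clipped unless they contain a trusted k-mer;
(c) simple bubbles (equal-length parallel unambiguous paths between the
same branch nodes) collapse to the higher-multiplicity side, ties to the
lexicographically smaller sequence.  Contigs are maximal unambiguous paths,
emitted in canonical orientation, sorted by (length desc, sequence asc) —
output is byte-deterministic.

Long reads and previous contigs are incorporated as *trusted* k-mers
(exempt from filters (a) and (b)) rather than threaded or aligned: this is
the simplest mechanism that preserves established assembly across both the
k-ladder and protocol iterations, and it makes trust preservation directly
testable (any trusted input reappears as a substring of some output contig
on error-free data).  Palindromic even-k k-mers are legal nodes; the
canonical representation plus the multi-k ladder make them harmless in
practice.  Exact canonical deduplication replaces the reference tool's
"similarity 1 nt" contig merging, whose unit is not interpretable as a
fraction; this is a deliberate substitution.

Sub-minimum contigs are dropped only at the final k; within the ladder all
contigs feed forward.

## Aligner and e-values (assess module)

The reconstruction analysis needs a BLASTN-like search.  Implementation:
exact 11-mer seed detection clusters by diagonal; a full affine-gap Gotoh
local DP (numba-compiled, with pointer traceback) runs over a window
spanning the seed clusters; the best local alignment is reported, its query
span masked, and the DP repeated, so a transcript interrupted by introns in
the subject yields one alignment per exon block.  The first reported score
is the exact Smith–Waterman optimum of the window (verified against an
independent row-scan formulation in the tests).  Scoring defaults are
megablast-like: match +1, mismatch −2, gap of length g costs 5 + 2g.

E = K·m·n·exp(−λS) with λ solved numerically for the scoring scheme under
uniform base composition (λ ≈ 1.34 for +1/−2) and K fixed at 0.1.  Exact K
computation is out of scope; at the default cutoff of 1e−60 the exponential
term dominates and K only shifts the required score by a few bases.  The
search space m·n is the product of total query-set and subject-set lengths,
mirroring database-style conventions.

Per-transcript coverage is measured against the *single* best-matching
contig (highest total alignment score), not a union over all contigs, so
paralogs cannot inflate "rebuilt" calls.  Categories: complete ≥ 0.95,
half-to-complete ≥ 0.5, less-than-half > 0, else not found.  The 0.95
(rather than 1.0) completeness cutoff allows for terminal k-mer-length
assembly artifacts; both thresholds are parameters because the source
protocol never defines them.

## Synthetic world (simulate module)

The generator emulates an inbred (single-haplotype) repeat-rich plant
genome: one truth contig; genes with exon lengths ~ Normal(130, 35) nt
truncated at 40 (legume-like); exon count per gene 1 + Poisson(3) (mean 4 —
multi-exon transcripts averaging ~520 nt, so that transcripts exceed the
insert size, the geometric premise of paired-end recruitment); intron
lengths from a mixture with 2/3 of mass uniform on [60, 150] nt and 1/3 on
[150, 1000] nt; 150 nt of unique flank either side of each gene
(promoter/UTR analogue, counted as part of the declared gene space);
repeat families (default 8, element length 1000 nt) as mutated copies at
1–5 % divergence from per-family consensi, filling toward an 80 % repeat
target *after* genes and flanks are placed; leftover space is unique
background.  At the default 100 kb / 30 gene scale the realised repeat
fraction is ~50–55 %: the 80 % target and 30 realistically sized genes are
mutually infeasible in 100 kb, and the gene model wins because every
quantitative claim the pipeline is tested on concerns gene recovery.

Reads: fragments uniform over the genome, lengths Normal(300, 30) truncated
at the read length, 2×100 nt from the fragment ends (strand randomised),
substitution errors at 0.1 %, base qualities 36–40 with a low-quality 3′
tail on 10 % of reads and 2 % wholly low-quality reads so trimming has
realistic work (retention lands near the mid-90s %).  Pair count =
depth·genome/(2·read length).  Everything is deterministic per seed.

What the generator does *not* model — and hence what a green test cannot
establish: heterozygosity, indel sequencing errors, GC/coverage bias,
nested or truncated transposons, repeats inside introns, multi-chromosome
structure.

## Quality trimming (qc module)

A base survives if Phred ≥ 30 and unambiguous; a read is reduced to its
single longest contiguous run of surviving bases (leftmost on ties) and
rejected below 30 nt.  Keeping one contiguous run — rather than deleting
interior low-quality bases — avoids fabricating chimeric junctions.  A pair
is kept only if both mates survive; singletons are not modelled because
downstream recruitment and insert logic assume intact pairs.

## Known limitations at desk scale

The package's end-to-end scenario (100 kb, 30 genes, 2×100 at 30×,
k 21→61, six iterations) reproduces the method's qualitative dynamics —
~4 % iteration-1 mapping, monotone growth of assembly and recruitment,
multi-hit appearance as tips reach repeats, more iterations for longer
introns — but three quantitative outcomes are bounded by scale effects
rather than by the method itself:

1. **Iteration-1 island loss.**  With exons near the read length and the
   200 nt output threshold, many single-exon islands (exon ± what mate
   clouds reach) are shorter than 200 nt at iteration 1.  Because the next
   reference is the iteration output alone, genes whose islands are dropped
   leave the reference permanently.  At the published scale this cannot
   happen — the reference transcripts (mean 1277 nt, minimum 203 nt) always
   seed contigs above threshold.
2. **No plateau by iteration 6.**  In 100 kb, repeats abut every gene
   flank, and at 1–5 % copy divergence roughly half of cross-copy reads
   still clear the 95 % identity bar, so contig tips keep creeping through
   repeat elements and total bases keep growing past iteration 6.  In a
   multi-Gb genome the gene space is ~1 % and this creep is negligible.
3. **Containment mapping vs. short exons.**  Reads spanning an exon
   boundary never map, so genes whose exons are all shorter than the read
   length recruit nothing and cannot be recovered at all.

These are documented as observed, not patched around: the corresponding
end-to-end assertions in `tests/test_acceptance.py` are left failing, with
the analysis above as the explanation.
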