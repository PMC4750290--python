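# genespace

Targeted reconstruction of the *gene space* — exons, introns, promoter/UTR
flanks — of a large, repeat-rich genome from cheap short-read data, when the
only reference available is a spliced transcript (Unigene) set.

Whole-genome de novo assembly of a genome that is mostly transposon is both
expensive and largely pointless if what you need are the genes (for marker
design, genotyping arrays, primer walking across introns).  `genespace`
instead alternates two steps, starting from the transcript set as the
reference:

1. **Recruitment (filtration).**  All read pairs are mapped against the
   current reference with a strict gapless mapper (default ≥ 95 % identity
   over the full read).  Every pair with *at least one* mapped mate is
   extracted — the unmapped mate of a "broken" pair is exactly the read
   sitting in an intron or flank that the reference does not yet contain.
2. **Assembly.**  The recruited reads are assembled with a multi-k De Bruijn
   graph (k = k<sub>min</sub>, k<sub>min</sub>+step, …, k<sub>max</sub>).
   Long reads — and, from the second iteration on, the previous iteration's
   contigs — enter the graph as *trusted* k-mers that are exempt from the
   coverage and tip filters, so established assembly is never eroded.

The output contigs become the next iteration's mapping reference and trusted
input.  Each pass extends exons roughly one insert length deeper into the
surrounding introns and flanks; the run stops when contig count and total
bases plateau (relative change below 1 %) or after `max_iterations`.

The package also ships an assessment module (N50/contig statistics, a
seed-triggered affine-gap local aligner with Karlin–Altschul e-values, and a
per-transcript reconstruction report) and a synthetic-data module that
generates repeat-rich genomes with known gene models, spliced transcripts
and paired-end reads, so the whole pipeline is testable without external
data.

## Worked example

```python
import genespace as gs

# a 100 kb synthetic genome: 30 multi-exon genes (exon mean 130 nt, two
# thirds of introns <= 150 nt), repeat families at 1-5 % divergence,
# 2x100 nt pairs at 30x with insert 300 +/- 30
params = gs.SimParams(rng_seed=1)
truth = gs.simulate_genome(params)
unigene = gs.derive_unigene(truth)
pairs, report = gs.trim_pair_list(list(gs.simulate_pairs(truth)))

protocol = gs.ProtocolParams(
    max_iterations=6,
    assembly=gs.AssemblyParams(kmin=21, kmax=61, step=10),
)
final, history = gs.run_protocol(unigene, pairs, None, protocol)
for h in history:
    print(h.as_tsv_row())
```

Output (iteration, contigs, total bases, mean/min/max length, N50, pairs
recruited, % reads mapped, % multi-hit):

```
1	20	7307	365.4	202	707	433	1109	4.07	0.00
2	19	12865	677.1	205	1791	979	1268	5.79	0.00
3	14	17476	1248.3	225	2676	1368	1997	11.37	0.00
4	33	25129	761.5	201	3065	1359	3513	19.31	0.52
5	70	39743	567.8	200	4349	1197	5146	27.77	1.88
6	103	54783	531.9	200	4575	570	7806	44.08	7.31
```

The signature dynamics of the method are all visible: only ~4 % of reads map
against the exon-only reference at iteration 1 (reads must fit entirely
inside an exon), total assembled bases grow every iteration as introns and
flanks are pulled in, recruitment grows with the reference, and multi-hit
reads appear once contig tips reach into repeat elements.  Scoring the final
assembly:

```python
cov = gs.truth_coverage(truth, final)        # vs known gene coordinates
recs, summary = gs.reconstruction_report(unigene, final)  # vs transcripts
```

reports 43 % of gene spans fully (≥ 95 %) covered and 67 % of transcripts
found at this desk scale — see `docs/methods.md` for why the scaled-down
world bounds these numbers (iteration-1 exon islands below the 200 nt
minimum-contig threshold are lost, and at this genome size repeats sit
immediately next to genes).

## Command line

```bash
genespace simulate --seed 1 --out-dir sim/        # genome, truth, unigene, reads
genespace trim --in1 r1.fq --in2 r2.fq --out1 t1.fq --out2 t2.fq
genespace recruit --ref unigene.fasta --in1 t1.fq --in2 t2.fq --out-prefix rec
genespace assemble --short1 rec_1.fastq --short2 rec_2.fastq --mink 20 --maxk 100 --step 5 --out contigs.fasta
genespace run --unigene unigene.fasta --in1 t1.fq --in2 t2.fq --max-iter 6 --out-dir run/
genespace assess --unigene unigene.fasta --assembly run/genespace.fasta --out report.tsv
genespace stats run/genespace.fasta
```

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch — it
simulates the default synthetic world from the given seed, trims, executes
the six-iteration protocol (k 21→61 step 10), and evaluates gene-span
coverage, transcript recovery and recruitment enrichment against the known
truth, logging per-iteration statistics to stderr:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
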