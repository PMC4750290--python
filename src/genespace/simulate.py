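"""Synthetic repeat-rich genomes with known gene structure, and read simulation.

The generator emulates the situation the pipeline was designed for: a large
inbred diploid-like plant genome dominated by repeated sequence, in which the
gene space (exons, introns and immediate promoter/UTR flanks) is a small
minority, and the only available reference is the spliced transcript set.

Default world:

* one 100 kb truth contig carrying 30 multi-exon genes;
* exon lengths ~ Normal(130, 35) nt truncated at 40 (legume-like exon sizes);
* intron lengths drawn from a mixture with two thirds of the mass uniform on
  [60, 150] nt and one third on [150, 1000] nt, so most introns are bridged
  by a single insert while a long tail exercises multi-iteration recovery;
* each gene flanked by 150 nt of unique sequence (promoter/UTR analogue),
  counted as part of the declared gene space;
* the remaining genome filled toward an 80 % target with mutated copies
  (1-5 % divergence) of per-family repeat consensus sequences, plus a little
  unique background;
* paired-end 2x100 nt reads at 30x, insert 300 +/- 30 nt, 0.1 % substitution
  errors, high-quality Phred profile with occasional low-quality 3' tails and
  a small fraction of wholly bad reads (so trimming has realistic work).

Everything is deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .seqio import ContigSet, ReadPair, SequenceRecord, reverse_complement

__all__ = [
    "SimParams",
    "GeneModel",
    "RepeatAnnotation",
    "GenomeTruth",
    "simulate_genome",
    "derive_unigene",
    "simulate_pairs",
    "truth_coverage",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimParams:
    genome_length: int = 100_000
    n_genes: int = 30
    exon_length_mean: float = 130.0
    exon_length_sd: float = 35.0
    exon_length_min: int = 40
    exons_per_gene_extra_mean: float = 3.0  # exons = 1 + Poisson(this)
    intron_short_range: tuple[int, int] = (60, 150)
    intron_long_range: tuple[int, int] = (150, 1000)
    intron_short_weight: float = 2.0 / 3.0
    gene_flank: int = 150
    repeat_fraction: float = 0.80
    repeat_family_count: int = 8
    repeat_element_length: int = 1000
    repeat_divergence_range: tuple[float, float] = (0.01, 0.05)
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 30.0
    substitution_error_rate: float = 0.001
    base_quality_range: tuple[int, int] = (36, 40)
    tail_fraction: float = 0.10
    tail_length_range: tuple[int, int] = (5, 15)
    tail_quality_range: tuple[int, int] = (2, 20)
    bad_read_fraction: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, ordered
    introns: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class RepeatAnnotation:
    family: str
    contig_id: str
    start: int
    end: int


@dataclass
class GenomeTruth:
    genome: ContigSet
    genes: list[GeneModel]
    repeats: list[RepeatAnnotation]
    params: SimParams

    @property
    def gene_space_fraction(self) -> float:
        """Declared gene-space share: spans plus unique flanks, over the genome."""
        flank = self.params.gene_flank
        genic = sum(g.span_length + 2 * flank for g in self.genes)
        return genic / self.genome.total_bases()

    @property
    def gene_span_fraction(self) -> float:
        return sum(g.span_length for g in self.genes) / self.genome.total_bases()

    @property
    def repeat_fraction_realised(self) -> float:
        return sum(r.end - r.start for r in self.repeats) / self.genome.total_bases()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _sample_gene(rng: np.random.Generator, p: SimParams) -> tuple[str, list[int], list[int]]:
    """Returns (sequence, exon lengths, intron lengths) in local coordinates."""
    n_exons = 1 + rng.poisson(p.exons_per_gene_extra_mean)
    exon_lens = [
        max(p.exon_length_min, int(round(rng.normal(p.exon_length_mean, p.exon_length_sd))))
        for _ in range(n_exons)
    ]
    intron_lens = []
    for _ in range(n_exons - 1):
        if rng.random() < p.intron_short_weight:
            lo, hi = p.intron_short_range
        else:
            lo, hi = p.intron_long_range
        intron_lens.append(int(rng.integers(lo, hi + 1)))
    total = sum(exon_lens) + sum(intron_lens)
    return _random_seq(rng, total), exon_lens, intron_lens


def simulate_genome(params: SimParams) -> GenomeTruth:
    """Build the truth genome: gene blocks, repeat copies, background."""
    rng = np.random.default_rng(params.rng_seed)
    flank = params.gene_flank

    gene_parts = []  # (seq, exon_lens, intron_lens, strand)
    for _ in range(params.n_genes):
        seq, ex, intr = _sample_gene(rng, params)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_parts.append((seq, ex, intr, strand))
    gene_block_total = sum(len(s) + 2 * flank for s, _, _, _ in gene_parts)
    if gene_block_total > params.genome_length:
        raise ValueError(
            f"infeasible packing: {params.n_genes} gene blocks need "
            f"{gene_block_total} nt but genome_length is {params.genome_length}"
        )

    repeat_budget = min(
        int(round(params.repeat_fraction * params.genome_length)),
        params.genome_length - gene_block_total,
    )
    consensi = [
        _random_seq(rng, params.repeat_element_length)
        for _ in range(params.repeat_family_count)
    ]
    repeat_parts = []  # (family index, seq)
    filled = 0
    while filled < repeat_budget:
        fam = int(rng.integers(params.repeat_family_count))
        lo, hi = params.repeat_divergence_range
        copy = _mutate(rng, consensi[fam], rng.uniform(lo, hi))
        if filled + len(copy) > repeat_budget:
            copy = copy[: repeat_budget - filled]
        if len(copy) < 30:
            break
        repeat_parts.append((fam, copy))
        filled += len(copy)

    background_total = params.genome_length - gene_block_total - filled
    bg_parts: list[str] = []
    while background_total > 0:
        n = min(background_total, int(rng.integers(200, 801)))
        bg_parts.append(_random_seq(rng, n))
        background_total -= n

    # interleave segments
    segments: list[tuple[str, object]] = (
        [("gene", gp) for gp in gene_parts]
        + [("repeat", rp) for rp in repeat_parts]
        + [("bg", b) for b in bg_parts]
    )
    order = rng.permutation(len(segments))

    chunks: list[str] = []
    genes: list[GeneModel] = []
    repeats: list[RepeatAnnotation] = []
    pos = 0
    gene_no = 0
    contig_id = "chr1"
    for idx in order:
        kind, payload = segments[idx]
        if kind == "gene":
            seq, exon_lens, intron_lens, strand = payload  # type: ignore[misc]
            gene_no += 1
            block = _random_seq(rng, flank) + seq + _random_seq(rng, flank)
            start = pos + flank
            exons, introns = [], []
            cur = start
            for i, el in enumerate(exon_lens):
                exons.append((cur, cur + el))
                cur += el
                if i < len(intron_lens):
                    introns.append((cur, cur + intron_lens[i]))
                    cur += intron_lens[i]
            genes.append(GeneModel(f"gene{gene_no:03d}", contig_id, strand, exons, introns))
            chunks.append(block)
            pos += len(block)
        elif kind == "repeat":
            fam, seq = payload  # type: ignore[misc]
            repeats.append(RepeatAnnotation(f"fam{fam:02d}", contig_id, pos, pos + len(seq)))
            chunks.append(seq)
            pos += len(seq)
        else:
            chunks.append(payload)  # type: ignore[arg-type]
            pos += len(payload)  # type: ignore[arg-type]

    genome_seq = "".join(chunks)
    genome = ContigSet(label="truth", contigs=[SequenceRecord(contig_id, genome_seq)])
    genes.sort(key=lambda g: g.span[0])
    return GenomeTruth(genome, genes, repeats, params)


def derive_unigene(truth: GenomeTruth) -> ContigSet:
    """Exactly spliced transcripts, one per gene (the synthetic Unigene set)."""
    seq_by_contig = {c.id: c.sequence for c in truth.genome}
    records = []
    for gene in truth.genes:
        genome = seq_by_contig[gene.contig_id]
        spliced = "".join(genome[s:e] for s, e in gene.exons)
        if gene.strand == "-":
            spliced = reverse_complement(spliced)
        records.append(SequenceRecord(gene.gene_id, spliced))
    return ContigSet(label="unigene", contigs=records)


def _qualities(rng: np.random.Generator, n: int, p: SimParams) -> list[int]:
    lo, hi = p.base_quality_range
    qual = rng.integers(lo, hi + 1, size=n)
    if rng.random() < p.bad_read_fraction:
        tlo, thi = p.tail_quality_range
        qual = rng.integers(tlo, thi + 1, size=n)
    elif rng.random() < p.tail_fraction:
        tlen = int(rng.integers(p.tail_length_range[0], p.tail_length_range[1] + 1))
        tlo, thi = p.tail_quality_range
        qual[n - tlen :] = rng.integers(tlo, thi + 1, size=tlen)
    return [int(q) for q in qual]


def _read_with_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return _mutate(rng, seq, rate)


def n_pairs_for(params: SimParams) -> int:
    return int(round(params.depth * params.genome_length / (2 * params.read_length)))


def simulate_pairs(truth: GenomeTruth, params: SimParams | None = None) -> Iterator[ReadPair]:
    """Uniform paired-end fragments with Normal insert sizes and Phred profiles."""
    p = params if params is not None else truth.params
    rng = np.random.default_rng(np.random.SeedSequence([p.rng_seed, 1]))
    genome = truth.genome.contigs[0].sequence
    glen = len(genome)
    rl = p.read_length
    n = n_pairs_for(p)
    for i in range(n):
        frag = int(round(rng.normal(p.insert_mean, p.insert_sd)))
        frag = max(rl, min(frag, glen))
        start = int(rng.integers(0, glen - frag + 1))
        fwd = genome[start : start + rl]
        rev = reverse_complement(genome[start + frag - rl : start + frag])
        if rng.random() < 0.5:  # fragments are sequenced from either strand
            fwd, rev = rev, fwd
        r1 = _read_with_errors(rng, fwd, p.substitution_error_rate)
        r2 = _read_with_errors(rng, rev, p.substitution_error_rate)
        pid = f"frag{i:07d}"
        yield ReadPair(
            pid,
            SequenceRecord(pid + "/1", r1, _qualities(rng, rl, p)),
            SequenceRecord(pid + "/2", r2, _qualities(rng, rl, p)),
        )


def truth_coverage(
    truth: GenomeTruth,
    assembly: ContigSet,
    max_evalue: float = 1e-30,
    complete_threshold: float = 0.95,
) -> dict:
    """Per-gene genomic span coverage by assembly contigs.

    Each gene's span sequence (first exon start to last exon end, forward
    strand) is used as the alignment query against the assembly; coverage is
    the unioned fraction of span positions inside qualifying local alignments.
    """
    from .assess import local_align, _covered_fraction

    seq_by_contig = {c.id: c.sequence for c in truth.genome}
    per_gene: dict[str, float] = {}
    for gene in truth.genes:
        s, e = gene.span
        span_seq = seq_by_contig[gene.contig_id][s:e]
        query = SequenceRecord(gene.gene_id, span_seq)
        if len(assembly) == 0:
            per_gene[gene.gene_id] = 0.0
            continue
        hsps = local_align(query, assembly, max_evalue=max_evalue)
        ivals = [(h.query_start, h.query_end) for h in hsps]
        per_gene[gene.gene_id] = _covered_fraction(ivals, len(query))
    n = len(per_gene)
    n_complete = sum(1 for v in per_gene.values() if v >= complete_threshold)
    return {
        "per_gene": per_gene,
        "n_genes": n,
        "fraction_complete": n_complete / n if n else 0.0,
        "mean_coverage": sum(per_gene.values()) / n if n else 0.0,
    }


# --- interchange ------------------------------------------------------------


def write_truth(truth: GenomeTruth, out_dir: str | Path) -> None:
    """Write genome.fasta, genes.gff3 (1-based closed), repeats.bed, manifest."""
    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genome, out / "genome.fasta")
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.genes:
            s, e = g.span
            fh.write(
                f"{g.contig_id}\tgenespace-sim\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig_id}\tgenespace-sim\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (is_, ie) in enumerate(g.introns, 1):
                fh.write(
                    f"{g.contig_id}\tgenespace-sim\tintron\t{is_ + 1}\t{ie}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.intron{i};Parent={g.gene_id}\n"
                )
    with open(out / "repeats.bed", "w") as fh:
        for r in truth.repeats:
            fh.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.family}\n")
    with open(out / "sim_params.json", "w") as fh:
        json.dump(asdict(truth.params), fh, indent=2, default=list)


def read_truth_annotations(out_dir: str | Path) -> tuple[list[GeneModel], list[RepeatAnnotation]]:
    """Round-trip loader for the GFF3/BED annotations written by write_truth."""
    out = Path(out_dir)
    genes: dict[str, dict] = {}
    with open(out / "genes.gff3") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, _src, kind, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            fields = dict(kv.split("=", 1) for kv in attrs.split(";"))
            iv = (int(start) - 1, int(end))
            if kind == "gene":
                genes[fields["ID"]] = {
                    "contig": contig, "strand": strand, "exons": [], "introns": [],
                }
            elif kind in ("exon", "intron"):
                genes[fields["Parent"]][kind + "s"].append(iv)
    gene_models = [
        GeneModel(gid, g["contig"], g["strand"], sorted(g["exons"]), sorted(g["introns"]))
        for gid, g in genes.items()
    ]
    gene_models.sort(key=lambda g: g.span[0])
    repeats = []
    with open(out / "repeats.bed") as fh:
        for line in fh:
            contig, start, end, family = line.split()
            repeats.append(RepeatAnnotation(family, contig, int(start), int(end)))
    return gene_models, repeats
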