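"""Synthetic genome, annotation, and full-length nascent-read simulator.

Generates the complete input anatomy the pipeline expects — a random
genome, disjoint gene models (optionally with downstream tRNA genes), and
pre-aligned SAM records whose soft clips carry the template-switch oligo,
an optional poly(A) tail, and the 3' ligation adapter — together with a
per-read truth table, so every stage is testable end to end with no
external aligner or download.

Read end geometry follows the four termination intermediates:

* ``POLYA`` ends at the gene's poly(A) site; a configurable fraction uses
  the dominant site exactly and the rest scatter with Gaussian jitter
  (poly(A)-site micro-heterogeneity).
* ``READTHROUGH`` 3' ends fall 50 nt plus a law-distributed excess past
  the pA; the law's median is exact by construction.
* ``CLEAVED_5P`` 3' ends sit within ±50 nt of the pA (truncated Gaussian).
* ``CLEAVED_3P`` 5' ends sit just past the pA, 3' ends follow the
  readthrough law.

Genes sit in "cassettes" that reserve a downstream clearance region, so
readthrough tails never run into the next gene body.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .annotation_io import GeneIndex, GeneModel
from .read_ingest import ADAPTER3_SEQ, TSO_SEQ, revcomp

__all__ = ["SimConfig", "SimGene", "simulate_genome", "simulate_reads",
           "simulate_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 100
    chrom: str = "chrSim"
    chrom_length: int | None = None  # None: sized to fit; explicit: packing checked
    minus_strand_fraction: float = 0.5
    gene_length_range: tuple[int, int] = (1200, 3000)
    intergenic_gap_range: tuple[int, int] = (500, 1500)
    downstream_clearance: int = 1500  # reserved run-on room past each pA
    pa_offset_from_tes: int = 0  # pA downstream of the annotated TES by this much
    # class proportions (POLYA, READTHROUGH, CLEAVED_5P, CLEAVED_3P)
    class_proportions: tuple[float, float, float, float] = (0.60, 0.25, 0.14, 0.01)
    readthrough_law: str = "exponential"  # exponential | gamma | constant
    readthrough_median: float = 160.0  # total distance past pA, 50-nt floor included
    rt_median_log_sd: float = 0.0  # per-gene median spread (lognormal, median-preserving)
    gamma_shape: float = 20.0
    read_seed: int | None = None  # draw reads independently of the genome layout
    jitter_sd: float = 10.0  # cleavage-end jitter (nt)
    polya_major_fraction: float = 0.6  # poly(A) ends using the dominant site exactly
    tail_length_range: tuple[int, int] = (20, 100)
    error_rate: float = 0.05  # uniform substitution rate
    reads_per_gene: int = 50
    trna_fraction: float = 0.0
    trna_convergent_fraction: float = 0.5
    trna_length: int = 72
    trna_twe_offset_tandem: int = 60  # tRNA start this far past the TWE
    trna_twe_offset_convergent: int = 10  # tRNA 3' end this far past the TWE
    trna_gene_readthrough_median: float = 80.0  # tRNA-adjacent genes terminate early

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.readthrough_median <= 50:
            raise ValueError("readthrough median must exceed the 50-nt floor")
        if self.readthrough_law not in ("exponential", "gamma", "constant"):
            raise ValueError(f"unknown readthrough law {self.readthrough_law!r}")


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str
    pa: int | None = None  # true poly(A) site (None for tRNAs)
    rt_median: float | None = None  # this gene's readthrough-law median
    true_twe: int | None = None

    def as_model(self) -> GeneModel:
        return GeneModel(self.gene_id, self.chrom, self.strand,
                         self.start, self.end, self.biotype)


def _sample_excess(rng: np.random.Generator, law: str, median: float,
                   gamma_shape: float, n: int) -> np.ndarray:
    """Distance past the 50-nt floor; the law's median is (median - 50) exactly."""
    m = median - 50.0
    if law == "constant":
        return np.full(n, m)
    if law == "exponential":
        return rng.exponential(m / np.log(2), n)
    scale = m / stats.gamma.ppf(0.5, a=gamma_shape)
    return rng.gamma(gamma_shape, scale, n)


def simulate_genome(config: SimConfig) -> tuple[str, list[SimGene]]:
    """Lay out disjoint genes (plus optional downstream tRNAs) on a random
    chromosome; deterministic for a fixed seed."""
    rng = np.random.default_rng([int(config.seed), 11])
    genes: list[SimGene] = []
    cursor = 500
    n_trna = int(round(config.n_genes * config.trna_fraction))
    trna_flags = np.zeros(config.n_genes, dtype=bool)
    if n_trna:
        trna_flags[rng.choice(config.n_genes, n_trna, replace=False)] = True
    for i in range(config.n_genes):
        length = int(rng.integers(*config.gene_length_range))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        has_trna = bool(trna_flags[i])
        if has_trna:
            rt_med = config.trna_gene_readthrough_median
        else:
            rt_med = config.readthrough_median
            if config.rt_median_log_sd > 0:
                rt_med = 50 + (rt_med - 50) * rng.lognormal(0.0, config.rt_median_log_sd)
        gid = f"gene{i:04d}"
        clearance = config.downstream_clearance
        if strand == "+":
            start = cursor
            end = start + length
            pa = end + config.pa_offset_from_tes
            twe = pa + int(round(rt_med))
            cursor = pa + clearance
        else:
            # downstream region (genomically left) comes first in the layout
            start = cursor + clearance
            end = start + length
            pa = start - config.pa_offset_from_tes
            twe = pa - int(round(rt_med))
            cursor = end
        genes.append(SimGene(gid, config.chrom, strand, start, end,
                             "protein_coding", pa, rt_med, twe))
        if has_trna:
            convergent = rng.random() < config.trna_convergent_fraction
            t_strand = ("-" if strand == "+" else "+") if convergent else strand
            if strand == "+":
                edge = twe + (config.trna_twe_offset_convergent if convergent
                              else config.trna_twe_offset_tandem)
                t_start, t_end = edge, edge + config.trna_length
            else:
                edge = twe - (config.trna_twe_offset_convergent if convergent
                              else config.trna_twe_offset_tandem)
                t_start, t_end = edge - config.trna_length, edge
            genes.append(SimGene(f"trna{i:04d}", config.chrom, t_strand,
                                 t_start, t_end, "tRNA"))
        cursor += int(rng.integers(*config.intergenic_gap_range))
    total = cursor + 500
    if config.chrom_length is not None:
        if total > config.chrom_length:
            raise ValueError(
                f"genes need {total} nt but chrom_length is {config.chrom_length}")
        total = config.chrom_length
    seq = "".join(rng.choice(_BASES, total))
    return seq, genes


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i].upper()]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def simulate_reads(
    config: SimConfig, genome: str, genes: list[SimGene]
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment], pd.DataFrame]:
    """Emit coordinate-sorted alignment records plus the per-read truth table."""
    read_seed = config.seed if config.read_seed is None else config.read_seed
    rng = np.random.default_rng([int(read_seed), 23])
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": len(genome)}],
    })
    classes = ("POLYA", "READTHROUGH", "CLEAVED_5P", "CLEAVED_3P")
    records: list[tuple[int, pysam.AlignedSegment]] = []
    truth_rows = []
    read_no = 0
    for gene in genes:
        if gene.biotype != "protein_coding":
            continue
        pa, strand = gene.pa, gene.strand
        body_span = (pa - gene.start) if strand == "+" else (gene.end - pa)
        draws = rng.choice(4, config.reads_per_gene, p=config.class_proportions)
        for k in draws:
            cls = classes[k]
            tail_len = 0
            if cls == "POLYA":
                d5 = -int(rng.integers(60, max(61, body_span - 20)))
                if rng.random() < config.polya_major_fraction or config.jitter_sd == 0:
                    d3 = 0
                else:
                    d3 = int(np.clip(round(rng.normal(0, config.jitter_sd)), -50, 50))
                tail_len = int(rng.integers(config.tail_length_range[0],
                                            config.tail_length_range[1] + 1))
            elif cls == "READTHROUGH":
                d5 = -int(rng.integers(60, max(61, body_span - 20)))
                excess = _sample_excess(rng, config.readthrough_law,
                                        gene.rt_median, config.gamma_shape, 1)[0]
                d3 = 50 + max(1, min(int(round(excess)), config.downstream_clearance - 100))
            elif cls == "CLEAVED_5P":
                d5 = -int(rng.integers(60, max(61, body_span - 20)))
                d3 = int(np.clip(round(rng.normal(0, config.jitter_sd)), -50, 50))
            else:  # CLEAVED_3P
                d5 = int(rng.integers(0, 31))
                excess = _sample_excess(rng, config.readthrough_law,
                                        gene.rt_median, config.gamma_shape, 1)[0]
                d3 = 50 + max(1, min(int(round(excess)), config.downstream_clearance - 100))
            if d3 <= d5:  # degenerate jitter draw; keep the read minimally long
                d3 = d5 + 20
            if strand == "+":
                five, three = pa + d5, pa + d3
                segment = genome[five:three]
            else:
                five, three = pa - d5, pa - d3
                segment = revcomp(genome[three:five])
            read_id = f"read{read_no:06d}"
            read_no += 1
            # read 5'->3': TSO, transcript, tail, adapter
            raw = TSO_SEQ + segment + "A" * tail_len + ADAPTER3_SEQ
            raw = _add_errors(rng, raw, config.error_rate)
            left_clip = len(TSO_SEQ)
            right_clip = tail_len + len(ADAPTER3_SEQ)
            if strand == "+":
                stored = raw
                cigar = [(4, left_clip), (0, three - five), (4, right_clip)]
                pos = five
            else:
                stored = revcomp(raw)
                cigar = [(4, right_clip), (0, five - three), (4, left_clip)]
                pos = three
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.query_sequence = stored
            a.flag = 16 if ((strand == "-") ^ (rng.random() < 0.5)) else 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            records.append((pos, a))
            truth_rows.append({
                "read_id": read_id, "gene_id": gene.gene_id, "true_class": cls,
                "true_d5": d5, "true_d3": d3, "true_tail_length": tail_len,
            })
    records.sort(key=lambda t: (t[0], t[1].query_name))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "gene_id", "true_class",
                                              "true_d5", "true_d3",
                                              "true_tail_length"])
    return header, [a for _, a in records], truth


def write_fasta(genome: str, chrom: str, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i:i + width] + "\n")


def write_gff3(genes: list[SimGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "tRNA" if g.biotype == "tRNA" else "gene"
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(f"{g.chrom}\tnanoterm_sim\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


def write_gene_truth(genes: list[SimGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\tbiotype\tpa\trt_median\ttrue_twe\n")
        for g in genes:
            pa = "" if g.pa is None else g.pa
            med = "" if g.rt_median is None else g.rt_median
            twe = "" if g.true_twe is None else g.true_twe
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t"
                     f"{g.biotype}\t{pa}\t{med}\t{twe}\n")


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full simulator and write FASTA, GFF3, SAM, and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(config)
    header, records, truth = simulate_reads(config, genome, genes)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "sam": outdir / "reads.sam",
        "read_truth": outdir / "read_truth.tsv",
        "gene_truth": outdir / "gene_truth.tsv",
    }
    write_fasta(genome, config.chrom, paths["fasta"])
    write_gff3(genes, paths["gff3"])
    write_gene_truth(genes, paths["gene_truth"])
    with pysam.AlignmentFile(str(paths["sam"]), "w", header=header) as fh:
        for a in records:
            fh.write(a)
    truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths


def gene_index(genes: list[SimGene]) -> GeneIndex:
    return GeneIndex(g.as_model() for g in genes)
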