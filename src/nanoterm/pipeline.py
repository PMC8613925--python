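"""End-to-end orchestration: ingest -> tails -> pA -> classify -> TW.

Thin glue over the stage modules; every stage's read counts are logged
and written to a JSON run manifest together with the thresholds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation_io import GeneIndex, read_annotation
from .classifier import classify_all, write_classified_tsv
from .comparative import detect_chimeras
from .pas_caller import (cluster_pacs, collect_polya_ends, select_single_pa_genes,
                         write_pa_bed, write_pac_tsv)
from .polya_tail import call_tail, write_tails_tsv
from .read_ingest import ingest_bam, write_reads_tsv
from .termination import tw_table
from .trna import pair_genes_with_trnas, twe_trna_distances

log = logging.getLogger("nanoterm")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All thresholds of the analysis; defaults are the published values."""

    bam: str = ""
    annotation: str = ""
    outdir: str = "nanoterm_out"
    seed: int = 0
    min_mapq: int = 0
    max_edits_tso: int = 6
    max_edits_adapter3: int = 4
    tail_threshold: int = 15  # poly(A) call: tail > 15 nt
    max_adapter_gap: int = 5  # trusted 3' end: adapter within 5 nt
    body_margin: int = 50  # gene-body / readthrough margin around pA
    cleaved3_window: int = 500  # 3' cleavage product 5'-end window
    tss_guard: int = 100  # close-tandem-neighbour TSS guard
    pac_gap: int = 24  # PAC single-linkage distance
    pac_min_support: int = 3
    pac_support_mode: str = "reads"
    min_tw_reads: int = 15
    include_cleaved3_in_tw: bool = True
    alpha: float = 0.001
    trna_max_gap: int = 200
    chimera_min_reads: int = 3


@dataclass
class PipelineResult:
    genes: GeneIndex
    reads: list
    tails: dict
    pa_table: dict
    clusters: list
    classified: list
    proportions: dict
    tw: pd.DataFrame
    counts: dict


def _threshold_header(cfg: RunConfig) -> str:
    pairs = ", ".join(f"{k}={v}" for k, v in asdict(cfg).items()
                      if k not in ("bam", "annotation", "outdir"))
    return f"# nanoterm {__version__}; thresholds: {pairs}\n"


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Run every stage in order and (optionally) write the output bundle."""
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
    if not Path(cfg.annotation).exists():
        raise FileNotFoundError(f"annotation not found: {cfg.annotation}")
    if not Path(cfg.bam).exists():
        raise FileNotFoundError(f"alignments not found: {cfg.bam}")

    genes = read_annotation(cfg.annotation)
    log.info("annotation: %d genes", len(genes))

    reads, counts = ingest_bam(cfg.bam, cfg.min_mapq, cfg.max_edits_tso,
                               cfg.max_edits_adapter3)
    log.info("ingest: %(input)d alignments, %(primary)d primary, "
             "%(double_adapter)d with both adapters", counts)

    tails = {r.read_id: call_tail(r.read_id, r.tail_segment) for r in reads}

    site_counts = collect_polya_ends(reads, tails, genes,
                                     tail_threshold=cfg.tail_threshold)
    clusters = cluster_pacs(site_counts, genes, cfg.pac_gap,
                            cfg.pac_min_support, cfg.pac_support_mode)
    pa_table = select_single_pa_genes(clusters)
    log.info("pA: %d PACs, %d single-PAC genes", len(clusters), len(pa_table))

    classified, proportions = classify_all(
        reads, tails, genes, pa_table,
        tail_threshold=cfg.tail_threshold, max_adapter_gap=cfg.max_adapter_gap,
        body_margin=cfg.body_margin, cleaved3_window=cfg.cleaved3_window,
        tss_guard=cfg.tss_guard,
    )
    n_cls = sum(1 for r in classified if r.read_class != "UNCLASSIFIED")
    assert len(classified) == len(reads), "read accounting broken"
    log.info("classify: %d/%d classified; proportions %s",
             n_cls, len(classified), proportions)
    counts["classified"] = n_cls
    counts["unclassified"] = len(classified) - n_cls

    tw = tw_table(classified, pa_table, genes, cfg.min_tw_reads,
                  cfg.include_cleaved3_in_tw, cfg.body_margin)
    log.info("termination windows: %d genes", len(tw))

    if write_outputs:
        write_reads_tsv(reads, outdir / "reads.tsv")
        write_tails_tsv(tails.values(), outdir / "tails.tsv")
        write_pac_tsv(clusters, outdir / "pacs.tsv")
        support = {c.gene_id: c.support for c in clusters}
        write_pa_bed(pa_table, genes, support, outdir / "pa_sites.bed")
        write_classified_tsv(classified, outdir / "classified.tsv")
        with open(outdir / "tw.tsv", "w") as fh:
            fh.write(_threshold_header(cfg))
            tw.to_csv(fh, sep="\t", index=False)
        pairings = pair_genes_with_trnas(genes, cfg.trna_max_gap)
        if pairings:
            dist_df, dropped = twe_trna_distances(pairings, tw, genes)
            with open(outdir / "trna_distances.tsv", "w") as fh:
                fh.write(_threshold_header(cfg))
                fh.write(f"# pairs without a termination window: {dropped}\n")
                dist_df.to_csv(fh, sep="\t", index=False)
        chimeras = detect_chimeras(classified, genes, pa_table,
                                   cfg.chimera_min_reads)
        with open(outdir / "chimeras.tsv", "w") as fh:
            fh.write(_threshold_header(cfg))
            fh.write("upstream_gene\tdownstream_gene\tn_spanning_cleaved\t"
                     "n_fed_polya\tn_spanning_full\n")
            for c in chimeras:
                fh.write(f"{c.upstream_gene}\t{c.downstream_gene}\t"
                         f"{c.n_spanning_cleaved_reads}\t{c.n_fed_polya_reads}\t"
                         f"{c.n_spanning_full}\n")
        manifest = {
            "version": __version__,
            "config": asdict(cfg),
            "counts": counts,
            "proportions": proportions,
            "n_tw_genes": int(len(tw)),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(genes, reads, tails, pa_table, clusters, classified,
                          proportions, tw, counts)
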