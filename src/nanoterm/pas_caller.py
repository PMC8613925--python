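"""Poly(A) site identification and clustering.

The aligned 3' end of every polyadenylated read (tail and adapter excluded)
is an observed poly(A) site.  Sites within the same gene are chained into
poly(A) site clusters (PACs) by single linkage with a 24-nt gap; clusters
supported by fewer than three reads are discarded; the most frequent site
in a cluster is its representative.  Termination analyses downstream are
restricted to genes with exactly one surviving PAC, which removes
alternative-polyadenylation ambiguity.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import GeneIndex, GeneModel
from .read_ingest import OrientedRead
from .polya_tail import TailCall

__all__ = [
    "PolyACluster",
    "collect_polya_ends",
    "cluster_pacs",
    "select_single_pa_genes",
    "write_pac_tsv",
    "write_pa_bed",
]

CLUSTER_GAP_NT = 24
MIN_SUPPORT = 3
TAIL_THRESHOLD_NT = 15
DOWNSTREAM_MARGIN_NT = 500


@dataclass(frozen=True)
class PolyACluster:
    gene_id: str
    sites: tuple[tuple[int, int], ...]  # (position, read count), sorted by position
    representative: int
    support: int

    @property
    def span(self) -> tuple[int, int]:
        return self.sites[0][0], self.sites[-1][0]


def assign_gene_for_end(
    read: OrientedRead, genes: GeneIndex, downstream_margin: int = DOWNSTREAM_MARGIN_NT
) -> GeneModel | None:
    """Same-strand gene whose TES-extended span covers the read.

    Used to bootstrap site collection before representative poly(A) sites
    exist: the gene span is TSS..TES extended ``downstream_margin`` nt past
    the TES.  Prefers the gene containing the read 5' end, else maximal
    overlap with the read.
    """
    lo = min(read.five_prime_pos, read.three_prime_pos)
    hi = max(read.five_prime_pos, read.three_prime_pos)
    best: tuple[int, str, GeneModel] | None = None
    for g in genes.overlapping(read.chrom, lo - downstream_margin, hi + downstream_margin,
                               strand=read.bio_strand):
        if g.strand == "+":
            g_lo, g_hi = g.start, g.end + downstream_margin
        else:
            g_lo, g_hi = g.start - downstream_margin, g.end
        if g_hi <= lo or hi <= g_lo:
            continue
        contains_5p = g.start <= read.five_prime_pos < g.end
        overlap = min(hi, g_hi) - max(lo, g_lo)
        key = (contains_5p, overlap, g.gene_id)
        if best is None or key > (best[0], best[1], best[2].gene_id):
            best = (contains_5p, overlap, g)
    return best[2] if best else None


def collect_polya_ends(
    reads: Iterable[OrientedRead],
    tails: Mapping[str, TailCall],
    genes: GeneIndex,
    tail_threshold: int = TAIL_THRESHOLD_NT,
    downstream_margin: int = DOWNSTREAM_MARGIN_NT,
) -> dict[str, Counter]:
    """Per-gene counter of poly(A)-read 3'-end positions.

    Only reads whose called tail exceeds ``tail_threshold`` contribute; the
    observed site is the aligned 3' end (half-open end on '+', start on '-'),
    with tail and adapter already excluded by the aligner soft clip.
    """
    out: dict[str, Counter] = defaultdict(Counter)
    for read in reads:
        tail = tails.get(read.read_id)
        if tail is None or tail.tail_length <= tail_threshold:
            continue
        gene = assign_gene_for_end(read, genes, downstream_margin)
        if gene is None:
            continue
        out[gene.gene_id][read.three_prime_pos] += 1
    return dict(out)


def cluster_pacs(
    site_counts: Mapping[str, Mapping[int, int]],
    genes: GeneIndex | None = None,
    gap: int = CLUSTER_GAP_NT,
    min_support: int = MIN_SUPPORT,
    support_mode: str = "reads",
) -> list[PolyACluster]:
    """Single-linkage chain sites into PACs and drop weak clusters.

    Consecutive sorted sites at distance <= ``gap`` merge.  ``support_mode``
    selects what "fewer than three poly(A) sites" counts: ``"reads"`` (total
    read support, the PAC-methodology convention, default) or
    ``"positions"`` (distinct end positions).  The representative is the
    max-count site, ties broken toward the most upstream (5'-most) site —
    strand-aware when the gene strand is known.
    """
    if support_mode not in ("reads", "positions"):
        raise ValueError("support_mode must be 'reads' or 'positions'")
    clusters: list[PolyACluster] = []
    for gene_id in sorted(site_counts):
        counts = site_counts[gene_id]
        strand = "+"
        if genes is not None and gene_id in genes.genes:
            strand = genes[gene_id].strand
        positions = sorted(counts)
        chain: list[int] = []
        chains: list[list[int]] = []
        for pos in positions:
            if chain and pos - chain[-1] > gap:
                chains.append(chain)
                chain = []
            chain.append(pos)
        if chain:
            chains.append(chain)
        for members in chains:
            support = sum(counts[p] for p in members)
            size = support if support_mode == "reads" else len(members)
            if size < min_support:
                continue
            max_count = max(counts[p] for p in members)
            top = [p for p in members if counts[p] == max_count]
            representative = min(top) if strand == "+" else max(top)
            clusters.append(
                PolyACluster(
                    gene_id=gene_id,
                    sites=tuple((p, counts[p]) for p in members),
                    representative=representative,
                    support=support,
                )
            )
    return clusters


def select_single_pa_genes(clusters: Sequence[PolyACluster]) -> dict[str, int]:
    """Genes with exactly one surviving PAC -> representative poly(A) site."""
    per_gene: dict[str, list[PolyACluster]] = defaultdict(list)
    for c in clusters:
        per_gene[c.gene_id].append(c)
    return {
        gene_id: cl[0].representative
        for gene_id, cl in per_gene.items()
        if len(cl) == 1
    }


def write_pac_tsv(clusters: Sequence[PolyACluster], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\trepresentative\tsupport\tspan_start\tspan_end\tsites\n")
        for c in clusters:
            sites = ",".join(f"{p}:{n}" for p, n in c.sites)
            fh.write(f"{c.gene_id}\t{c.representative}\t{c.support}\t"
                     f"{c.span[0]}\t{c.span[1]}\t{sites}\n")


def write_pa_bed(pa_table: Mapping[str, int], genes: GeneIndex,
                 support: Mapping[str, int], path: str) -> None:
    """Representative poly(A) sites as BED6 (name=gene_id, score=support)."""
    rows = []
    for gene_id, pos in pa_table.items():
        g = genes[gene_id]
        rows.append((g.chrom, pos, pos + 1, gene_id, support.get(gene_id, 0), g.strand))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, name, score, strand in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
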