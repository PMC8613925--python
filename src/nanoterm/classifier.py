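"""Classification of termination RNA intermediates.

Each oriented read is assigned to a gene and then to one of four
intermediate classes defined positionally around the gene's representative
poly(A) site (pA), using signed strand-aware distances (downstream
positive):

* ``POLYA`` — poly(A) tail longer than 15 nt: cleaved and polyadenylated.
* ``READTHROUGH`` — non-poly(A), 5' end in the gene body (>50 nt upstream
  of pA) and 3' end more than 50 nt past pA: Pol II not yet released and
  the transcript not yet cleaved.
* ``CLEAVED_5P`` — non-poly(A), 5' end in the gene body, 3' end within
  ±50 nt of pA: the upstream cleavage product before polyadenylation.
* ``CLEAVED_3P`` — non-poly(A), 5' end within 500 nt downstream of pA: the
  downstream cleavage product normally degraded by the 5'->3' torpedo
  exonuclease.  When a same-strand neighbour starts nearby, the 5' end
  must additionally lie at least 100 nt before that neighbour's TSS, so
  that the neighbour's own nascent transcripts are not miscounted.

Non-poly(A) calls are trusted only when the 3' adapter sits within 5 nt of
the alignment end; anything else is ``UNCLASSIFIED`` (kept and counted —
read accounting stays conservative).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .annotation_io import GeneIndex, GeneModel
from .polya_tail import TailCall
from .read_ingest import OrientedRead

__all__ = [
    "CLASSES",
    "ClassifiedRead",
    "classify_by_coords",
    "assign_gene",
    "classify_read",
    "classify_all",
    "write_classified_tsv",
]

CLASSES = ("POLYA", "READTHROUGH", "CLEAVED_5P", "CLEAVED_3P")

TAIL_THRESHOLD_NT = 15
MAX_ADAPTER_GAP_NT = 5
BODY_MARGIN_NT = 50
CLEAVED3_WINDOW_NT = 500
NEIGHBOR_TSS_GUARD_NT = 100


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    gene_id: str | None
    read_class: str  # one of CLASSES or "UNCLASSIFIED"
    d5: int | None  # signed distance of 5' end from pA, downstream positive
    d3: int | None
    tail_length: int
    reason: str = ""


def classify_by_coords(
    tail_length: int,
    three_prime_gap: int,
    d5: int,
    d3: int,
    downstream_tss_d: int | None = None,
    *,
    tail_threshold: int = TAIL_THRESHOLD_NT,
    max_adapter_gap: int = MAX_ADAPTER_GAP_NT,
    body_margin: int = BODY_MARGIN_NT,
    cleaved3_window: int = CLEAVED3_WINDOW_NT,
    tss_guard: int = NEIGHBOR_TSS_GUARD_NT,
) -> str:
    """Pure positional decision ladder; ``downstream_tss_d`` is the signed
    distance of the nearest same-strand downstream gene's TSS from pA, or
    ``None`` when no such gene starts within the 3'-cleavage window."""
    if tail_length > tail_threshold:
        return "POLYA"
    if three_prime_gap >= max_adapter_gap:
        return "UNCLASSIFIED"
    if d5 < -body_margin and d3 > body_margin:
        return "READTHROUGH"
    if d5 < -body_margin and -body_margin <= d3 <= body_margin:
        return "CLEAVED_5P"
    if 0 <= d5 <= cleaved3_window:
        if downstream_tss_d is not None and downstream_tss_d <= cleaved3_window:
            if d5 > downstream_tss_d - tss_guard:
                return "UNCLASSIFIED"
        return "CLEAVED_3P"
    return "UNCLASSIFIED"


def assign_gene(
    read: OrientedRead,
    genes: GeneIndex,
    pa_table: Mapping[str, int] | None = None,
    downstream_margin: int = CLEAVED3_WINDOW_NT,
) -> GeneModel | None:
    """Choose the gene a read reports on.

    Candidates are same-strand genes whose span, extended to pA + 500 nt
    (TES + margin when the gene has no called pA), overlaps the read.  The
    gene containing the read 5' end wins; otherwise maximal overlap.
    """
    lo = min(read.five_prime_pos, read.three_prime_pos)
    hi = max(read.five_prime_pos, read.three_prime_pos)
    best: tuple[bool, int, str] | None = None
    best_gene: GeneModel | None = None
    for g in genes.overlapping(read.chrom, lo - downstream_margin, hi + downstream_margin,
                               strand=read.bio_strand):
        pa = pa_table.get(g.gene_id) if pa_table else None
        anchor = pa if pa is not None else g.tes
        if g.strand == "+":
            g_lo, g_hi = g.start, max(g.end, anchor + downstream_margin)
        else:
            g_lo, g_hi = min(g.start, anchor - downstream_margin), g.end
        if g_hi <= lo or hi <= g_lo:
            continue
        contains_5p = g.start <= read.five_prime_pos < g.end
        overlap = min(hi, g_hi) - max(lo, g_lo)
        key = (contains_5p, overlap, g.gene_id)
        if best is None or key > best:
            best, best_gene = key, g
    return best_gene


def _signed(pos: int, pa: int, strand: str) -> int:
    return pos - pa if strand == "+" else pa - pos


def _downstream_tss_d(gene: GeneModel, genes: GeneIndex, pa: int,
                      window: int = CLEAVED3_WINDOW_NT) -> int | None:
    """Signed pA-relative TSS of the nearest same-strand downstream gene,
    when that TSS falls within the 3'-cleavage search window."""
    it = (genes.first_right_of(gene.chrom, pa) if gene.strand == "+"
          else genes.first_left_of(gene.chrom, pa))
    for nb in it:
        if nb.gene_id == gene.gene_id or nb.strand != gene.strand:
            continue
        d = _signed(nb.tss, pa, gene.strand)
        if d < 0:
            continue
        return d if d <= window else None
    return None


def classify_read(
    read: OrientedRead,
    tail: TailCall,
    gene: GeneModel,
    pa: int | None,
    genes: GeneIndex | None = None,
    **thresholds,
) -> ClassifiedRead:
    if pa is None:
        return ClassifiedRead(read.read_id, gene.gene_id, "UNCLASSIFIED",
                              None, None, tail.tail_length, reason="no_pa")
    d5 = _signed(read.five_prime_pos, pa, gene.strand)
    d3 = _signed(read.three_prime_pos, pa, gene.strand)
    window = thresholds.get("cleaved3_window", CLEAVED3_WINDOW_NT)
    tss_d = _downstream_tss_d(gene, genes, pa, window) if genes is not None else None
    cls = classify_by_coords(tail.tail_length, read.three_prime_gap, d5, d3,
                             tss_d, **thresholds)
    return ClassifiedRead(read.read_id, gene.gene_id, cls, d5, d3, tail.tail_length)


def classify_all(
    reads: Iterable[OrientedRead],
    tails: Mapping[str, TailCall],
    genes: GeneIndex,
    pa_table: Mapping[str, int],
    **thresholds,
) -> tuple[list[ClassifiedRead], dict[str, float]]:
    """Classify every read; returns the per-read table and the genome-wide
    class proportions among classified reads (empty dict when none)."""
    out: list[ClassifiedRead] = []
    for read in reads:
        tail = tails.get(read.read_id)
        if tail is None:
            tail = TailCall(read.read_id, 0, 1.0)
        gene = assign_gene(read, genes, pa_table)
        if gene is None:
            out.append(ClassifiedRead(read.read_id, None, "UNCLASSIFIED",
                                      None, None, tail.tail_length, reason="no_gene"))
            continue
        out.append(classify_read(read, tail, gene, pa_table.get(gene.gene_id),
                                 genes, **thresholds))
    counted = Counter(r.read_class for r in out if r.read_class in CLASSES)
    total = sum(counted.values())
    proportions = {c: counted.get(c, 0) / total for c in CLASSES} if total else {}
    return out, proportions


def write_classified_tsv(rows: Sequence[ClassifiedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tgene_id\tclass\td5\td3\ttail_length\treason\n")
        for r in rows:
            d5 = "" if r.d5 is None else r.d5
            d3 = "" if r.d3 is None else r.d3
            fh.write(f"{r.read_id}\t{r.gene_id or ''}\t{r.read_class}\t{d5}\t{d3}\t"
                     f"{r.tail_length}\t{r.reason}\n")
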