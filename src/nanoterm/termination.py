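"""Termination windows and end-position meta-profiles.

A gene's termination window (TW) is the median readthrough distance — the
distance from the representative poly(A) site (pA) to the 3' ends of reads
still attached past the pA (readthrough transcripts and 3' cleavage
products with 3' ends more than 50 nt downstream of pA).  The median is
robust to sequencing depth, unlike the longest read.  The termination
window end (TWE) is the pA shifted downstream by the TW: the modal Pol II
release point.  Genes need at least 15 contributing reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneIndex
from .classifier import ClassifiedRead

__all__ = [
    "TerminationWindow",
    "MetaProfile",
    "readthrough_distance",
    "collect_distances",
    "compute_tw",
    "tw_table",
    "meta_profile",
    "write_bedgraph",
]

MIN_TW_READS = 15
TW_D3_MIN_NT = 50  # contributing reads must end >50 nt past pA


@dataclass(frozen=True)
class TerminationWindow:
    gene_id: str
    tw: float  # nt, median readthrough distance (0.5-nt resolution)
    n_reads: int
    twe: int  # genomic position: pA shifted downstream by tw, rounded half-up
    per_read_distances: tuple[int, ...] = field(default=(), repr=False)


@dataclass(frozen=True)
class MetaProfile:
    anchor: str  # "pA" or "TWE"
    end_type: str  # "5p" or "3p"
    window: int
    offsets: np.ndarray  # -window..+window
    density: np.ndarray  # sums to 1 when any signal; all-zero otherwise
    n_ends: int


def readthrough_distance(read: ClassifiedRead, d3_min: int = TW_D3_MIN_NT) -> int | None:
    """The pA-to-3'-end distance for TW-contributing reads, else ``None``."""
    if read.read_class not in ("READTHROUGH", "CLEAVED_3P"):
        return None
    if read.d3 is None or read.d3 <= d3_min:
        return None
    return read.d3


def collect_distances(
    reads: Iterable[ClassifiedRead],
    include_cleaved3: bool = True,
    d3_min: int = TW_D3_MIN_NT,
) -> dict[str, list[int]]:
    """Per-gene readthrough-distance lists; each read contributes once."""
    out: dict[str, list[int]] = defaultdict(list)
    for r in reads:
        if not include_cleaved3 and r.read_class == "CLEAVED_3P":
            continue
        d = readthrough_distance(r, d3_min)
        if d is not None and r.gene_id is not None:
            out[r.gene_id].append(d)
    return dict(out)


def compute_tw(
    gene_id: str,
    pa: int,
    strand: str,
    distances: Sequence[int],
    min_reads: int = MIN_TW_READS,
) -> TerminationWindow | None:
    """Median readthrough distance, or ``None`` below the read threshold.

    Even counts take the mean of the central pair (0.5-nt resolution); the
    TWE rounds half-up and is shifted downstream strand-aware.
    """
    if len(distances) < min_reads:
        return None
    tw = float(np.median(np.asarray(distances, dtype=float)))
    shift = int(np.floor(tw + 0.5))
    twe = pa + shift if strand == "+" else pa - shift
    return TerminationWindow(gene_id, tw, len(distances), twe,
                             tuple(sorted(distances)))


def tw_table(
    reads: Iterable[ClassifiedRead],
    pa_table: Mapping[str, int],
    genes: GeneIndex,
    min_reads: int = MIN_TW_READS,
    include_cleaved3: bool = True,
    d3_min: int = TW_D3_MIN_NT,
) -> pd.DataFrame:
    """Per-gene termination-window table (gene_id, chrom, strand, pA, tw,
    twe, n_reads), one row per qualifying gene."""
    dists = collect_distances(reads, include_cleaved3, d3_min)
    rows = []
    for gene_id in sorted(dists):
        if gene_id not in pa_table or gene_id not in genes.genes:
            continue
        g = genes[gene_id]
        win = compute_tw(gene_id, pa_table[gene_id], g.strand, dists[gene_id], min_reads)
        if win is None:
            continue
        rows.append({
            "gene_id": gene_id, "chrom": g.chrom, "strand": g.strand,
            "pA": pa_table[gene_id], "tw": win.tw, "twe": win.twe,
            "n_reads": win.n_reads,
        })
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "pA",
                                       "tw", "twe", "n_reads"])


def meta_profile(
    reads: Iterable[ClassifiedRead],
    pa_table: Mapping[str, int],
    genes: GeneIndex,
    end_type: str = "3p",
    window: int = 500,
    anchors: Mapping[str, int] | None = None,
    anchor_name: str = "pA",
    exclude_polya: bool = True,
) -> MetaProfile:
    """Pooled per-position end density around per-gene anchors.

    By default the anchor is the gene's pA; pass ``anchors`` (e.g. TWE
    positions from :func:`tw_table`) to re-anchor.  Offsets are signed and
    strand-aware (downstream positive); counts normalize to unit sum, with
    no smoothing.  Only non-poly(A) reads contribute by default.
    """
    counts = np.zeros(2 * window + 1, dtype=float)
    n = 0
    for r in reads:
        if r.gene_id is None or r.gene_id not in pa_table:
            continue
        if exclude_polya and r.read_class == "POLYA":
            continue
        if r.read_class == "UNCLASSIFIED":
            continue
        d = r.d5 if end_type == "5p" else r.d3
        if d is None:
            continue
        shift = 0
        if anchors is not None:
            if r.gene_id not in anchors:
                continue
            g = genes[r.gene_id]
            pa = pa_table[r.gene_id]
            shift = (anchors[r.gene_id] - pa) if g.strand == "+" else (pa - anchors[r.gene_id])
        off = d - shift
        if -window <= off <= window:
            counts[off + window] += 1
            n += 1
    total = counts.sum()
    density = counts / total if total > 0 else counts
    return MetaProfile(anchor_name, end_type, window,
                       np.arange(-window, window + 1), density, n)


def write_bedgraph(
    positions: Mapping[tuple[str, int], float], path: str
) -> None:
    """Write {(chrom, pos): value} as a bedGraph (one strand per file)."""
    with open(path, "w") as fh:
        for (chrom, pos), val in sorted(positions.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{val:g}\n")
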