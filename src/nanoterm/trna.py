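"""Termination at Pol II genes with tRNA genes immediately downstream.

Closely spaced downstream tRNA genes (gap < 200 nt) act as efficient
termination signals; the quantity of interest is the signed distance from
the termination window end (TWE) of the upstream Pol II gene to the
tRNA's proximal edge — the tRNA start for tandem pairs and the tRNA 3'
end for convergent pairs.  Positive distances place the TWE upstream of
the tRNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotation_io import GeneIndex, downstream_neighbor

__all__ = ["TrnaPairing", "pair_genes_with_trnas", "twe_trna_distances",
           "modal_distance", "matched_control_cohort"]

MAX_TRNA_GAP_NT = 200


@dataclass(frozen=True)
class TrnaPairing:
    gene_id: str
    trna_id: str
    orientation: str  # "tandem" or "convergent"
    gap: int
    reference_edge: int  # genomic coordinate of the tRNA edge facing the gene


def pair_genes_with_trnas(
    genes: GeneIndex, max_gap: int = MAX_TRNA_GAP_NT
) -> list[TrnaPairing]:
    """Protein-coding genes whose nearest downstream gene is a tRNA within
    ``max_gap`` nt of the TES; at most one pairing per gene."""
    pairings = []
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        rel = downstream_neighbor(g, genes, max_gap)
        if rel is None:
            continue
        nb = genes[rel.downstream_gene]
        if nb.biotype != "tRNA":
            continue
        # proximal edge: genomically left of the tRNA for a '+' query, right for '-'
        edge = nb.start if g.strand == "+" else nb.end
        pairings.append(TrnaPairing(g.gene_id, nb.gene_id, rel.orientation,
                                    rel.gap, edge))
    return sorted(pairings, key=lambda p: p.gene_id)


def twe_trna_distances(
    pairings: Sequence[TrnaPairing],
    tw_df: pd.DataFrame,
    genes: GeneIndex,
) -> tuple[pd.DataFrame, int]:
    """Signed TWE-to-tRNA distances for paired genes with a termination
    window; returns (per-pair table, number of pairs dropped for lacking a
    TW).  Tandem pairs measure to the tRNA start, convergent pairs to the
    tRNA 3' end — both are the proximal genomic edge."""
    twe = dict(zip(tw_df["gene_id"], tw_df["twe"]))
    rows, dropped = [], 0
    for p in pairings:
        if p.gene_id not in twe:
            dropped += 1
            continue
        g = genes[p.gene_id]
        t = twe[p.gene_id]
        dist = (p.reference_edge - t) if g.strand == "+" else (t - p.reference_edge)
        rows.append({"gene_id": p.gene_id, "trna_id": p.trna_id,
                     "orientation": p.orientation, "gap": p.gap,
                     "twe": t, "distance": int(dist)})
    df = pd.DataFrame(rows, columns=["gene_id", "trna_id", "orientation",
                                     "gap", "twe", "distance"])
    return df, dropped


def modal_distance(df: pd.DataFrame, orientation: str) -> int | None:
    """Most frequent TWE-to-tRNA distance for one orientation class."""
    sub = df[df["orientation"] == orientation]["distance"]
    if sub.empty:
        return None
    counts = Counter(sub)
    top = max(counts.values())
    return min(d for d, c in counts.items() if c == top)


def matched_control_cohort(
    genes: GeneIndex,
    pairings: Sequence[TrnaPairing],
    max_gap: int = MAX_TRNA_GAP_NT,
    bin_nt: int = 25,
) -> list[str]:
    """Genes with a *non*-tRNA downstream neighbour, gap-matched to the
    tRNA cohort by simple binning (at most as many controls per gap bin as
    tRNA-paired genes in that bin)."""
    want = Counter(p.gap // bin_nt for p in pairings)
    cohort: list[str] = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.biotype != "protein_coding":
            continue
        rel = downstream_neighbor(g, genes, max_gap)
        if rel is None:
            continue
        nb = genes[rel.downstream_gene]
        if nb.biotype == "tRNA":
            continue
        b = rel.gap // bin_nt
        if want.get(b, 0) > 0:
            want[b] -= 1
            cohort.append(g.gene_id)
    return cohort
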