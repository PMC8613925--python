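"""Between-genotype termination comparison and readthrough chimera calls.

Per-gene termination windows are compared between two samples (for
example wildtype against an exonuclease mutant) with a two-sided
Mann-Whitney U test on the underlying readthrough-distance lists; the
significance threshold defaults to p < 0.001 with no multiple-testing
correction, and Benjamini-Hochberg q-values are emitted as an extra
column for users who want them.

Chimera detection looks for the signature of defective torpedo
degradation at tandem gene pairs: uncleaved 3' cleavage products of the
upstream gene running past the downstream gene's TSS, and poly(A) reads
ending at the downstream gene's pA whose 5' ends trace back to the
upstream pA (serial cleavage and polyadenylation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import GeneIndex, downstream_neighbor
from .classifier import ClassifiedRead

__all__ = ["TwComparison", "ChimeraCall", "compare_tw", "compare_tw_table",
           "detect_chimeras"]

ALPHA = 0.001
MIN_TW_READS = 15
CHIMERA_MIN_READS = 3
PA_MATCH_TOL_NT = 50
EXACT_MAX_N = 25


@dataclass(frozen=True)
class TwComparison:
    gene_id: str
    tw_a: float
    tw_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    significant: bool
    direction: int  # sign(median_b - median_a)


@dataclass(frozen=True)
class ChimeraCall:
    upstream_gene: str
    downstream_gene: str
    n_spanning_cleaved_reads: int
    n_fed_polya_reads: int
    n_spanning_full: int  # spanning cleaved reads covering the whole downstream gene


def compare_tw(
    gene_id: str,
    distances_a: Sequence[float],
    distances_b: Sequence[float],
    alpha: float = ALPHA,
    min_reads: int = MIN_TW_READS,
) -> TwComparison | None:
    """Two-sided Mann-Whitney U on two per-gene distance samples.

    Exact null distribution when both samples are small (n <= 25) and
    tie-free; normal approximation with tie and continuity corrections
    otherwise.  Returns ``None`` when either sample is below the read
    threshold.
    """
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if len(a) < min_reads or len(b) < min_reads:
        return None
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return TwComparison(
        gene_id=gene_id, tw_a=med_a, tw_b=med_b, n_a=len(a), n_b=len(b),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        direction=int(np.sign(med_b - med_a)),
    )


def compare_tw_table(
    dists_a: Mapping[str, Sequence[float]],
    dists_b: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
    min_reads: int = MIN_TW_READS,
) -> pd.DataFrame:
    """All-genes comparison table with a Benjamini-Hochberg q-value column."""
    rows = []
    for gene_id in sorted(set(dists_a) & set(dists_b)):
        cmp = compare_tw(gene_id, dists_a[gene_id], dists_b[gene_id], alpha, min_reads)
        if cmp is None:
            continue
        rows.append({
            "gene_id": cmp.gene_id, "tw_a": cmp.tw_a, "tw_b": cmp.tw_b,
            "n_a": cmp.n_a, "n_b": cmp.n_b, "u_statistic": cmp.u_statistic,
            "p_value": cmp.p_value, "significant": cmp.significant,
            "direction": cmp.direction,
        })
    df = pd.DataFrame(rows, columns=["gene_id", "tw_a", "tw_b", "n_a", "n_b",
                                     "u_statistic", "p_value", "significant",
                                     "direction"])
    if len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def detect_chimeras(
    reads: Iterable[ClassifiedRead],
    genes: GeneIndex,
    pa_table: Mapping[str, int],
    min_reads: int = CHIMERA_MIN_READS,
    max_gap: int = 10_000,
    pa_tol: int = PA_MATCH_TOL_NT,
) -> list[ChimeraCall]:
    """Cleaved readthrough transcripts entering the immediate downstream gene.

    For each tandem (same-strand) gene pair with a called upstream pA:

    * ``n_spanning_cleaved_reads`` — upstream CLEAVED_3P reads whose 3' end
      passes the downstream gene's TSS;
    * ``n_fed_polya_reads`` — POLYA reads of the downstream gene ending
      within ``pa_tol`` of its pA whose 5' end lies at/after the upstream
      pA and before the downstream TSS.

    Pairs reach the table when either count >= ``min_reads``; read
    positions are reconstructed from the pA-relative distances carried by
    each classified read.
    """
    by_gene: dict[str, list[ClassifiedRead]] = {}
    for r in reads:
        if r.gene_id is not None:
            by_gene.setdefault(r.gene_id, []).append(r)

    calls: list[ChimeraCall] = []
    for gene_id in sorted(pa_table):
        if gene_id not in genes.genes:
            continue
        up = genes[gene_id]
        rel = downstream_neighbor(up, genes, max_gap)
        if rel is None or rel.orientation != "tandem":
            continue
        down = genes[rel.downstream_gene]
        pa_up = pa_table[gene_id]
        sgn = 1 if up.strand == "+" else -1
        tss_d = sgn * (down.tss - pa_up)  # downstream TSS, pA-relative
        tes_d = sgn * (down.tes - pa_up)

        n_span = n_full = 0
        for r in by_gene.get(gene_id, ()):
            if r.read_class == "CLEAVED_3P" and r.d3 is not None and r.d3 > tss_d:
                n_span += 1
                if r.d3 > tes_d:
                    n_full += 1

        n_fed = 0
        pa_down = pa_table.get(down.gene_id)
        if pa_down is not None:
            pa_down_d = sgn * (pa_down - pa_up)
            for r in by_gene.get(down.gene_id, ()):
                if r.read_class != "POLYA" or r.d5 is None or r.d3 is None:
                    continue
                # distances here are relative to the downstream gene's pA
                if abs(r.d3) > pa_tol:
                    continue
                five_d = pa_down_d + r.d5  # re-express 5' end relative to upstream pA
                if 0 <= five_d < tss_d:
                    n_fed += 1

        if n_span >= min_reads or n_fed >= min_reads:
            calls.append(ChimeraCall(gene_id, down.gene_id, n_span, n_fed, n_full))
    return calls
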