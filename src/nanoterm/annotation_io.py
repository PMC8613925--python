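"""Gene-annotation parsing and strand-aware neighbour resolution.

Internally every feature is stored 0-based half-open regardless of strand;
GFF3 input (1-based, closed) is converted on read, BED input passes through.
The transcription start site (TSS) and transcription end site (TES) are
derived from ``start``/``end`` and the strand, never stored separately.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "NeighborRelation",
    "GeneIndex",
    "read_annotation",
    "downstream_neighbor",
    "write_genes_tsv",
]

#: feature-type / attribute driven biotype assignment used by default
DEFAULT_BIOTYPE_RULES = {
    "feature_types": {"gene": "protein_coding", "tRNA": "tRNA", "tRNA_gene": "tRNA"},
    "attribute_keys": ("biotype", "gene_biotype", "locus_type"),
}


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates are 0-based half-open with ``start < end``."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid span [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base on '+', rightmost on '-'."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Annotated transcription end (the 3' boundary of the gene span)."""
        return self.end if self.strand == "+" else self.start

    def overlaps(self, other: "GeneModel") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class NeighborRelation:
    """Nearest downstream gene relative to a query gene's TES.

    ``gap`` is the distance from the query TES to the neighbour's proximal
    edge; ``orientation`` follows transcription directions: ``tandem`` for
    same-strand pairs, ``convergent`` when the neighbour points back at the
    query, ``divergent`` otherwise (never produced by a TES-side search).
    """

    upstream_gene: str
    downstream_gene: str
    orientation: str
    gap: int


class GeneIndex:
    """Per-chromosome interval index over a set of :class:`GeneModel`."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        # sorted starts/ends per chromosome for directional nearest queries
        self._by_start: dict[str, list[GeneModel]] = {}
        self._by_end: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id: {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
            self._by_start.setdefault(g.chrom, []).append(g)
            self._by_end.setdefault(g.chrom, []).append(g)
        for chrom in self._by_start:
            self._by_start[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._by_end[chrom].sort(key=lambda g: (g.end, g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def overlapping(self, chrom: str, start: int, end: int, strand: str | None = None) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return hits

    def first_right_of(self, chrom: str, pos: int) -> Iterator[GeneModel]:
        """Genes with ``start >= pos``, nearest first."""
        lst = self._by_start.get(chrom, [])
        i = bisect_left([g.start for g in lst], pos)
        yield from lst[i:]

    def first_left_of(self, chrom: str, pos: int) -> Iterator[GeneModel]:
        """Genes with ``end <= pos``, nearest first."""
        lst = self._by_end.get(chrom, [])
        i = bisect_right([g.end for g in lst], pos)
        yield from reversed(lst[:i])


def _biotype_from(feature_type: str, attributes: dict, rules: dict) -> str:
    for key in rules.get("attribute_keys", ()):
        if key in attributes:
            val = attributes[key]
            if isinstance(val, (list, tuple)):
                val = val[0]
            return str(val)
    return rules.get("feature_types", {}).get(feature_type, "other")


def _read_gff3(path: str, rules: dict) -> list[GeneModel]:
    wanted = set(rules.get("feature_types", {}))
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error", sort_attribute_values=True,
    )
    out = []
    for ftype in wanted:
        for feat in db.features_of_type(ftype):
            if feat.strand not in "+-":
                warnings.warn(f"skipping {feat.id}: unstranded feature")
                continue
            gid = feat.attributes.get("ID", [feat.id])[0]
            out.append(
                GeneModel(
                    gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                    start=feat.start - 1, end=feat.end,  # 1-based closed -> 0-based half-open
                    biotype=_biotype_from(ftype, dict(feat.attributes), rules),
                )
            )
    return out


def _read_bed(path: str, rules: dict) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED line with <6 fields: {line!r}")
            chrom, start, end, name, _score, strand = f[:6]
            if strand not in "+-":
                warnings.warn(f"skipping {name}: strand {strand!r}")
                continue
            biotype = f[6] if len(f) > 6 and len(f) not in (12,) and f[6] in ("protein_coding", "tRNA", "other") else "protein_coding"
            out.append(GeneModel(name, chrom, strand, int(start), int(end), biotype))
    return out


def read_annotation(path: str | Path, biotype_rules: dict | None = None) -> GeneIndex:
    """Read a GFF3 or BED6/BED12 annotation into a :class:`GeneIndex`.

    GFF3 coordinates (1-based closed) are converted to the internal 0-based
    half-open convention; BED passes through unchanged.  Duplicate gene ids
    raise; features on strands other than ``+``/``-`` are skipped with a
    warning.
    """
    rules = biotype_rules or DEFAULT_BIOTYPE_RULES
    path = str(path)
    if path.endswith((".bed", ".bed6", ".bed12")):
        genes = _read_bed(path, rules)
    else:
        genes = _read_gff3(path, rules)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id: {g.gene_id}")
        seen.add(g.gene_id)
    return GeneIndex(genes)


def downstream_neighbor(
    gene: GeneModel, genes: GeneIndex, max_gap: int
) -> NeighborRelation | None:
    """Nearest gene beginning downstream of ``gene``'s TES within ``max_gap``.

    Downstream is genomically right of the TES on '+' and left on '-'.
    Genes overlapping the query are skipped (closely-spaced-gene analyses
    assume disjoint gene bodies).  The gap is TES to the neighbour's proximal
    edge; orientation is tandem for same-strand neighbours and convergent
    otherwise.  Returns ``None`` when nothing qualifies.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    tes = gene.tes
    candidates = (
        genes.first_right_of(gene.chrom, tes)
        if gene.strand == "+"
        else genes.first_left_of(gene.chrom, tes)
    )
    for nb in candidates:
        if nb.gene_id == gene.gene_id or nb.overlaps(gene):
            continue
        gap = (nb.start - tes) if gene.strand == "+" else (tes - nb.end)
        if gap >= max_gap:
            return None
        orientation = "tandem" if nb.strand == gene.strand else "convergent"
        return NeighborRelation(gene.gene_id, nb.gene_id, orientation, gap)
    return None


def write_genes_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tstart\tend\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\t{g.biotype}\n")
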