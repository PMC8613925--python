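import numpy as np
import pytest

from nanoterm.annotation_io import (GeneIndex, GeneModel, downstream_neighbor,
                                    read_annotation)


def make_index(*genes):
    return GeneIndex(genes)


class TestReadAnnotation:
    def test_gff3_converts_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1;biotype=protein_coding\n"
                     "chr1\tsrc\ttRNA\t3001\t3072\t.\t-\t.\tID=t1\n")
        idx = read_annotation(p)
        assert idx["g1"].start == 1000 and idx["g1"].end == 2000
        assert idx["t1"].biotype == "tRNA" and idx["t1"].strand == "-"

    def test_bed_passes_through(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t1000\t2000\tg1\t0\t+\n")
        idx = read_annotation(p)
        assert idx["g1"].start == 1000 and idx["g1"].end == 2000

    def test_duplicate_gene_id_is_an_error(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\nchr1\t300\t400\tg1\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(p)

    def test_odd_strand_skipped_with_warning(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t.\nchr1\t300\t400\tg2\t0\t+\n")
        with pytest.warns(UserWarning):
            idx = read_annotation(p)
        assert list(idx.genes) == ["g2"]


class TestTssTes:
    def test_strand_aware_derivation(self):
        plus = GeneModel("a", "c", "+", 100, 500)
        minus = GeneModel("b", "c", "-", 100, 500)
        assert (plus.tss, plus.tes) == (100, 500)
        assert (minus.tss, minus.tes) == (500, 100)


class TestDownstreamNeighbor:
    def test_tandem_gap(self):
        a = GeneModel("a", "c", "+", 4000, 5000)
        t = GeneModel("t", "c", "+", 5100, 5180, "tRNA")
        rel = downstream_neighbor(a, make_index(a, t), 200)
        assert rel.orientation == "tandem" and rel.gap == 100
        assert rel.downstream_gene == "t"

    def test_convergent_gap(self):
        a = GeneModel("a", "c", "+", 4000, 5000)
        t = GeneModel("t", "c", "-", 5050, 5130, "tRNA")
        rel = downstream_neighbor(a, make_index(a, t), 200)
        assert rel.orientation == "convergent" and rel.gap == 50

    def test_gap_at_threshold_excluded(self):
        a = GeneModel("a", "c", "+", 4000, 5000)
        b = GeneModel("b", "c", "+", 5250, 5500)
        assert downstream_neighbor(a, make_index(a, b), 200) is None
        assert downstream_neighbor(a, make_index(a, b), 251) is not None

    def test_minus_strand_query_searches_left(self):
        a = GeneModel("a", "c", "-", 4000, 5000)  # TES at 4000
        b = GeneModel("b", "c", "-", 3800, 3900)
        rel = downstream_neighbor(a, make_index(a, b), 200)
        assert rel.downstream_gene == "b" and rel.gap == 100
        assert rel.orientation == "tandem"

    def test_overlapping_gene_skipped(self):
        a = GeneModel("a", "c", "+", 4000, 5000)
        nested = GeneModel("n", "c", "+", 4500, 5200)
        far = GeneModel("f", "c", "+", 5100, 5300)
        rel = downstream_neighbor(a, make_index(a, nested, far), 200)
        assert rel.downstream_gene == "f"


def brute_force_neighbor(gene, all_genes, max_gap):
    best = None
    for nb in all_genes:
        if nb.gene_id == gene.gene_id or nb.chrom != gene.chrom or nb.overlaps(gene):
            continue
        gap = (nb.start - gene.tes) if gene.strand == "+" else (gene.tes - nb.end)
        if gap < 0 or gap >= max_gap:
            continue
        if best is None or gap < best[0]:
            best = (gap, nb)
    if best is None:
        return None
    orient = "tandem" if best[1].strand == gene.strand else "convergent"
    return (best[1].gene_id, orient, best[0])


def random_annotation(rng, n):
    starts = rng.choice(np.arange(0, 100_000, 7), size=n, replace=False)
    genes, used_ends = [], set()
    for i, s in enumerate(sorted(starts)):
        end = int(s) + int(rng.integers(50, 400))
        while end in used_ends:  # unique ends keep nearest-neighbour ties away
            end += 1
        used_ends.add(end)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", "c", strand, int(s), end))
    return genes


class TestNeighborProperties:
    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            genes = random_annotation(rng, int(rng.integers(5, 200)))
            idx = GeneIndex(genes)
            for g in genes:
                rel = downstream_neighbor(g, idx, 500)
                expected = brute_force_neighbor(g, genes, 500)
                got = None if rel is None else (rel.downstream_gene,
                                                rel.orientation, rel.gap)
                assert got == expected, g

    def test_strand_mirror_invariance(self):
        rng = np.random.default_rng(11)
        genes = random_annotation(rng, 80)
        pivot = 200_000
        flip = {"+": "-", "-": "+"}
        mirrored = [GeneModel(g.gene_id, g.chrom, flip[g.strand],
                              pivot - g.end, pivot - g.start, g.biotype)
                    for g in genes]
        idx, midx = GeneIndex(genes), GeneIndex(mirrored)
        for g, m in zip(genes, mirrored):
            a = downstream_neighbor(g, idx, 500)
            b = downstream_neighbor(m, midx, 500)
            a_key = None if a is None else (a.downstream_gene, a.orientation, a.gap)
            b_key = None if b is None else (b.downstream_gene, b.orientation, b.gap)
            assert a_key == b_key
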