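import numpy as np
import pandas as pd
import pytest

from nanoterm.annotation_io import GeneIndex, GeneModel
from nanoterm.classifier import ClassifiedRead
from nanoterm.simulate import SimConfig, simulate_dataset
from nanoterm.pipeline import RunConfig, run_pipeline
from nanoterm.termination import (compute_tw, meta_profile,
                                  readthrough_distance, tw_table)


def classified(read_id, gene_id, cls, d5, d3, tail=0):
    return ClassifiedRead(read_id, gene_id, cls, d5, d3, tail)


class TestReadthroughDistance:
    def test_identity_on_contributing_read(self):
        assert readthrough_distance(classified("r", "g", "READTHROUGH", -200, 120)) == 120

    def test_d3_at_50_excluded(self):
        assert readthrough_distance(classified("r", "g", "READTHROUGH", -200, 50)) is None

    def test_cleaved_3p_contributes(self):
        assert readthrough_distance(classified("r", "g", "CLEAVED_3P", 10, 130)) == 130

    def test_polya_never_contributes(self):
        assert readthrough_distance(classified("r", "g", "POLYA", -200, 400, 30)) is None


class TestComputeTw:
    def test_odd_median(self):
        win = compute_tw("g", 5000, "+", [60, 80, 100], min_reads=3)
        assert win.tw == 80 and win.twe == 5080

    def test_even_median_is_mean_of_central_pair(self):
        win = compute_tw("g", 5000, "+", [60, 80, 100, 140], min_reads=4)
        assert win.tw == 90

    def test_below_threshold_gives_none(self):
        assert compute_tw("g", 5000, "+", list(range(60, 200, 10))) is None

    def test_minus_strand_twe_shifts_upstream(self):
        win = compute_tw("g", 9000, "-", [100, 120, 140], min_reads=3)
        assert win.twe == 9000 - 120

    def test_twe_rounds_half_up(self):
        win = compute_tw("g", 5000, "+", [100, 101, 102, 103], min_reads=4)
        assert win.tw == 101.5 and win.twe == 5102

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        d = list(rng.integers(51, 500, 25))
        a = compute_tw("g", 5000, "+", d)
        b = compute_tw("g", 5000, "+", list(reversed(d)))
        assert a.tw == b.tw and a.twe == b.twe

    def test_median_bounded_by_max(self):
        rng = np.random.default_rng(4)
        d = list(51 + rng.exponential(110, 40).astype(int))
        win = compute_tw("g", 0, "+", d)
        assert win.tw <= max(d)


class TestTwTable:
    def test_gene_below_threshold_absent(self):
        genes = GeneIndex([GeneModel("g", "c", "+", 0, 5000)])
        reads = [classified(f"r{i}", "g", "READTHROUGH", -200, 100 + i)
                 for i in range(14)]
        assert len(tw_table(reads, {"g": 5000}, genes)) == 0
        reads.append(classified("r14", "g", "CLEAVED_3P", 10, 300))
        assert len(tw_table(reads, {"g": 5000}, genes)) == 1

    def test_cohort_median_recovery(self):
        cfg = SimConfig(seed=21, n_genes=40, reads_per_gene=120,
                        error_rate=0.0, jitter_sd=0.0)
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            paths = simulate_dataset(cfg, d)
            rc = RunConfig(bam=str(paths["sam"]), annotation=str(paths["gff3"]),
                           outdir=d)
            res = run_pipeline(rc, write_outputs=False)
        assert abs(res.tw["tw"].median() - 160) <= 10

    def test_replicate_tw_correlation(self):
        # same genes, independent read draws; per-gene medians spread with a
        # broad long-tailed law matching real between-gene TW variation
        import tempfile
        tws = []
        for read_seed in (101, 202):
            cfg = SimConfig(seed=33, read_seed=read_seed, n_genes=40,
                            reads_per_gene=120, error_rate=0.0, jitter_sd=0.0,
                            rt_median_log_sd=0.8)
            with tempfile.TemporaryDirectory() as d:
                paths = simulate_dataset(cfg, d)
                rc = RunConfig(bam=str(paths["sam"]),
                               annotation=str(paths["gff3"]), outdir=d)
                res = run_pipeline(rc, write_outputs=False)
            tws.append(res.tw.set_index("gene_id")["tw"])
        both = pd.concat(tws, axis=1, join="inner")
        assert len(both) >= 20
        r = np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]
        assert r > 0.8


class TestMetaProfile:
    def setup_method(self):
        self.genes = GeneIndex([GeneModel("g", "c", "+", 0, 5000)])
        self.pa = {"g": 5000}

    def test_delta_at_pa_for_cleavage_products(self):
        reads = [classified(f"r{i}", "g", "CLEAVED_3P", 0, 300) for i in range(30)]
        prof = meta_profile(reads, self.pa, self.genes, end_type="5p", window=100)
        assert prof.density[100] == 1.0 and prof.density.sum() == pytest.approx(1.0)

    def test_uniform_ends_give_flat_profile(self):
        rng = np.random.default_rng(6)
        reads = [classified(f"r{i}", "g", "READTHROUGH", -200, int(d3))
                 for i, d3 in enumerate(rng.integers(51, 251, 4000))]
        prof = meta_profile(reads, self.pa, self.genes, end_type="3p", window=250)
        assert prof.density.sum() == pytest.approx(1.0)
        active = prof.density[prof.offsets >= 51]
        expected = 1 / 200
        assert np.all(np.abs(active[:-50] - expected) < 5 * np.sqrt(expected / 4000))

    def test_empty_signal_flagged_all_zero(self):
        prof = meta_profile([], self.pa, self.genes)
        assert prof.n_ends == 0 and prof.density.sum() == 0

    def test_twe_reanchoring_shifts_offsets(self):
        reads = [classified(f"r{i}", "g", "READTHROUGH", -200, 160)
                 for i in range(10)]
        prof = meta_profile(reads, self.pa, self.genes, end_type="3p",
                            window=50, anchors={"g": 5160}, anchor_name="TWE")
        assert prof.density[50] == 1.0  # offset 0 relative to the TWE
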