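import pandas as pd
import pytest

from nanoterm.pipeline import RunConfig, run_pipeline
from nanoterm.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Error-free, jitter-free simulated dataset with tRNA neighbours:
    the ground-truth-recovery workhorse."""
    d = tmp_path_factory.mktemp("clean_sim")
    cfg = SimConfig(seed=7, n_genes=30, reads_per_gene=60, error_rate=0.0,
                    jitter_sd=0.0, trna_fraction=0.2)
    paths = simulate_dataset(cfg, d)
    return cfg, paths


@pytest.fixture(scope="session")
def clean_run(clean_sim):
    cfg, paths = clean_sim
    rc = RunConfig(bam=str(paths["sam"]), annotation=str(paths["gff3"]),
                   outdir=str(paths["sam"].parent / "out"))
    result = run_pipeline(rc)
    truth = pd.read_csv(paths["read_truth"], sep="\t")
    gene_truth = pd.read_csv(paths["gene_truth"], sep="\t")
    return rc, result, truth, gene_truth
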