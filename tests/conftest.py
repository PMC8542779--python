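import logging

import pandas as pd
import pytest

from ribojoint import SimulationConfig, make_demo, simulate_dataset

logging.getLogger("ribojoint").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_scenario():
    """The default recovery scenario: 1000 genes, 4 reps/group, NB phi=0.05,
    tx effects +/-2, TE effects +/-3, base RPKM >= 10."""
    config = SimulationConfig(n_genes=1000, n_reps=4, seed=7)
    annotation, truth, rna, ribo = simulate_dataset(config)
    lengths = pd.Series(
        {m.gene_id: m.total_len for m in annotation}, name="length", dtype=float
    )
    lengths.index.name = "gene_id"
    return config, annotation, truth, rna, ribo, lengths


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """A small packaged demo scenario plus its pipeline config path."""
    outdir = tmp_path_factory.mktemp("demo")
    cfg_path = make_demo(outdir, seed=42, n_genes=150)
    return outdir, cfg_path
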