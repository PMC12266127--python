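import numpy as np
import pandas as pd
import pytest

from methdyn import (
    MethCalls,
    SimConfig,
    simulate_methylome,
    simulate_regulome_and_expression,
)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    # small genome: ~2000 CpGs over 300 one-kb bins, enough for every stage
    return SimConfig(
        seed=5,
        n_chroms=1,
        chrom_length_bp=300_000,
        cpg_spacing_mean_bp=150.0,
        n_genes=200,
    )


@pytest.fixture(scope="session")
def tiny_methylome(tiny_cfg):
    return simulate_methylome(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg, tiny_methylome):
    calls, truth = tiny_methylome
    atac, h3k4me1, genes, expr = simulate_regulome_and_expression(
        tiny_cfg, truth, calls
    )
    return {
        "cfg": tiny_cfg,
        "calls": calls,
        "truth": truth,
        "atac": atac,
        "h3k4me1": h3k4me1,
        "genes": genes,
        "expr": expr,
    }


def make_calls(records, timepoints=None) -> MethCalls:
    """Build a MethCalls from (chrom, pos, sample, n_meth, n_total) tuples."""
    df = pd.DataFrame(
        records, columns=["chrom", "pos", "sample_id", "n_meth", "n_total"]
    )
    return MethCalls(df, timepoints or {})


@pytest.fixture
def rng():
    return np.random.default_rng(42)
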