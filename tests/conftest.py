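import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tfregulon import (ExpressionProfile, GeneModel, RunConfig,
                       SimulationConfig, simulate_study)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_profile(log2fc, genes=None) -> ExpressionProfile:
    """Profile from a plain log2fc vector; responder flag at 2-fold."""
    x = np.asarray(log2fc, dtype=float)
    genes = genes or [f"g{i:04d}" for i in range(len(x))]
    return ExpressionProfile(pd.DataFrame(
        {"log2fc": x, "responder2x": np.abs(x) >= 1.0},
        index=pd.Index(genes, name="gene")))


def make_genes(tss_positions, chrom="chr1", strand="+") -> GeneModel:
    """GeneModel with one TSS per gene at the given positions."""
    n = len(tss_positions)
    return GeneModel(pd.DataFrame({
        "symbol": [f"g{i:04d}" for i in range(n)],
        "chrom": chrom, "strand": strand,
        "tss": np.asarray(tss_positions, dtype=np.int64),
        "quality": 3}))


@pytest.fixture(scope="session")
def default_bundle():
    """One seeded study at the default conditions, shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_bundle):
    from tfregulon import run_study
    b = default_bundle
    return run_study(b.genes, b.peaksets, b.profile, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
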