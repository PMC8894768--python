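import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aleuro.containers import CountMatrix, SimConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=1, n_genes=300, n_proteins=120,
                     n_replicates_per_tissue=3)


@pytest.fixture()
def tiny_counts():
    """Hand-sized paired count matrix at one timepoint (2 blocks)."""
    genes = pd.Index([f"g{i}" for i in range(6)], name="gene")
    counts = pd.DataFrame(
        np.array([[10, 12, 20, 22],
                  [100, 90, 95, 105],
                  [0, 0, 0, 0],
                  [50, 60, 10, 12],
                  [5, 4, 6, 7],
                  [200, 210, 190, 205]]),
        index=genes, columns=["AL_r1", "ST_r1", "AL_r2", "ST_r2"])
    lengths = pd.Series([1000, 2000, 1500, 800, 1200, 900],
                        index=genes, name="length", dtype=float)
    samples = pd.DataFrame({
        "tissue": ["AL", "ST", "AL", "ST"],
        "timepoint": [18, 18, 18, 18],
        "replicate_block": ["b1", "b1", "b2", "b2"],
    }, index=counts.columns)
    return CountMatrix(counts, lengths, samples)


@pytest.fixture()
def flat_profile():
    n = 40
    return pd.DataFrame({
        "position": np.arange(n, dtype=float),
        "intensity": np.where(np.arange(n) < 20, 4.0, 2.0),
        "domain": np.where(np.arange(n) < 20, "engulfment", "other"),
        "saturated": np.zeros(n, dtype=bool),
    })
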