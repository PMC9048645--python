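import numpy as np
import pandas as pd
import pytest

from cernapipe.io import CountMatrix


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3-gene x 6-sample matrix, two groups of three."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.integers(10, 200, size=(3, 6)),
        index=["gA", "gB", "gC"],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("OE" if i < 3 else "NC") for i in range(6)}
    return CountMatrix(counts.astype(np.int64), groups)


@pytest.fixture
def medium_counts() -> CountMatrix:
    """200-gene x 6-sample NB matrix for statistical sanity checks."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.02, size=(200, 6)),
        index=[f"g{i:03d}" for i in range(200)],
        columns=[f"s{i}" for i in range(6)],
    )
    groups = {f"s{i}": ("OE" if i < 3 else "NC") for i in range(6)}
    return CountMatrix(counts.astype(np.int64), groups)


@pytest.fixture
def deg_frame() -> pd.DataFrame:
    """Hand-written DEG table covering all status values."""
    return pd.DataFrame({
        "gene_id": ["u1", "u2", "d1", "n1", "n2"],
        "logFC": [2.5, 1.2, -3.0, 0.4, 1.5],
        "logCPM": [5.0, 6.0, 4.0, 7.0, 3.0],
        "p_value": [1e-6, 1e-4, 1e-8, 0.3, 0.2],
        "fdr": [1e-5, 1e-3, 1e-7, 0.5, 0.4],
        "status": ["up", "up", "down", "ns", "ns"],
    })
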