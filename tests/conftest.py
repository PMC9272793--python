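import numpy as np
import pandas as pd
import pytest

from spacepal.datasets import BlobSpec, make_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_points() -> pd.DataFrame:
    """Three well-separated 60-point blobs; small enough for fast pipeline runs."""
    specs = [
        BlobSpec(center=(0.0, 0.0), spread=0.5, n=60, label="alpha"),
        BlobSpec(center=(10.0, 0.0), spread=0.5, n=60, label="beta"),
        BlobSpec(center=(0.0, 10.0), spread=0.5, n=60, label="gamma"),
    ]
    return make_blobs(specs, seed=7)


@pytest.fixture
def toy_tsv(tmp_path, toy_points):
    path = tmp_path / "points.tsv"
    toy_points.to_csv(path, sep="\t", index=False)
    return path
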