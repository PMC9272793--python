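"""Deterministic synthetic point tables with controlled spatial-overlap structure.

Real inputs are 2-D embeddings (UMAP/t-SNE) of cells or spot coordinates from
a tissue slide; for tests and demos we emulate their clustered geometry with
isotropic Gaussian blobs whose center distances control how much neighboring
clusters overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BlobSpec", "make_blobs", "overlap_ladder", "neighbor_triplet"]


@dataclass(frozen=True)
class BlobSpec:
    """One isotropic Gaussian blob: center, per-axis spread (sd), count, label."""

    center: tuple[float, float]
    spread: float
    n: int
    label: str

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError(f"spread must be positive, got {self.spread}")
        if self.n < 1:
            raise ValueError(f"point count must be >= 1, got {self.n}")


def make_blobs(specs: list[BlobSpec], seed: int) -> pd.DataFrame:
    """Sample the blobs into a point table (columns x, y, cluster).

    Deterministic for a fixed seed and spec list.
    """
    if not specs:
        raise ValueError("need at least one blob spec")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        xy = rng.normal(loc=spec.center, scale=spec.spread, size=(spec.n, 2))
        frames.append(
            pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "cluster": spec.label})
        )
    return pd.concat(frames, ignore_index=True)


def overlap_ladder(
    n_levels: int,
    seed: int,
    n_points: int = 500,
    spread: float = 1.0,
) -> list[pd.DataFrame]:
    """Two equal blobs at decreasing center distance: 10 spreads down to 0.

    Every level reuses the same seed, so only the second blob's center moves
    between levels; this isolates the effect of separation on the spatial
    overlap score.
    """
    if n_levels < 2:
        raise ValueError(f"need at least 2 levels, got {n_levels}")
    distances = np.linspace(10.0 * spread, 0.0, n_levels)
    tables = []
    for dist in distances:
        specs = [
            BlobSpec(center=(0.0, 0.0), spread=spread, n=n_points, label="a"),
            BlobSpec(center=(float(dist), 0.0), spread=spread, n=n_points, label="b"),
        ]
        tables.append(make_blobs(specs, seed))
    return tables


def neighbor_triplet(
    seed: int,
    n_points: int = 400,
    spread: float = 1.0,
) -> pd.DataFrame:
    """Two heavily overlapping blobs plus one distant blob.

    Clusters ``a`` and ``b`` sit half a spread apart (large Jaccard overlap);
    cluster ``c`` sits 20 spreads away (no overlap with either). The canonical
    test case for "overlapping clusters should get the most dissimilar colors".
    """
    specs = [
        BlobSpec(center=(0.0, 0.0), spread=spread, n=n_points, label="a"),
        BlobSpec(center=(0.5 * spread, 0.0), spread=spread, n=n_points, label="b"),
        BlobSpec(center=(20.0 * spread, 0.0), spread=spread, n=n_points, label="c"),
    ]
    return make_blobs(specs, seed)
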