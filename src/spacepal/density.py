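"""Per-cluster 2-D kernel density fields on a shared grid and Jaccard spatial overlap.

The spatial footprint of each cluster is summarized by the set of "hot" grid
points: nodes of a common 100x100 lattice where the cluster's kernel density
exceeds a cutoff derived from a single random permutation of the cluster
labels (the permutation destroys spatial structure, so its density field is a
null reference; the cutoff is a high percentile of that null field). The
Jaccard index between two clusters' hot sets measures how much their
footprints overlap, i.e. how spatially adjacent they are on the plot.

Conventions follow the normal-kernel 2-D density estimator of MASS::kde2d:
axis bandwidths come from the normal-reference rule and the Gaussian kernel's
standard deviation is bandwidth/4. Density fields are evaluated on one grid
spanning the bounding box of *all* points, so hot sets from different
clusters live on the same lattice and set overlap is well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "HotSet",
    "canonical_clusters",
    "validate_points",
    "make_grid",
    "nrd_bandwidth",
    "fit_kde",
    "cluster_fields",
    "permutation_cutoffs",
    "hot_sets",
    "overlap_matrix",
]

# bandwidth floor for degenerate clusters, as a fraction of the global axis range
_BANDWIDTH_FLOOR_FRAC = 1e-6
# half-width used to pad an axis whose observed range is exactly zero
_ZERO_RANGE_PAD = 0.5

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Grid:
    """Shared evaluation lattice: strictly increasing x and y node coordinates."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("x", self.x), ("y", self.y)):
            if v.ndim != 1 or v.size < 2 or not np.all(np.diff(v) > 0):
                raise ValueError(f"grid {name} must be 1-D, >=2 nodes, strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.x.size, self.y.size)


@dataclass(frozen=True)
class HotSet:
    """Boolean mask of hot grid nodes for one cluster, plus the cutoff used."""

    mask: np.ndarray  # (nx, ny) bool
    cutoff: float

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> list[tuple[int, int]]:
        """Hot nodes as (i, j) index pairs into (grid.x, grid.y)."""
        ii, jj = np.nonzero(self.mask)
        return list(zip(ii.tolist(), jj.tolist()))


def canonical_clusters(labels: Sequence[Hashable]) -> list:
    """Unique cluster labels in canonical order (lexicographic on text form)."""
    return sorted(pd.unique(np.asarray(labels, dtype=object)), key=str)


def validate_points(points: pd.DataFrame) -> pd.DataFrame:
    """Check a point table (columns x, y, cluster): finite coordinates, no missing labels."""
    for col in ("x", "y", "cluster"):
        if col not in points.columns:
            raise ValueError(
                f"point table is missing column {col!r}; has {list(points.columns)}"
            )
    if len(points) == 0:
        raise ValueError("point table is empty")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = np.nonzero(~np.isfinite(xy).all(axis=1))[0]
        raise ValueError(
            f"{bad.size} rows have missing or non-finite coordinates "
            f"(first rows: {bad[:5].tolist()})"
        )
    if points["cluster"].isna().any():
        n_bad = int(points["cluster"].isna().sum())
        raise ValueError(f"{n_bad} rows have missing cluster labels")
    return points


def _axis_nodes(values: np.ndarray, n: int, axis_name: str) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        warnings.warn(
            f"zero range on {axis_name} axis; padding by +/-{_ZERO_RANGE_PAD}",
            stacklevel=3,
        )
        lo, hi = lo - _ZERO_RANGE_PAD, hi + _ZERO_RANGE_PAD
    return np.linspace(lo, hi, n)


def make_grid(points: pd.DataFrame, n: int = 100) -> Grid:
    """Equally spaced n-node lattice per axis over the bounding box of all points.

    The extent pools every cluster, so the same grid serves every cluster's
    density field. A degenerate (zero-range) axis is padded and warned about.
    """
    if n < 2:
        raise ValueError(f"grid size must be >= 2, got {n}")
    validate_points(points)
    return Grid(
        x=_axis_nodes(points["x"].to_numpy(dtype=float), n, "x"),
        y=_axis_nodes(points["y"].to_numpy(dtype=float), n, "y"),
    )


def nrd_bandwidth(values: np.ndarray, floor: float) -> float:
    """Normal-reference-rule bandwidth: h = 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    The leading factor 4 matches the convention in which the Gaussian kernel's
    standard deviation is h/4. If IQR = 0 the spread estimate falls back to the
    sample sd; if that is also 0 (or n < 2) the positive ``floor`` is returned
    so single-point or zero-variance clusters never yield a degenerate kernel.
    """
    if floor <= 0:
        raise ValueError("bandwidth floor must be positive")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return floor
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75.0, 25.0])))
    spread = sd if iqr == 0.0 else min(sd, iqr / 1.34)
    if spread <= 0.0:
        return floor
    return 4.0 * 1.06 * spread * v.size ** (-0.2)


def fit_kde(
    x: np.ndarray, y: np.ndarray, grid: Grid, hx: float, hy: float
) -> np.ndarray:
    """Product-Gaussian kernel density field on the grid, by direct summation.

    ``field[i, j]`` is the density at ``(grid.x[i], grid.y[j])``:
    ``(1/n) sum_k phi((gx-x_k)/sx) phi((gy-y_k)/sy) / (sx*sy)`` with
    ``sx = hx/4``, ``sy = hy/4`` and ``phi`` the standard normal pdf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("x and y must be equal-length, non-empty")
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    sx, sy = hx / 4.0, hy / 4.0
    tx = (grid.x[:, None] - x[None, :]) / sx  # (nx, n)
    ty = (grid.y[:, None] - y[None, :]) / sy  # (ny, n)
    kx = np.exp(-0.5 * tx * tx) / (_SQRT_2PI * sx)
    ky = np.exp(-0.5 * ty * ty) / (_SQRT_2PI * sy)
    return kx @ ky.T / x.size


def _bandwidths_for(
    x: np.ndarray, y: np.ndarray, grid: Grid
) -> tuple[float, float]:
    floor_x = _BANDWIDTH_FLOOR_FRAC * (grid.x[-1] - grid.x[0])
    floor_y = _BANDWIDTH_FLOOR_FRAC * (grid.y[-1] - grid.y[0])
    return nrd_bandwidth(x, floor_x), nrd_bandwidth(y, floor_y)


def cluster_fields(
    points: pd.DataFrame, grid: Grid
) -> tuple[dict, dict]:
    """Fit one density field per cluster on the shared grid.

    Returns ``(fields, bandwidths)`` keyed by cluster label in canonical
    order; ``bandwidths[label]`` is the (h_x, h_y) pair used.
    """
    validate_points(points)
    fields: dict = {}
    bandwidths: dict = {}
    labels = points["cluster"].to_numpy(dtype=object)
    for lab in canonical_clusters(labels):
        sel = labels == lab
        cx = points["x"].to_numpy(dtype=float)[sel]
        cy = points["y"].to_numpy(dtype=float)[sel]
        hx, hy = _bandwidths_for(cx, cy, grid)
        fields[lab] = fit_kde(cx, cy, grid, hx, hy)
        bandwidths[lab] = (hx, hy)
    return fields, bandwidths


def permutation_cutoffs(
    points: pd.DataFrame,
    grid: Grid,
    rng: np.random.Generator,
    percentile: float = 95.0,
) -> dict:
    """Per-cluster hot-point cutoffs from one random permutation of the labels.

    The label vector is permuted once (coordinates fixed, cluster sizes
    preserved), every permuted cluster's density field is refitted — with
    bandwidths recomputed from the permuted membership — and each cluster's
    cutoff is the given percentile (default 95) of its permuted field's grid
    values, linearly interpolated between order statistics.
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    validate_points(points)
    labels = points["cluster"].to_numpy(dtype=object)
    permuted = labels[rng.permutation(labels.size)]
    xs = points["x"].to_numpy(dtype=float)
    ys = points["y"].to_numpy(dtype=float)
    cutoffs: dict = {}
    for lab in canonical_clusters(labels):
        sel = permuted == lab
        cx, cy = xs[sel], ys[sel]
        hx, hy = _bandwidths_for(cx, cy, grid)
        field = fit_kde(cx, cy, grid, hx, hy)
        cutoffs[lab] = float(np.percentile(field, percentile))
    return cutoffs


def hot_sets(fields: Mapping, cutoffs: Mapping) -> dict:
    """Threshold each cluster's field at its cutoff (strictly greater than).

    Empty hot sets are permitted (the cluster has no spatial footprint above
    its null reference) but warned about.
    """
    if set(fields) != set(cutoffs):
        raise ValueError("fields and cutoffs must share cluster keys")
    out: dict = {}
    for lab in sorted(fields, key=str):
        mask = fields[lab] > cutoffs[lab]
        if not mask.any():
            warnings.warn(f"cluster {lab!r} has an empty hot-grid-point set", stacklevel=2)
        out[lab] = HotSet(mask=mask, cutoff=float(cutoffs[lab]))
    return out


def overlap_matrix(hotsets: Mapping) -> pd.DataFrame:
    """Jaccard index J(a,b) = |S_a ∩ S_b| / |S_a ∪ S_b| between cluster hot sets.

    Returned as a symmetric DataFrame indexed by cluster label in canonical
    order, entries in [0, 1]. When both sets are empty the ratio is 0/0;
    it is defined here as 0 (no evidence of adjacency) with a warning.
    """
    labels = sorted(hotsets, key=str)
    c = len(labels)
    j = np.zeros((c, c))
    warned = False
    for a in range(c):
        ma = hotsets[labels[a]].mask
        for b in range(a, c):
            mb = hotsets[labels[b]].mask
            union = int(np.count_nonzero(ma | mb))
            if union == 0:
                if not warned:
                    warnings.warn(
                        "both hot sets empty for at least one cluster pair; "
                        "their Jaccard index is defined as 0",
                        stacklevel=2,
                    )
                    warned = True
                val = 0.0
            else:
                val = int(np.count_nonzero(ma & mb)) / union
            j[a, b] = j[b, a] = val
    return pd.DataFrame(j, index=labels, columns=labels)
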