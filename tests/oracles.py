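"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package: scores are
triple loops, densities are per-node direct sums, optima come from exhaustive
enumeration. They are slow and simple on purpose.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np


def score_loop(j: np.ndarray, d: np.ndarray, assignment) -> float:
    """Color score by explicit loop over unordered cluster pairs."""
    c = len(assignment)
    total = 0.0
    for a in range(c):
        for b in range(a + 1, c):
            total += j[a, b] * d[assignment[a], assignment[b]]
    return total


def exhaustive_optimum(j: np.ndarray, d: np.ndarray, m: int) -> float:
    """Best color score over all injective cluster -> palette maps."""
    c = j.shape[0]
    return max(score_loop(j, d, p) for p in permutations(range(m), c))


def kde_direct_sum(x, y, grid_x, grid_y, hx: float, hy: float) -> np.ndarray:
    """Density field computed node by node with math.exp sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = hx / 4.0, hy / 4.0
    n = x.size
    norm = 1.0 / (2.0 * math.pi * sx * sy * n)
    out = np.empty((len(grid_x), len(grid_y)))
    for i, gx in enumerate(grid_x):
        for jj, gy in enumerate(grid_y):
            s = 0.0
            for k in range(n):
                tx = (gx - x[k]) / sx
                ty = (gy - y[k]) / sy
                s += math.exp(-0.5 * (tx * tx + ty * ty))
            out[i, jj] = s * norm
    return out


def kde_direct_sum_fast(x, y, grid_x, grid_y, hx: float, hy: float) -> np.ndarray:
    """Node-by-node direct sum, vectorized only over the sample points.

    Still structurally independent of the package's outer-product evaluation;
    usable on the full 100x100 grid.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = hx / 4.0, hy / 4.0
    norm = 1.0 / (2.0 * np.pi * sx * sy * x.size)
    out = np.empty((len(grid_x), len(grid_y)))
    for i, gx in enumerate(grid_x):
        tx = (gx - x) / sx
        ex = np.exp(-0.5 * tx * tx)
        for jj, gy in enumerate(grid_y):
            ty = (gy - y) / sy
            out[i, jj] = float(np.sum(ex * np.exp(-0.5 * ty * ty))) * norm
    return out


def random_instance(c: int, m: int, rng: np.random.Generator):
    """Random symmetric overlap matrix and random-palette distance matrix."""
    from spacepal.colors import distance_matrix, parse_hex

    j = rng.uniform(0.0, 1.0, size=(c, c))
    j = (j + j.T) / 2.0
    np.fill_diagonal(j, 1.0)
    hexes = ["#%02X%02X%02X" % tuple(rng.integers(0, 256, size=3)) for _ in range(m)]
    d = distance_matrix([parse_hex(h) for h in hexes])
    return j, d
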