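"""Palette assignment optimization: overlap-weighted color score, restarts, exchanges.

The decision variable is an injective map from clusters to palette colors
(a permutation when the palette has exactly as many colors as clusters).
The objective — the color score — is the sum over unordered cluster pairs of
J(a,b) * D(P_a, P_b): spatial overlap times assigned-color dissimilarity.
Maximizing it pushes the most dissimilar colors onto the most spatially
entangled cluster pairs. (The equivalent ordered double sum over all (a, b)
is exactly twice this value, so the argmax is unchanged.)

The search is best-of-N random restarts followed by stochastic hill climbing
over pairwise color exchanges: each proposal swaps the colors of two random
clusters (or, when the palette is larger than the cluster count, swaps one
cluster's color with an unused pool color); a proposal is kept only if it
strictly increases the score, and the search stops early after a run of
consecutive non-improving proposals.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field as dc_field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .colors import ChannelWeights, Color, CvdMode, distance_matrix, parse_hex
from .density import (
    canonical_clusters,
    cluster_fields,
    hot_sets,
    make_grid,
    overlap_matrix,
    permutation_cutoffs,
    validate_points,
)

__all__ = [
    "SearchConfig",
    "PaletteResult",
    "color_score",
    "random_restart",
    "exchange_refinement",
    "optimize_palette",
]

ScoreTrace = list  # of (proposal index, best score so far)


@dataclass(frozen=True)
class SearchConfig:
    """Search budget: restarts, exchange proposals, and early-stop patience."""

    n_restarts: int = 1000
    max_exchanges: int = 2000
    patience: int = 500

    def __post_init__(self) -> None:
        for name in ("n_restarts", "max_exchanges", "patience"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.patience > self.max_exchanges:
            raise ValueError(
                f"patience ({self.patience}) must not exceed "
                f"max_exchanges ({self.max_exchanges})"
            )


def color_score(j: np.ndarray, d: np.ndarray, assignment: np.ndarray) -> float:
    """Overlap-weighted sum of assigned-color distances over unordered cluster pairs.

    ``assignment[k]`` is the palette index of cluster ``k``. The diagonal
    contributes nothing because D has a zero diagonal.
    """
    j = np.asarray(j, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    c = assignment.size
    if j.shape != (c, c):
        raise ValueError(f"overlap matrix shape {j.shape} != ({c}, {c})")
    if assignment.size and assignment.max() >= d.shape[0]:
        raise ValueError("assignment refers to palette indices outside D")
    sub = d[np.ix_(assignment, assignment)]
    return 0.5 * float(np.sum(j * sub))


def random_restart(
    j: np.ndarray,
    d: np.ndarray,
    config: SearchConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Best of ``n_restarts`` uniformly random injective assignments.

    Ties keep the earliest drawn assignment. Palette size M (= D's dimension)
    must be at least the cluster count C.
    """
    c = np.asarray(j).shape[0]
    m = np.asarray(d).shape[0]
    if m < c:
        raise ValueError(
            f"palette must have at least as many colors as clusters (M={m} < C={c})"
        )
    best_assign: np.ndarray | None = None
    best_score = -np.inf
    for _ in range(config.n_restarts):
        cand = rng.permutation(m)[:c]
        s = color_score(j, d, cand)
        if s > best_score:
            best_score, best_assign = s, cand
    assert best_assign is not None
    return best_assign, best_score


def exchange_refinement(
    start: np.ndarray,
    j: np.ndarray,
    d: np.ndarray,
    config: SearchConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, ScoreTrace]:
    """Hill-climb from ``start`` by random pairwise color exchanges.

    Each proposal picks uniformly among all swap candidates: the C(C-1)/2
    unordered cluster pairs plus, when the palette is larger than the cluster
    count, the C x |pool| (cluster, unused color) pairs. A proposal is
    accepted only if it strictly increases the score; equal-score proposals
    are rejected and count toward the patience counter, which resets on every
    acceptance. Returns ``(assignment, score, trace)`` where the trace lists
    (proposal index, best score so far) starting at index 0.
    """
    assign = np.asarray(start, dtype=int).copy()
    c = assign.size
    m = np.asarray(d).shape[0]
    pool = sorted(set(range(m)) - set(assign.tolist()))
    best = color_score(j, d, assign)
    trace: ScoreTrace = [(0, best)]
    pairs = list(combinations(range(c), 2))
    n_pairs = len(pairs)
    rejects = 0
    for t in range(1, config.max_exchanges + 1):
        n_cand = n_pairs + c * len(pool)
        if n_cand == 0:  # single cluster, no spare colors: nothing to propose
            break
        k = int(rng.integers(n_cand))
        if k < n_pairs:
            a, b = pairs[k]
            assign[a], assign[b] = assign[b], assign[a]
            s = color_score(j, d, assign)
            if s > best:
                best = s
                rejects = 0
            else:
                assign[a], assign[b] = assign[b], assign[a]
                rejects += 1
        else:
            k -= n_pairs
            ci, pi = divmod(k, len(pool))
            old = assign[ci]
            assign[ci] = pool[pi]
            s = color_score(j, d, assign)
            if s > best:
                pool[pi] = int(old)
                best = s
                rejects = 0
            else:
                assign[ci] = old
                rejects += 1
        trace.append((t, best))
        if rejects >= config.patience:
            break
    return assign, best, trace


@dataclass
class PaletteResult:
    """Everything the end-to-end optimization produced.

    ``mapping`` is the user-facing output: each cluster label mapped to one of
    the input hex strings (byte-for-byte), injectively.
    """

    mapping: dict
    score: float
    restart_score: float
    assignment: np.ndarray
    overlap: pd.DataFrame
    cutoffs: dict
    trace: ScoreTrace = dc_field(repr=False)
    config: SearchConfig = SearchConfig()
    seed: int | None = None


@contextmanager
def _stage(name: str):
    """Label errors with the pipeline stage that raised them."""
    try:
        yield
    except ValueError as exc:
        raise ValueError(f"[{name}] {exc}") from exc


def optimize_palette(
    points: pd.DataFrame,
    palette: Sequence[str],
    *,
    weights: ChannelWeights | None = None,
    cvd: CvdMode | None = None,
    config: SearchConfig | None = None,
    grid_size: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> PaletteResult:
    """Run the full pipeline: densities -> hot sets -> overlap -> palette search.

    Parameters
    ----------
    points
        Point table with columns ``x``, ``y`` (finite coordinates: a 2-D
        embedding or spatial spot positions) and ``cluster`` (categorical
        label per point).
    palette
        Candidate colors as hex strings (#RRGGBB); at least as many colors
        as there are clusters.
    weights, cvd
        Channel weights and color-vision-deficiency mode for the color
        distance; defaults are unweighted RGB with no CVD simulation.
    config
        Search budget; defaults to 1000 restarts, 2000 exchange proposals,
        patience 500.
    grid_size, percentile
        Density-lattice resolution per axis (default 100) and the percentile
        of the permuted-label field used as each cluster's hot cutoff
        (default 95).
    seed
        Seeds one random stream that drives, in order, the label permutation,
        the restarts, and the exchange proposals, so a seed fixes the run.

    Returns
    -------
    PaletteResult
        With ``mapping`` the injective cluster -> input-hex assignment.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(seed)

    with _stage("input validation"):
        validate_points(points)
        parsed: list[Color] = [parse_hex(h, index=i) for i, h in enumerate(palette)]
        labels = canonical_clusters(points["cluster"].to_numpy(dtype=object))
        if len(labels) < 2:
            warnings.warn(
                "only one cluster present; any palette color is optimal",
                stacklevel=2,
            )
        if len(parsed) < len(labels):
            raise ValueError(
                "palette must have at least as many colors as clusters "
                f"(M={len(parsed)} < C={len(labels)})"
            )

    with _stage("density fitting"):
        grid = make_grid(points, n=grid_size)
        fields, _ = cluster_fields(points, grid)

    with _stage("permutation cutoffs"):
        cutoffs = permutation_cutoffs(points, grid, rng, percentile=percentile)

    with _stage("spatial overlap"):
        hots = hot_sets(fields, cutoffs)
        overlap = overlap_matrix(hots)
        j = overlap.to_numpy()

    with _stage("color distances"):
        d = distance_matrix(parsed, w=weights, mode=cvd)

    with _stage("palette search"):
        start, restart_score = random_restart(j, d, config, rng)
        assign, score, trace = exchange_refinement(start, j, d, config, rng)

    mapping = {
        lab: palette[assign[i]] for i, lab in enumerate(labels)
    }
    return PaletteResult(
        mapping=mapping,
        score=score,
        restart_score=restart_score,
        assignment=assign,
        overlap=overlap,
        cutoffs=cutoffs,
        trace=trace,
        config=config,
        seed=seed,
    )
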