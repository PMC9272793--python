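# Methods

## Model and procedure

spacepal treats palette assignment as a combinatorial optimization problem on
two precomputed matrices: a C×C spatial-overlap matrix J between clusters and
an M×M dissimilarity matrix D between palette colors (M ≥ C). The objective,
the *color score* of an injective assignment P (cluster k → palette color
P_k), is

    score(P) = Σ_{a<b} J_{a,b} · D_{P_a, P_b}.

Summing over unordered pairs halves the equivalent ordered double sum (the
diagonal contributes nothing since D has a zero diagonal); the factor 2 is
constant over assignments, so the argmax is unchanged. Maximizing the score
pushes large color distances onto cluster pairs with large spatial overlap.

### Spatial overlap J

Each cluster's spatial footprint is estimated with a product-Gaussian kernel
density evaluated by direct summation on a shared lattice:

- **Grid.** 100 nodes per axis (configurable, ≥10 via the CLI), equally
  spaced over the bounding box of *all* points. A single global grid is a
  forcing constraint: Jaccard overlap between hot-node sets is only defined
  on a common lattice. An axis with zero observed range is padded by ±0.5
  coordinate units with a warning.
- **Bandwidths.** Per cluster and per axis, the normal-reference rule
  h = 4 · 1.06 · min(sd, IQR/1.34) · n^(−1/5), with the kernel standard
  deviation h/4 (the convention of the classic 2-D KDE in MASS::kde2d, whose
  output our fields match to machine precision). IQR uses linear
  interpolation between order statistics. If IQR = 0 the spread estimate
  falls back to sd; if sd is also 0, or the cluster has a single point, a
  floor of 1e−6 × (global axis range) keeps the kernel non-degenerate, so
  tiny clusters never crash a run.
- **Hot cutoffs.** The cluster labels are permuted once (coordinates fixed,
  cluster sizes preserved), densities are refitted per permuted cluster with
  bandwidths recomputed from the permuted membership, and each cluster's
  cutoff is the 95th percentile (linear interpolation) of its permuted
  field's 10 000 grid values. The permutation destroys spatial structure, so
  the cutoff asks: "how dense can this many points look by chance anywhere
  on the plot?" Nodes with true density *strictly greater* than the cutoff
  form the hot set. Because only one permutation is drawn, cutoffs — and
  hence hot sets — vary across seeds; the seed is exposed so every run is
  reproducible.
- **Jaccard.** J_{a,b} = |S_a ∩ S_b| / |S_a ∪ S_b| over hot-node sets.
  J is defined as 0 when both sets are empty (0/0 otherwise; an empty hot
  set means no footprint above the null, i.e. no evidence of adjacency), and
  both empty hot sets and the 0/0 case are warned about.

### Color dissimilarity D

Colors are parsed from #RRGGBB (or #RGB) hex into channels on [0, 1]
(byte/255 exactly; only relative distances matter to the argmax, so the
channel scale is a free choice). D_{e,f} is the weighted Euclidean distance
√(Σ_c w_c (e_c − f_c)²) with nonnegative channel weights, default (1, 1, 1).
Scaling all weights by k scales every distance by √k and therefore leaves
the optimal assignment set unchanged.

For colorblind-friendly output the palette can first be passed through a
color-vision-deficiency simulation: the severity-parameterized 3×3 matrices
of Machado, Oliveira & Fernandes (2009) for protan, deutan and tritan
deficiencies, tabulated at severity steps of 0.1 and linearly interpolated
between steps. The matrices act in linear-light RGB, so channels are sRGB
gamma-decoded before and re-encoded after the transform, with clipping to
[0, 1]. Severity 0 (or kind "none") is exactly the identity; because every
tabulated row sums to 1, neutral grays are fixed points of the transform.
Distances are then computed between the transformed colors. Duplicate
palette colors are allowed (the off-diagonal zero is warned about, and the
optimizer simply avoids spending the pair on overlapping clusters).

### Search

The optimizer draws `n_restarts` (default 1000) uniformly random injective
assignments and keeps the best (earliest on ties), then refines it with up to
`max_exchanges` (default 2000) random exchange proposals. Each proposal picks
uniformly among all swap candidates — the C(C−1)/2 unordered cluster pairs
plus, when M > C, the C·|pool| (cluster, unused color) pairs, so spare
palette colors can enter the assignment. A proposal is accepted only if it
*strictly* increases the score; equal-score proposals are rejected and count
toward a patience counter (default 500) that resets on every acceptance and
stops the search when exhausted. The acceptance rule makes the best-score
trace non-decreasing by construction, and the returned score can never fall
below the restart score.

One seeded generator drives, in order: the label permutation, the restarts,
and the exchange proposals. A single seed therefore fixes the entire run,
down to byte-identical output files.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid size | 100 | density lattice nodes per axis (shared by all clusters) |
| percentile | 95 | permuted-field percentile used as the hot cutoff |
| restarts | 1000 | random initial assignments drawn |
| exchanges | 2000 | maximum exchange proposals during refinement |
| patience | 500 | consecutive non-improving proposals before early stop |
| weights | (1, 1, 1) | per-channel weights in the RGB distance |
| CVD kind / severity | none / 1.0 | deficiency simulation applied before distances |
| seed | 0 | seeds the single random stream for the whole run |

## Synthetic data

The generator produces isotropic Gaussian blobs (center, spread, count,
label); anisotropy would add nothing to the properties under test. Two
built-in arrangements drive the test suite and the acceptance script:

- `overlap_ladder`: two 500-point blobs whose center distance shrinks from
  10 spreads to 0 across levels, with identical noise at every level, so the
  Jaccard overlap isolates the effect of separation — 0 when far apart and
  rising toward 1 as the centers coincide.
- `neighbor_triplet`: two blobs half a spread apart plus one 20 spreads
  away — the minimal instance of "overlapping clusters must get the most
  dissimilar colors". With the palette {black, 50% gray, white}, black–white
  is the unique maximum-distance pair (√3 vs ≈0.87), so the optimum is
  identifiable by enumerating all six assignments.

These fixtures emulate the clustered geometry of real embeddings, not their
full character: real UMAPs have curved, anisotropic, variable-density
clusters, uneven cluster sizes, and many more clusters than colors that are
visually distinct. Passing tests demonstrate that the pipeline measures
spatial adjacency correctly and optimizes the stated objective on such
geometry — not that any fixed palette is large enough for a given dataset,
nor that RGB distance matches perceived distinctness in general.

## Numerical choices

- Density fields are evaluated by exact direct summation (an outer-product
  matmul per cluster), not FFT binning: at 100×100 nodes this costs
  milliseconds and agrees with a brute-force oracle to ~1e−15 relative
  error, which keeps the test oracles trivial.
- Percentiles (IQR and cutoffs) use linear interpolation between order
  statistics throughout.
- Hotness uses strict inequality (density > cutoff).
- Restart ties keep the earliest draw; exchange proposals accept only strict
  improvements, so plateaus terminate via patience rather than cycling.
- Cluster order everywhere (matrices, output rows) is lexicographic on the
  label's text form — stable across runs and label types.
- Degenerate inputs: one-point clusters get a single-kernel field via the
  bandwidth floor; zero-range axes are padded; empty hot sets and all-empty
  Jaccard pairs are warned, never fatal.

## Design choices that were genuinely open

- **Global vs per-cluster grid extent:** per-cluster extents would make hot
  sets incomparable, so the shared global lattice is the only choice that
  makes set overlap meaningful. Density values at a cluster's fringe are
  lower than a tight per-cluster fit would give; the permutation cutoff is
  computed on the same lattice, so the comparison stays internally
  consistent.
- **CVD method:** the Machado matrices are the standard tabulated choice;
  other simulations (e.g. Brettel-style dichromat projections) would change
  distances numerically but not the pipeline. Severity interpolation follows
  the published table's intent.
- **M > C palettes:** handled by a color pool with cluster↔pool swap
  proposals weighted by pool size, so unused colors can displace assigned
  ones. With M = C this reduces exactly to permutation search.
- **Weighted-distance form:** weights multiply squared channel differences
  inside the square root — the standard weighted Euclidean metric, chosen so
  uniform weight scaling is a monotone transform of all distances.

## Problem sizes

The test suite and the acceptance script run on synthetic instances chosen
to make exhaustive verification possible: optimizer checks use 3–6 clusters
(≤720 assignments to enumerate, 20 instances), KDE checks use ≤200-point
clusters on the full 100×100 grid (10 clusters), trace monotonicity uses a
10-cluster blob grid over 50 seeds, and the overlap ladder uses two 500-point
blobs at 5 separations. The full acceptance run completes in a few seconds.

## Known limitations

- The color score is a sum, so with many clusters a few high-overlap pairs
  can dominate and leave low-overlap pairs with similar colors; there is no
  minimum-distance guarantee per pair.
- Hill climbing with restarts is not exact for large C; it provably attains
  the enumerated optimum ≥95% of the time on small instances, but offers no
  such guarantee at C in the tens.
- RGB Euclidean distance (even channel-weighted) is not perceptually
  uniform; the method optimizes the stated metric, which is an imperfect
  proxy for perceived distinctness.
- One label permutation defines the cutoffs, so hot sets are seed-dependent;
  averaging several permutations would stabilize them but is deliberately
  not done to keep the published procedure.
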