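# spacepal

Spatially aware color-palette assignment for single-cell and spatial
transcriptomics visualization.

## The problem

Cluster plots of single-cell data (UMAP/t-SNE embeddings) and spatial
transcriptomics slides (e.g. 10x Visium spot maps) routinely show tens of
clusters, each in its own color. Standard plotting layers assign palette
colors alphabetically or at random, so spatially neighboring clusters often
end up with colors the eye cannot tell apart, blurring cluster boundaries and
suggesting spurious structure. spacepal fixes the *assignment*, not the
palette: given the 2-D coordinates, a cluster label per point, and a
user-chosen palette, it detects which cluster pairs actually touch on the
plot and permutes the palette so those pairs receive maximally dissimilar
colors.

## The method

1. **Density fields.** For each cluster, a 2-D Gaussian kernel density is
   fitted on a shared 100×100 lattice spanning the bounding box of all
   points. Bandwidths follow the normal-reference rule
   h = 4·1.06·min(sd, IQR/1.34)·n^(−1/5) per axis, with kernel sd = h/4.
2. **Hot grid points.** Cluster labels are randomly permuted once and the
   densities refitted; each cluster's cutoff is the 95th percentile of its
   permuted-label field. Grid nodes whose true density exceeds the cutoff are
   the cluster's "hot" set S_k — its spatial footprint.
3. **Spatial overlap.** For clusters a, b the overlap score is the Jaccard
   index J_{a,b} = |S_a ∩ S_b| / |S_a ∪ S_b|.
4. **Color dissimilarity.** For palette colors e, f, D_{e,f} is the
   (optionally channel-weighted) Euclidean distance between their RGB
   triples — after an optional color-vision-deficiency transform (Machado et
   al. 2009 matrices) for colorblind-friendly output.
5. **Assignment search.** With P_k the color assigned to cluster k, the
   color score Σ_{a<b} J_{a,b}·D_{P_a,P_b} is maximized over injective
   assignments by best-of-1000 random restarts followed by up to 2000 random
   pairwise color exchanges, keeping only strict improvements and stopping
   early after 500 consecutive non-improving proposals.

See `docs/methods.md` for assumptions, parameter details and limitations.

## Worked example

Three Gaussian clusters: `a` and `b` heavily overlapping, `c` far away, with
the palette {black, 50% gray, white}:

```python
import spacepal as sp

pts = sp.neighbor_triplet(seed=0)      # columns x, y, cluster
pts.to_csv("demo.tsv", sep="\t", index=False)
```

```sh
spacepal --input demo.tsv --palette "#000000,#808080,#FFFFFF" --seed 1 --verbose
```

prints (log on stderr, mapping on stdout):

```
INFO Jaccard overlap matrix:
      a     b    c
a  1.00  0.66  0.0
b  0.66  1.00  0.0
c  0.00  0.00  1.0
INFO permutation cutoffs: {'a': '0.02097', 'b': '0.01978', 'c': '0.02036'}
INFO best restart score: 1.14246
INFO final score: 1.14246
INFO exchange proposals evaluated: 500
cluster	hex
a	#FFFFFF
b	#000000
c	#808080
```

The overlapping pair (J = 0.66) gets the two most dissimilar colors, black
and white (the score 1.14 is 0.66·√3); the isolated cluster takes the gray.
The mapping is written as TSV with `--output`, and `--report` adds a JSON
record of the score trace, overlap matrix, cutoffs, config and seed. The same
mapping is available in Python via `sp.optimize_palette(pts, palette,
seed=1).mapping` and can be fed to any plotting layer, e.g.
`scale_color_manual(values=...)` in ggplot2 or a matplotlib color lookup.

Key CLI flags: `--weights r,g,b` (channel weights), `--cvd
{none,protan,deutan,tritan}` with `--cvd-severity`, `--grid-size`,
`--percentile`, `--restarts`, `--exchanges`, `--patience`, `--seed`.

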