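import math

import numpy as np
import pandas as pd
import pytest

from oracles import kde_direct_sum
from spacepal.datasets import BlobSpec, make_blobs
from spacepal.density import (
    Grid,
    canonical_clusters,
    cluster_fields,
    fit_kde,
    hot_sets,
    make_grid,
    nrd_bandwidth,
    overlap_matrix,
    permutation_cutoffs,
    validate_points,
)


def _table(x, y, cluster):
    return pd.DataFrame({"x": x, "y": y, "cluster": cluster})


class TestGrid:
    def test_equally_spaced_over_pooled_bounding_box(self):
        pts = _table(np.arange(100.0), np.arange(100.0), ["a"] * 50 + ["b"] * 50)
        grid = make_grid(pts, n=100)
        assert np.allclose(grid.x, np.arange(100.0))
        assert np.allclose(grid.y, np.arange(100.0))

    def test_grid_ignores_cluster_labels(self):
        xy = np.linspace(-3, 5, 40)
        g1 = make_grid(_table(xy, xy, ["a"] * 40), n=50)
        g2 = make_grid(_table(xy, xy, ["a", "b"] * 20), n=50)
        assert np.array_equal(g1.x, g2.x) and np.array_equal(g1.y, g2.y)

    def test_zero_range_axis_padded_with_warning(self):
        pts = _table([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], list("abc"))
        with pytest.warns(UserWarning, match="zero range"):
            grid = make_grid(pts, n=10)
        assert grid.x[0] == pytest.approx(0.5) and grid.x[-1] == pytest.approx(1.5)
        assert np.all(np.diff(grid.x) > 0)

    def test_validates_missing_and_nonfinite(self):
        with pytest.raises(ValueError, match="missing column"):
            validate_points(pd.DataFrame({"x": [1.0], "y": [2.0]}))
        with pytest.raises(ValueError, match="non-finite"):
            validate_points(_table([1.0, np.nan], [0.0, 1.0], ["a", "b"]))

    def test_canonical_order_is_lexicographic_on_text(self):
        assert canonical_clusters(["10", "2", "b", "A"]) == ["10", "2", "A", "b"]


class TestBandwidth:
    def test_two_point_sample_matches_hand_formula(self):
        # sd of (0,1) is sqrt(1/2); IQR (linear interpolation) is 0.5
        sd = math.sqrt(0.5)
        expected = 4.0 * 1.06 * min(sd, 0.5 / 1.34) * 2 ** (-0.2)
        assert nrd_bandwidth(np.array([0.0, 1.0]), floor=1e-9) == pytest.approx(
            expected, rel=1e-12
        )

    def test_identical_values_fall_to_floor(self):
        assert nrd_bandwidth(np.array([3.0, 3.0, 3.0]), floor=1e-4) == 1e-4

    def test_single_value_falls_to_floor(self):
        assert nrd_bandwidth(np.array([5.0]), floor=1e-4) == 1e-4

    def test_scale_equivariance(self, rng):
        v = rng.normal(size=50)
        h = nrd_bandwidth(v, floor=1e-12)
        assert nrd_bandwidth(7.0 * v, floor=1e-12) == pytest.approx(7.0 * h, rel=1e-12)


class TestKde:
    def test_single_point_at_node_gives_analytic_peak(self):
        grid = Grid(np.linspace(-1, 1, 11), np.linspace(-1, 1, 11))
        hx = hy = 0.8  # kernel sd = 0.2
        z = fit_kde([0.0], [0.0], grid, hx, hy)
        assert z[5, 5] == pytest.approx(1.0 / (2 * math.pi * 0.2 * 0.2), rel=1e-12)

    def test_reflection_symmetry(self):
        grid = Grid(np.linspace(-2, 2, 21), np.linspace(-2, 2, 21))
        z = fit_kde([-1.0, 1.0], [0.5, -0.5], grid, 1.0, 1.0)
        assert np.allclose(z, z[::-1, ::-1], rtol=1e-12)

    def test_matches_direct_sum_oracle(self, rng):
        grid = Grid(np.linspace(-4, 3, 15), np.linspace(-2, 6, 17))
        x = rng.normal(size=30)
        y = rng.normal(loc=2.0, size=30)
        z = fit_kde(x, y, grid, 1.3, 0.9)
        oracle = kde_direct_sum(x, y, grid.x, grid.y, 1.3, 0.9)
        assert np.max(np.abs(z - oracle) / np.maximum(oracle, 1e-300)) < 1e-10

    def test_rejects_bad_bandwidths(self):
        grid = Grid(np.linspace(0, 1, 5), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            fit_kde([0.5], [0.5], grid, 0.0, 1.0)


class TestPermutationCutoffs:
    def test_single_cluster_permutation_is_identity(self, rng):
        # with one cluster any label permutation reproduces the true field,
        # so the cutoff is the 95th percentile of that field
        pts = _table(rng.normal(size=50), rng.normal(size=50), ["only"] * 50)
        grid = make_grid(pts, n=20)
        fields, _ = cluster_fields(pts, grid)
        cut = permutation_cutoffs(pts, grid, np.random.default_rng(0))
        assert cut["only"] == pytest.approx(np.percentile(fields["only"], 95.0))

    def test_constant_field_cutoff_is_that_constant(self):
        field = np.full((10, 10), 3.25)
        assert np.percentile(field, 95.0) == 3.25  # any percentile of a constant

    def test_same_seed_reproduces_cutoffs(self, toy_points):
        grid = make_grid(toy_points)
        c1 = permutation_cutoffs(toy_points, grid, np.random.default_rng(42))
        c2 = permutation_cutoffs(toy_points, grid, np.random.default_rng(42))
        assert c1 == c2

    def test_matches_independent_recomputation(self, toy_points):
        """Rerun the permutation with the same seed in test code and compare."""
        grid = make_grid(toy_points, n=30)
        got = permutation_cutoffs(toy_points, grid, np.random.default_rng(9), percentile=95.0)
        labels = toy_points["cluster"].to_numpy(dtype=object)
        perm = labels[np.random.default_rng(9).permutation(len(labels))]
        for lab in np.unique(labels.astype(str)):
            sel = perm == lab
            sub = toy_points[sel]
            floor_x = 1e-6 * (grid.x[-1] - grid.x[0])
            floor_y = 1e-6 * (grid.y[-1] - grid.y[0])
            hx = nrd_bandwidth(sub["x"].to_numpy(), floor_x)
            hy = nrd_bandwidth(sub["y"].to_numpy(), floor_y)
            field = kde_direct_sum(
                sub["x"].to_numpy(), sub["y"].to_numpy(), grid.x, grid.y, hx, hy
            )
            assert got[lab] == pytest.approx(np.percentile(field, 95.0), rel=1e-10)

    def test_percentile_validated(self, toy_points):
        grid = make_grid(toy_points)
        with pytest.raises(ValueError):
            permutation_cutoffs(toy_points, grid, np.random.default_rng(0), percentile=0.0)


class TestHotSetsAndOverlap:
    def test_cutoff_below_minimum_marks_all_nodes_hot(self):
        field = np.arange(16.0).reshape(4, 4) + 1.0
        hs = hot_sets({"a": field}, {"a": 0.0})
        assert hs["a"].size == 16

    def test_cutoff_above_maximum_gives_empty_set_with_warning(self):
        field = np.ones((4, 4))
        with pytest.warns(UserWarning, match="empty hot"):
            hs = hot_sets({"a": field}, {"a": 5.0})
        assert hs["a"].size == 0

    def test_strict_inequality_at_cutoff(self):
        field = np.array([[1.0, 2.0], [3.0, 4.0]])
        hs = hot_sets({"a": field}, {"a": 2.0})
        assert hs["a"].indices() == [(1, 0), (1, 1)]

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            hot_sets({"a": np.ones((2, 2))}, {"b": 0.0})

    def _hs(self, mask):
        from spacepal.density import HotSet

        return HotSet(mask=np.asarray(mask, bool), cutoff=0.0)

    def test_jaccard_identical_disjoint_and_half(self):
        m1 = np.zeros((3, 3), bool)
        m1[0, :2] = True
        m2 = np.zeros((3, 3), bool)
        m2[1, :2] = True
        half_a = np.zeros((3, 3), bool)
        half_a[0, :3] = True  # {(0,0),(0,1),(0,2)}
        half_b = np.zeros((3, 3), bool)
        half_b[0, 1:] = True
        half_b[1, 0] = True  # overlap 2, union 4
        j = overlap_matrix(
            {"p": self._hs(m1), "q": self._hs(m1.copy()), "r": self._hs(m2)}
        )
        assert j.loc["p", "q"] == 1.0
        assert j.loc["p", "r"] == 0.0
        j2 = overlap_matrix({"u": self._hs(half_a), "v": self._hs(half_b)})
        assert j2.loc["u", "v"] == 0.5

    def test_both_empty_defined_as_zero_with_warning(self):
        empty = self._hs(np.zeros((2, 2), bool))
        with pytest.warns(UserWarning, match="empty"):
            j = overlap_matrix({"a": empty, "b": empty})
        assert j.loc["a", "b"] == 0.0 and j.loc["a", "a"] == 0.0

    def test_symmetric_unit_interval_and_unit_diagonal(self, rng):
        for _ in range(5):
            masks = {
                lab: self._hs(rng.uniform(size=(8, 8)) > 0.6) for lab in "abcd"
            }
            j = overlap_matrix(masks)
            v = j.to_numpy()
            assert np.array_equal(v, v.T)
            assert np.all((v >= 0.0) & (v <= 1.0))
            for lab in "abcd":
                if masks[lab].size > 0:
                    assert j.loc[lab, lab] == 1.0


class TestPipelineInvariances:
    def test_relabeling_clusters_only_reorders_matrix(self, toy_points):
        grid = make_grid(toy_points)
        fields, _ = cluster_fields(toy_points, grid)
        renamed = toy_points.assign(
            cluster=toy_points["cluster"].map(
                {"alpha": "z_last", "beta": "a_first", "gamma": "m_mid"}
            )
        )
        fields2, _ = cluster_fields(renamed, grid)
        assert np.array_equal(fields["alpha"], fields2["z_last"])
        assert np.array_equal(fields["beta"], fields2["a_first"])

    def test_integer_translation_leaves_overlap_unchanged(self):
        rng = np.random.default_rng(3)
        base = _table(
            rng.integers(0, 30, 200).astype(float),
            rng.integers(0, 30, 200).astype(float),
            rng.choice(["a", "b", "c"], 200),
        )

        def jaccard(pts, seed=11):
            grid = make_grid(pts, n=40)
            fields, _ = cluster_fields(pts, grid)
            cuts = permutation_cutoffs(pts, grid, np.random.default_rng(seed))
            return overlap_matrix(hot_sets(fields, cuts))

        shifted = base.assign(x=base["x"] + 7.0, y=base["y"] - 3.0)
        pd.testing.assert_frame_equal(jaccard(base), jaccard(shifted))

    def test_well_separated_blobs_have_zero_overlap(self):
        pts = make_blobs(
            [
                BlobSpec(center=(0.0, 0.0), spread=1.0, n=300, label="a"),
                BlobSpec(center=(50.0, 0.0), spread=1.0, n=300, label="b"),
            ],
            seed=5,
        )
        grid = make_grid(pts)
        fields, _ = cluster_fields(pts, grid)
        cuts = permutation_cutoffs(pts, grid, np.random.default_rng(5))
        j = overlap_matrix(hot_sets(fields, cuts))
        assert j.loc["a", "b"] == 0.0
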