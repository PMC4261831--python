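"""Normalization, clustering (vs a brute-force oracle) and IDW interpolation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sedtriad.integrate import (SpatialField, ec50_to_potency, hcluster,
                                idw_interpolate, minmax_normalize,
                                site_cluster_pipeline, spearman_distance)


def complete_linkage_oracle(dist):
    """Brute-force agglomeration: repeatedly merge the closest pair under
    max-distance between clusters.  Returns sorted merge heights."""
    clusters = [frozenset([i]) for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestMinMax:
    def test_hand_computed_vector(self):
        out = minmax_normalize([0.02, 0.33, 0.37, 0.31, 0.25])
        assert out == pytest.approx([0.0, 0.886, 1.0, 0.829, 0.657], abs=1e-3)

    def test_constant_vector_maps_to_zero(self):
        assert minmax_normalize([3.0, 3.0, 3.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_two_values(self):
        assert minmax_normalize([5.0, 9.0]) == pytest.approx([0.0, 1.0])

    def test_missing_propagates(self):
        out = minmax_normalize([1.0, np.nan, 3.0])
        assert out[0] == 0.0 and out[2] == 1.0 and np.isnan(out[1])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([np.nan, np.nan])


class TestPotency:
    def test_published_fpg_column(self):
        out = ec50_to_potency([65.4, 72.6, 97.1, 104.1])
        assert out == pytest.approx([1.0, 0.814, 0.181, 0.0], abs=1e-3)

    def test_non_estimable_scores_zero(self):
        out = ec50_to_potency([50.0, np.nan, 100.0])
        assert out == pytest.approx([1.0, 0.0, 0.0])

    def test_single_estimable_degenerates_to_zero(self):
        assert ec50_to_potency([80.0]) == pytest.approx([0.0])


class TestSpearmanDistance:
    def test_identical_and_reversed_profiles(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5],
                                 [1, 2, 3, 4, 5],
                                 [5, 4, 3, 2, 1]], index=["a", "b", "c"])
        d = spearman_distance(profiles)
        assert d.loc["a", "b"] == pytest.approx(0.0)
        assert d.loc["a", "c"] == pytest.approx(2.0)

    def test_hand_computed_rank_correlation(self):
        profiles = pd.DataFrame([[1, 2, 3, 4, 5], [1, 3, 2, 5, 4]], index=["a", "b"])
        assert spearman_distance(profiles).loc["a", "b"] == pytest.approx(0.2)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        profiles = pd.DataFrame(rng.normal(size=(4, 6)))
        d = spearman_distance(profiles).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(rng.uniform(1, 10, size=(3, 7)))
        transformed = profiles.copy()
        transformed.iloc[0] = np.exp(transformed.iloc[0] / 3.0)
        d1, d2 = spearman_distance(profiles), spearman_distance(transformed)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_constant_profile_warns_distance_one(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [2, 2, 2, 2]], index=["a", "b"])
        with pytest.warns(UserWarning):
            d = spearman_distance(profiles)
        assert d.loc["a", "b"] == pytest.approx(1.0)


class TestHcluster:
    def test_two_leaves(self):
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        link = hcluster(d)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(3.0)

    def test_block_structure_merges_within_blocks_first(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 1.0
        d[2, 3] = d[3, 2] = 2.0
        link = hcluster(d)
        assert sorted(link[:, 2]) == pytest.approx([1.0, 2.0, 10.0])

    def test_merge_heights_match_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = rng.integers(3, 6)
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            link = hcluster(d)
            assert sorted(link[:, 2]) == pytest.approx(complete_linkage_oracle(d))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            hcluster(d)


class TestSitePipeline:
    def test_case_study_site_topology(self, loe_matrix):
        """Northern sites pair up, southern sites pair up, and the reference
        attaches to the southern cluster before the northern one."""
        from scipy.cluster import hierarchy
        res = site_cluster_pipeline(loe_matrix)
        sites = list(res.normalized.index)
        for k in (2, 3):
            flat = hierarchy.fcluster(res.site_linkage, t=k, criterion="maxclust")
            members = dict(zip(sites, flat))
            assert members["N1"] == members["N2"]
            assert members["S1"] == members["S2"]
            if k == 2:
                assert members["R"] == members["S1"]   # R sides with the south
            if k == 3:
                assert members["R"] not in (members["N1"], members["S1"])

    def test_duplicate_site_rows_merge_at_zero(self, loe_matrix):
        dup = loe_matrix.copy()
        dup.loc["R2"] = dup.loc["R"]
        res = site_cluster_pipeline(dup)
        assert res.site_linkage[:, 2].min() == pytest.approx(0.0)

    def test_normalized_values_bounded(self, loe_matrix):
        res = site_cluster_pipeline(loe_matrix)
        vals = res.normalized.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_newick_trees_parse_with_biopython(self, loe_matrix):
        from io import StringIO
        from Bio import Phylo
        res = site_cluster_pipeline(loe_matrix)
        tree = Phylo.read(StringIO(res.site_newick), "newick")
        names = sorted(t.name for t in tree.get_terminals())
        assert names == sorted(loe_matrix.index)

    def test_too_small_matrix_rejected(self, loe_matrix):
        with pytest.raises(ValueError):
            site_cluster_pipeline(loe_matrix.iloc[:1])


class TestIdw:
    @pytest.fixture()
    def field(self):
        pts = pd.DataFrame({"site": ["a", "b"], "x": [0.0, 2.0], "y": [0.0, 0.0]})
        vals = pd.Series([0.0, 1.0], index=["a", "b"])
        return SpatialField(points=pts, values=vals, bbox=(0.0, 2.0, -1.0, 1.0),
                            resolution=(5, 3))

    def test_exact_at_data_points(self, field):
        surf = idw_interpolate(field)
        # grid columns 0 and 4 at y=0 (middle row) coincide with the points
        assert surf[1, 0] == pytest.approx(0.0)
        assert surf[1, 4] == pytest.approx(1.0)

    def test_midpoint_symmetry(self, field):
        surf = idw_interpolate(field)
        assert surf[1, 2] == pytest.approx(0.5)

    def test_constant_field(self, field):
        field.values[:] = 0.7
        assert idw_interpolate(field) == pytest.approx(np.full((3, 5), 0.7))

    def test_surface_bounded_by_inputs(self):
        rng = np.random.default_rng(7)
        pts = pd.DataFrame({"site": [f"s{i}" for i in range(6)],
                            "x": rng.uniform(0, 10, 6), "y": rng.uniform(0, 10, 6)})
        vals = pd.Series(rng.uniform(-3, 5, 6), index=pts["site"])
        field = SpatialField(pts, vals, (0, 10, 0, 10), (20, 20))
        surf = idw_interpolate(field)
        assert surf.min() >= vals.min() - 1e-9
        assert surf.max() <= vals.max() + 1e-9

    def test_conflicting_duplicate_points_rejected(self):
        pts = pd.DataFrame({"site": ["a", "b"], "x": [1.0, 1.0], "y": [1.0, 1.0]})
        vals = pd.Series([0.0, 1.0], index=["a", "b"])
        field = SpatialField(pts, vals, (0, 2, 0, 2), (3, 3))
        with pytest.raises(ValueError):
            idw_interpolate(field)
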