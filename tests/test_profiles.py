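"""Tractometry core: resampling, orientation, cleaning, weights, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import mahalanobis

from tractokit import (
    ScalarMap,
    Tractogram,
    arc_length,
    clean_group,
    extract_profiles,
    make_scalar_map,
    node_weights,
    orient_group,
    resample_streamline,
)
from tractokit.profiles import _resample_group


class TestResample:
    def test_straight_line_uniform_spacing(self):
        s = np.array([[0.0, 0, 0], [99.0, 0, 0]])
        out = resample_streamline(s, 100)
        np.testing.assert_allclose(out[:, 0], np.arange(100.0), atol=1e-9)
        assert np.all(out[:, 1:] == 0)

    def test_two_nodes_returns_endpoints(self):
        s = np.array([[0.0, 0, 0], [1, 2, 3], [4, 4, 4], [9, 1, 0]])
        out = resample_streamline(s, 2)
        np.testing.assert_array_equal(out, s[[0, -1]])

    def test_quarter_circle_arc_length(self):
        # dense-sampling oracle: quarter circle radius 10 has length 5*pi
        theta = np.linspace(0, np.pi / 2, 10000)
        circle = np.column_stack(
            [10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)]
        )
        out = resample_streamline(circle, 100)
        assert abs(arc_length(out) - 5 * np.pi) / (5 * np.pi) < 1e-3

    def test_zero_length_streamline_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            resample_streamline(np.array([[1.0, 1, 1], [1.0, 1, 1 + 1e-300]]),
                                10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 10_000))
    def test_properties_endpoints_and_length(self, n_nodes, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 1, (12, 3)), axis=0)
        out = resample_streamline(pts, n_nodes)
        assert out.shape == (n_nodes, 3)
        np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)
        # arc length is preserved up to interpolation error (never exceeded)
        assert arc_length(out) <= arc_length(pts) + 1e-9
        # each resampled segment spans exactly L/(n-1) of arc, so no chord
        # can exceed that arc spacing
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert seg.max() <= arc_length(pts) / (n_nodes - 1) + 1e-9


class TestOrient:
    def test_flip_restores_endpoint_coherence(self, outlier_bundle):
        name = next(iter(outlier_bundle.groups))
        before = np.stack([s[0] for s in outlier_bundle.group_streamlines(name)])
        oriented = orient_group(outlier_bundle, name)
        after = np.stack([s[0] for s in oriented.group_streamlines(name)])
        spread = lambda x: np.linalg.norm(x - x.mean(0), axis=1).mean()
        assert spread(after) < spread(before)

    def test_idempotent(self, outlier_bundle):
        name = next(iter(outlier_bundle.groups))
        once = orient_group(outlier_bundle, name)
        twice = orient_group(once, name)
        assert all(np.array_equal(a, b)
                   for a, b in zip(once.streamlines, twice.streamlines))

    def test_two_streamline_toy_matches_brute_force(self, friendly_reference):
        a = np.column_stack([np.linspace(0, 50, 20), np.zeros(20), np.zeros(20)])
        b = a[::-1] + [0.0, 1.0, 0.0]
        t = Tractogram([a, b], friendly_reference,
                       {"g": np.array([0, 1])})
        oriented = orient_group(t, "g", n_nodes=20)
        # brute force: try both orientations of b against a
        keep = np.linalg.norm(a - b, axis=1).sum()
        flip = np.linalg.norm(a - b[::-1], axis=1).sum()
        expect = b[::-1] if flip < keep else b
        np.testing.assert_allclose(oriented.streamlines[1], expect)


class TestClean:
    def test_identical_streamlines_all_kept(self, friendly_reference):
        s = np.column_stack([np.linspace(0, 60, 30), np.zeros(30), np.zeros(30)])
        t = Tractogram([s.copy() for _ in range(20)], friendly_reference,
                       {"g": np.arange(20)})
        kept = clean_group(t, "g")
        assert len(kept) == 20

    def test_planted_outliers_exactly_removed(self, outlier_bundle):
        name = next(iter(outlier_bundle.groups))
        oriented = orient_group(outlier_bundle, name)
        kept = clean_group(oriented, name)
        removed = sorted(set(range(len(outlier_bundle))) - set(kept))
        assert removed == sorted(outlier_bundle.metadata["outlier_indices"])

    def test_brute_force_mahalanobis_agrees_on_first_round(self, outlier_bundle):
        """Independent per-node Mahalanobis via scipy on a small instance."""
        name = next(iter(outlier_bundle.groups))
        oriented = orient_group(outlier_bundle, name)
        coords = _resample_group(oriented.group_streamlines(name), 30)
        s, n, _ = coords.shape
        scores = np.zeros(s)
        for j in range(n):
            x = coords[:, j, :]
            vi = np.linalg.inv(np.cov(x.T))
            mu = x.mean(axis=0)
            scores += np.array([mahalanobis(x[i], mu, vi) for i in range(s)])
        scores /= n
        brute_first_round = np.flatnonzero(scores > 3.0)
        from tractokit.profiles import _mahalanobis_scores

        ours = np.flatnonzero(_mahalanobis_scores(coords) > 3.0)
        np.testing.assert_array_equal(ours, brute_first_round)

    def test_monotone_and_infinite_thresholds(self, outlier_bundle):
        name = next(iter(outlier_bundle.groups))
        oriented = orient_group(outlier_bundle, name)
        kept_all = clean_group(oriented, name, distance_threshold=np.inf,
                               length_threshold=np.inf)
        assert len(kept_all) == len(outlier_bundle)
        kept_r1 = set(clean_group(oriented, name, n_rounds=1))
        kept_r5 = set(clean_group(oriented, name, n_rounds=5))
        assert kept_r5 <= kept_r1

    def test_small_groups_skipped_with_warning(self, friendly_reference, caplog):
        s = np.column_stack([np.linspace(0, 60, 30), np.zeros(30), np.zeros(30)])
        sls = [s + [0, i * 0.1, 0] for i in range(5)]
        t = Tractogram(sls, friendly_reference, {"g": np.arange(5)})
        with caplog.at_level("WARNING"):
            kept = clean_group(t, "g")
        assert len(kept) == 5
        assert "skipping cleaning" in caplog.text


class TestNodeWeights:
    def test_single_streamline_weight_one(self):
        coords = np.random.default_rng(0).normal(size=(1, 10, 3))
        w = node_weights(coords)
        np.testing.assert_array_equal(w, np.ones((1, 10)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(2, 15), st.integers(2, 20), st.integers(0, 10_000))
    def test_weights_sum_to_one(self, n_sl, n_nodes, seed):
        coords = np.random.default_rng(seed).normal(size=(n_sl, n_nodes, 3))
        w = node_weights(coords)
        np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-12)

    def test_collinear_offsets_hand_computed(self):
        # 3 streamlines at perpendicular offsets 0, 1, 2 mm from the middle:
        # the coordinate-wise median is the offset-1 streamline, distances
        # (1, 0, 1), raw weights 1/(d + eps).
        eps = 1e-10
        base = np.zeros((3, 4, 3))
        base[:, :, 0] = np.arange(4)
        base[1, :, 1] = 1.0
        base[2, :, 1] = 2.0
        w = node_weights(base)
        raw = np.array([1 / (1 + eps), 1 / eps, 1 / (1 + eps)])
        np.testing.assert_allclose(w[:, 0], raw / raw.sum(), rtol=1e-9)


class TestExtractProfiles:
    def test_constant_map_gives_constant_profile(self, clean_bundle,
                                                 constant_map):
        prof = extract_profiles(clean_bundle, [constant_map])
        np.testing.assert_allclose(prof.values, 0.5, atol=1e-9)

    def test_linear_field_recovers_node_positions(self, clean_bundle, x_map):
        prof, details = extract_profiles(clean_bundle, [x_map],
                                         return_details=True)
        name = next(iter(clean_bundle.groups))
        d = details[name]
        expect = (d.weights * d.resampled[:, :, 0]).sum(axis=0)
        # trilinear interpolation of a linear field is exact in the interior
        np.testing.assert_allclose(prof.values[0, 0], expect, atol=1e-9)

    def test_default_node_count_is_100(self, clean_bundle, constant_map):
        prof = extract_profiles(clean_bundle, [constant_map])
        assert prof.values.shape[-1] == 100

    def test_streamline_order_invariance(self, clean_bundle, x_map):
        base = extract_profiles(clean_bundle, [x_map], clean=False)
        perm = np.random.default_rng(1).permutation(len(clean_bundle))
        name = next(iter(clean_bundle.groups))
        # keep the same reference streamline (first of the group) so the
        # orientation target is unchanged, permute the rest
        perm = np.concatenate([[0], 1 + np.random.default_rng(1).permutation(
            len(clean_bundle) - 1)])
        shuffled = Tractogram(
            [clean_bundle.streamlines[i] for i in perm],
            clean_bundle.reference,
            {name: np.arange(len(clean_bundle))},
        )
        out = extract_profiles(shuffled, [x_map], clean=False)
        np.testing.assert_allclose(out.values, base.values, atol=1e-9)

    def test_rigid_translation_equivariance(self, clean_bundle, x_map):
        base = extract_profiles(clean_bundle, [x_map])
        shift = np.array([5.0, -3.0, 2.0])
        moved_affine = x_map.affine.copy()
        moved_affine[:3, 3] += shift
        moved_ref_affine = clean_bundle.reference.affine.copy()
        moved_ref_affine[:3, 3] += shift
        from tractokit import SpatialReference

        moved = Tractogram(
            [s + shift for s in clean_bundle.streamlines],
            SpatialReference(clean_bundle.reference.shape,
                             clean_bundle.reference.voxel_sizes,
                             moved_ref_affine),
            dict(clean_bundle.groups),
        )
        moved_map = ScalarMap(x_map.values, moved_affine, x_map.metric_name)
        out = extract_profiles(moved, [moved_map])
        np.testing.assert_allclose(out.values, base.values, atol=1e-8)

    def test_no_overlap_flags_missing(self, clean_bundle, caplog):
        far = make_scalar_map((4, 4, 4), np.eye(4),
                              lambda p: np.full(len(p), 1.0),
                              metric_name="MK")
        # a 4 mm cube at the origin misses most of the bundle; nodes outside
        # are dropped, fully-outside tracts are flagged missing
        with caplog.at_level("WARNING"):
            prof = extract_profiles(clean_bundle, [far])
        assert np.isnan(prof.values).any()

    def test_missing_group_flagged(self, clean_bundle, constant_map, caplog):
        t = clean_bundle.copy()
        t.groups["empty"] = np.array([], dtype=np.int64)
        with caplog.at_level("WARNING"):
            prof = extract_profiles(t, [constant_map])
        i = prof.tract_names.index("empty")
        assert np.isnan(prof.values[i]).all()
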