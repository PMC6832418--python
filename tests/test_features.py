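"""Multiscale feature computation against analytic cases and the oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscloud import (
    MultiscaleFeatures,
    PointCloud,
    ScaleLadder,
    extract,
    neighborhood,
    point_features,
    spectrum,
    z_range,
)
from conftest import brute_force_features


def rotation_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestNeighborhood:
    def test_includes_points_within_half_diameter(self):
        cloud = PointCloud([[0, 0, 0], [0.2, 0, 0]])
        assert set(neighborhood(cloud, 0, 0.5)) == {0, 1}

    def test_excludes_points_beyond_half_diameter(self):
        cloud = PointCloud([[0, 0, 0], [0.2, 0, 0]])
        assert set(neighborhood(cloud, 0, 0.3)) == {0}

    def test_matches_all_pairs_filter(self, random_cloud_500):
        coords = random_cloud_500.coords
        d = 0.4
        for i in range(0, 500, 17):
            expected = np.flatnonzero(
                np.linalg.norm(coords - coords[i], axis=1) <= d / 2
            )
            np.testing.assert_array_equal(
                np.sort(neighborhood(random_cloud_500, i, d)), expected
            )

    def test_count_monotone_in_diameter(self, random_cloud_500):
        counts = [
            len(neighborhood(random_cloud_500, 7, d))
            for d in (0.1, 0.2, 0.4, 0.8)
        ]
        assert counts == sorted(counts)

    def test_rejects_nonpositive_diameter(self, random_cloud_500):
        with pytest.raises(ValueError):
            neighborhood(random_cloud_500, 0, 0.0)


class TestSpectrum:
    def test_collinear_points_are_rank_one(self):
        spec = spectrum([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert spec.eigvals[0] > 0
        assert spec.eigvals[1] == pytest.approx(0.0, abs=1e-12)
        assert spec.eigvals[2] == pytest.approx(0.0, abs=1e-12)

    def test_planar_grid_eigenvalues_match_hand_computation(self):
        # unit 2x2 grid in the XY plane: variances 0.25, 0.25, 0
        spec = spectrum([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
        np.testing.assert_allclose(
            spec.eigvals, [0.25, 0.25, 0.0], atol=1e-12
        )

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(11)
        spec = spectrum(rng.normal(size=(40, 3)))
        np.testing.assert_allclose(
            spec.eigvecs.T @ spec.eigvecs, np.eye(3), atol=1e-9
        )

    def test_rotation_invariance_of_eigenvalues(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(60, 3))
        rot = random_rotation(rng)
        np.testing.assert_allclose(
            spectrum(pts).eigvals,
            spectrum(pts @ rot.T).eigvals,
            atol=1e-9,
        )

    def test_single_point_degenerates_to_zero(self):
        assert spectrum([[1.0, 2.0, 3.0]]).eigvals == (0.0, 0.0, 0.0)


class TestPointFeatures:
    def test_linear_spectrum(self):
        spec = spectrum([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        l, pl, sph, hor, percz = point_features(spec, 0.5)
        assert l == pytest.approx(1.0)
        assert pl == pytest.approx(0.0, abs=1e-12)
        assert sph == pytest.approx(0.0, abs=1e-12)
        assert percz == 0.5

    def test_isotropic_spectrum_is_spherical(self):
        from mscloud.features import NeighborhoodSpectrum

        spec = NeighborhoodSpectrum((2.0, 2.0, 2.0), np.eye(3), 99)
        l, pl, sph, *_ = point_features(spec, 0.0)
        assert (l, pl, sph) == (0.0, 0.0, 1.0)

    def test_horizontal_and_vertical_plane_normals(self):
        rng = np.random.default_rng(13)
        flat = np.column_stack(
            [rng.uniform(size=50), rng.uniform(size=50), np.zeros(50)]
        )
        assert point_features(spectrum(flat), 0)[3] == pytest.approx(
            0.0, abs=1e-6
        )
        wall = np.column_stack(
            [np.zeros(50), rng.uniform(size=50), rng.uniform(size=50)]
        )
        assert point_features(spectrum(wall), 0)[3] == pytest.approx(
            90.0, abs=1e-6
        )

    def test_degenerate_spectrum_yields_zeros(self):
        spec = spectrum([[3.0, 4.0, 5.0]])
        np.testing.assert_array_equal(
            point_features(spec, 1.5), [0, 0, 0, 0, 1.5]
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shape_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(3, 30), 3))
        spec = spectrum(pts)
        if spec.eigvals[0] > 0:
            l, pl, sph, *_ = point_features(spec, 0.0)
            assert l + pl + sph == pytest.approx(1.0, abs=1e-12)
            assert min(l, pl, sph) >= 0.0


class TestZRange:
    def test_single_point_column(self):
        cloud = PointCloud([[0, 0, 5.0], [10, 10, 0.0]])
        assert z_range(cloud, 0, 0.5) == 0.0

    def test_percentile_span_of_uniform_column(self):
        z = np.round(np.arange(101) * 0.01, 2)
        cloud = PointCloud(np.column_stack([np.zeros(101), np.zeros(101), z]))
        # independent check of the percentile rule
        lo, hi = np.percentile(z, [5, 95])
        assert hi - lo == pytest.approx(0.90, abs=1e-12)
        assert z_range(cloud, 0, 0.2) == pytest.approx(0.90, abs=1e-12)

    def test_robust_to_a_single_outlier(self):
        z = np.arange(101) * 0.01
        base = PointCloud(np.column_stack([np.zeros(101), np.zeros(101), z]))
        spiked = PointCloud(
            np.vstack([base.coords, [[0.0, 0.0, 100.0]]])
        )
        assert abs(z_range(spiked, 0, 0.2) - z_range(base, 0, 0.2)) < 0.2

    def test_column_is_unbounded_vertically(self):
        cloud = PointCloud([[0, 0, 0.0], [0.01, 0, 50.0], [5, 5, 1.0]])
        assert z_range(cloud, 0, 0.1) == pytest.approx(0.9 * 50.0)


class TestExtract:
    def test_single_point_cloud_all_zero(self):
        feats = extract(PointCloud([[1.0, 2.0, 3.0]]), ScaleLadder((0.1, 0.2)))
        np.testing.assert_array_equal(feats.to_numpy(), 0.0)

    def test_matches_brute_force_oracle(self, random_cloud_500, small_ladder):
        got = extract(random_cloud_500, small_ladder)
        want = brute_force_features(random_cloud_500, small_ladder)
        assert list(got.columns) == list(want.columns)
        np.testing.assert_allclose(
            got.to_numpy(), want.to_numpy(), atol=1e-9
        )

    def test_invariant_under_z_rotation_and_translation(
        self, random_cloud_500, small_ladder
    ):
        base = extract(random_cloud_500, small_ladder)
        rot = rotation_z(0.83)
        moved = PointCloud(
            random_cloud_500.coords @ rot.T + np.array([12.0, -7.0, 3.0])
        )
        np.testing.assert_allclose(
            extract(moved, small_ladder).to_numpy(),
            base.to_numpy(),
            atol=1e-6,
        )

    def test_shape_ratios_invariant_under_arbitrary_rotation(
        self, random_cloud_500
    ):
        ladder = ScaleLadder((0.4,))
        base = extract(random_cloud_500, ladder)
        rot = random_rotation(np.random.default_rng(21))
        turned = extract(
            PointCloud(random_cloud_500.coords @ rot.T), ladder
        )
        np.testing.assert_allclose(
            turned[["L1", "PL1", "SPH1"]].to_numpy(),
            base[["L1", "PL1", "SPH1"]].to_numpy(),
            atol=1e-6,
        )

    def test_column_naming_and_ranges(self, random_cloud_500, small_ladder):
        feats = extract(random_cloud_500, small_ladder)
        assert list(feats.columns) == [
            "L1", "PL1", "SPH1", "HOR1", "PERCZ1",
            "L2", "PL2", "SPH2", "HOR2", "PERCZ2",
        ]
        assert np.all(np.isfinite(feats.to_numpy()))
        for col in ("L1", "PL1", "SPH1", "L2", "PL2", "SPH2"):
            assert feats[col].between(0, 1).all()
        for col in ("HOR1", "HOR2"):
            assert feats[col].between(0, 90).all()
        assert (feats[["PERCZ1", "PERCZ2"]] >= 0).all().all()

    def test_chunking_does_not_change_results(self, random_cloud_500):
        big = MultiscaleFeatures(scales=(0.3,), chunk_size=100000)
        small = MultiscaleFeatures(scales=(0.3,), chunk_size=64)
        coords = random_cloud_500.coords
        np.testing.assert_allclose(
            big.fit(coords).transform(coords),
            small.fit(coords).transform(coords),
            atol=1e-12,
        )

    def test_empty_cloud_rejected(self):
        tf = MultiscaleFeatures(scales=(0.1,))
        with pytest.raises(ValueError, match="empty"):
            tf.fit(np.zeros((0, 3))).transform(np.zeros((0, 3)))

    def test_transformer_feature_names(self):
        tf = MultiscaleFeatures(scales=(0.1, 0.2)).fit(np.zeros((2, 3)))
        assert tf.get_feature_names_out()[0] == "L1"
        assert len(tf.get_feature_names_out()) == 10


class TestScaleLadder:
    def test_default_is_six_rungs_5cm_to_50cm(self):
        ladder = ScaleLadder()
        assert len(ladder) == 6
        assert ladder.diameters[0] == 0.05
        assert ladder.diameters[-1] == 0.50

    @pytest.mark.parametrize(
        "bad", [(), (0.2, 0.1), (0.1, 0.1), (-0.1,), (0.0, 0.1)]
    )
    def test_rejects_invalid_ladders(self, bad):
        with pytest.raises(ValueError):
            ScaleLadder(bad)
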