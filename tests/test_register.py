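import numpy as np
import pytest

from nervemap import (
    LandmarkPairs,
    Transform2D,
    apply_transform,
    fit_affine,
    fit_rigid,
    fit_tps,
    transform_points,
)
from nervemap.register import bending_energy, invert_transform, load_landmarks_csv


def _rot(deg):
    th = np.deg2rad(deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


class TestFitRigid:
    def test_identity(self, rng):
        pts = rng.uniform(0, 100, (6, 2))
        t = fit_rigid(LandmarkPairs(pts, pts))
        np.testing.assert_allclose(t.matrix, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    def test_recovers_rotation_about_centroid(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        c = pts.mean(axis=0)
        dst = (pts - c) @ _rot(90).T + c
        t = fit_rigid(LandmarkPairs(pts, dst))
        angle = np.degrees(np.arctan2(t.matrix[1, 0], t.matrix[0, 0]))
        assert angle == pytest.approx(90.0, abs=1e-9)
        np.testing.assert_allclose(transform_points(t, pts), dst, atol=1e-9)

    def test_recovers_translation_and_scale(self, rng):
        pts = rng.uniform(0, 50, (8, 2))
        dst = 1.7 * (pts @ _rot(33).T) + np.array([5.0, -3.0])
        t = fit_rigid(LandmarkPairs(pts, dst), allow_scale=True)
        np.testing.assert_allclose(transform_points(t, pts), dst, atol=1e-9)
        assert np.sqrt(np.linalg.det(t.matrix)) == pytest.approx(1.7, abs=1e-9)

    def test_one_pair_raises(self):
        with pytest.raises(ValueError):
            fit_rigid(LandmarkPairs([[0.0, 0.0]], [[1.0, 1.0]]))

    def test_coincident_sources_raise(self):
        src = np.ones((3, 2))
        with pytest.raises(ValueError):
            fit_rigid(LandmarkPairs(src, np.random.default_rng(0).uniform(0, 1, (3, 2))))

    def test_no_reflection_by_default(self, rng):
        pts = rng.uniform(0, 10, (5, 2))
        dst = pts * np.array([-1.0, 1.0])  # mirrored
        t = fit_rigid(LandmarkPairs(pts, dst))
        assert np.linalg.det(t.matrix) == pytest.approx(1.0, abs=1e-9)
        t2 = fit_rigid(LandmarkPairs(pts, dst), allow_reflection=True)
        assert np.linalg.det(t2.matrix) == pytest.approx(-1.0, abs=1e-9)

    def test_optimal_among_random_rigids(self, rng):
        """The Procrustes fit beats 200 random rigid transforms on
        noisy 5-point sets."""
        src = rng.uniform(0, 100, (5, 2))
        dst = (src @ _rot(25).T) + np.array([4.0, 7.0]) + rng.normal(0, 2, (5, 2))
        t = fit_rigid(LandmarkPairs(src, dst))
        best = np.mean(np.sum((transform_points(t, src) - dst) ** 2, axis=1))
        for _ in range(200):
            th = rng.uniform(0, 360)
            rotated = src @ _rot(th).T
            # optimal translation for this rotation, then a random nudge
            tr = (dst - rotated).mean(axis=0) + rng.normal(0, 1, 2)
            resid = np.mean(np.sum((rotated + tr - dst) ** 2, axis=1))
            assert best <= resid + 1e-9

    def test_composition_round_trip(self, rng):
        src = rng.uniform(0, 100, (6, 2))
        dst = src @ _rot(40).T + np.array([3.0, -8.0])
        fwd = fit_rigid(LandmarkPairs(src, dst))
        back = fit_rigid(LandmarkPairs(dst, src))
        returned = transform_points(back, transform_points(fwd, src))
        np.testing.assert_allclose(returned, src, atol=1e-6)


class TestFitTps:
    def test_interpolates_at_lambda_zero(self, rng):
        src = rng.uniform(0, 100, (8, 2))
        dst = src + rng.normal(0, 5, (8, 2))
        t = fit_tps(LandmarkPairs(src, dst), lam=0.0)
        np.testing.assert_allclose(transform_points(t, src), dst, atol=1e-6)

    def test_affine_pairs_have_zero_bending(self, rng):
        """Landmarks related by a pure affine map yield bending energy 0
        and the TPS equals that affine map on a test grid."""
        src = rng.uniform(0, 50, (7, 2))
        a = np.array([[1.2, 0.3], [-0.1, 0.9]])
        b = np.array([4.0, -2.0])
        dst = src @ a.T + b
        t = fit_tps(LandmarkPairs(src, dst), lam=0.0)
        assert bending_energy(t) == pytest.approx(0.0, abs=1e-8)
        gx, gy = np.meshgrid(np.linspace(0, 50, 9), np.linspace(0, 50, 9))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        np.testing.assert_allclose(transform_points(t, grid), grid @ a.T + b, atol=1e-6)

    def test_large_lambda_approaches_affine(self, rng):
        src = rng.uniform(0, 100, (10, 2))
        dst = src @ np.array([[1.1, 0.2], [0.0, 0.95]]).T + rng.normal(0, 3, (10, 2))
        aff = fit_affine(LandmarkPairs(src, dst))
        resid_aff = np.sum((transform_points(aff, src) - dst) ** 2)
        t = fit_tps(LandmarkPairs(src, dst), lam=1e9)
        resid_tps = np.sum((transform_points(t, src) - dst) ** 2)
        assert resid_tps == pytest.approx(resid_aff, rel=1e-3)

    def test_collinear_raises(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            fit_tps(LandmarkPairs(src, src))

    def test_known_eight_point_warp_reproduced_on_dense_grid(self, rng):
        """Fitting the 8 control pairs of a known TPS reproduces the warp
        everywhere within 1e-4 px."""
        src = rng.uniform(10, 90, (8, 2))
        dst = src + rng.normal(0, 4, (8, 2))
        truth = fit_tps(LandmarkPairs(src, dst), lam=0.0)
        refit = fit_tps(LandmarkPairs(src, transform_points(truth, src)), lam=0.0)
        gx, gy = np.meshgrid(np.linspace(0, 100, 40), np.linspace(0, 100, 40))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        err = np.abs(transform_points(refit, grid) - transform_points(truth, grid))
        assert err.max() < 1e-4

    def test_serialization_round_trip(self, rng):
        src = rng.uniform(0, 10, (5, 2))
        t = fit_tps(LandmarkPairs(src, src + 1.0), lam=0.5)
        t2 = Transform2D.from_json(t.to_json())
        pts = rng.uniform(0, 10, (20, 2))
        np.testing.assert_allclose(transform_points(t, pts), transform_points(t2, pts))


class TestApplyTransform:
    def test_identity(self, rng):
        img = rng.integers(0, 255, (12, 15), dtype=np.uint8)
        ident = Transform2D("rigid", np.eye(2), np.zeros(2))
        out = apply_transform(img, ident, img.shape)
        np.testing.assert_array_equal(out, img)

    def test_translation_moves_pixel(self):
        """Translating by (+5, 0) in x moves a bright pixel at (row 10,
        col 10) to (row 10, col 15)."""
        img = np.zeros((20, 20))
        img[10, 10] = 1.0
        t = Transform2D("rigid", np.eye(2), np.array([5.0, 0.0]))
        out = apply_transform(img, t, (20, 20))
        assert out[10, 15] == 1.0
        assert out.sum() == 1.0

    def test_binary_values_preserved_under_nearest(self, rng):
        mask = (rng.random((16, 16)) < 0.3).astype(float)
        t = fit_rigid(LandmarkPairs(rng.uniform(0, 16, (4, 2)), rng.uniform(0, 16, (4, 2))))
        out = apply_transform(mask, t, (16, 16), "nearest", fill=0.0)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_fill_value_outside_domain(self):
        img = np.ones((4, 4))
        t = Transform2D("rigid", np.eye(2), np.array([10.0, 0.0]))
        out = apply_transform(img, t, (4, 4), fill=-1.0)
        assert (out == -1.0).all()

    def test_rgb_channels_supported(self, rng):
        img = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        ident = Transform2D("rigid", np.eye(2), np.zeros(2))
        np.testing.assert_array_equal(apply_transform(img, ident, (8, 8)), img)

    def test_tps_image_round_trip_near_landmarks(self, rng):
        """Warping forward then applying the inverse-direction resampling
        approximately restores a smooth image."""
        src = np.array([[2.0, 2.0], [14.0, 2.0], [2.0, 14.0], [14.0, 14.0], [8.0, 8.0]])
        dst = src + rng.normal(0, 0.5, src.shape)
        t = fit_tps(LandmarkPairs(src, dst), lam=0.0)
        inv = invert_transform(t)
        back = transform_points(inv, transform_points(t, src))
        np.testing.assert_allclose(back, src, atol=0.2)


class TestLandmarkIO:
    def test_csv_round_trip(self, tmp_path, rng):
        src = rng.uniform(0, 100, (4, 2))
        dst = rng.uniform(0, 100, (4, 2))
        p = tmp_path / "lm.csv"
        rows = np.column_stack([src, dst])
        np.savetxt(p, rows, delimiter=",", header="x_src,y_src,x_dst,y_dst", comments="")
        pairs = load_landmarks_csv(p)
        np.testing.assert_allclose(pairs.source, src)
        np.testing.assert_allclose(pairs.target, dst)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LandmarkPairs(np.zeros((3, 2)), np.zeros((4, 2)))
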