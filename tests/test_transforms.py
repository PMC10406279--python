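"""Transform algebra: application, composition, inversion, mask warping."""

import numpy as np
import pytest
from scipy.optimize import root

from fetalicv import (BinaryMask, BSplineTransform, Geometry, LinearTransform,
                      TransformChain, Volume, apply_transform, compose, invert,
                      load_transform, save_transform, warp_mask)


def ball_mask(shape=(40, 40, 40), spacing=1.0, radius=12.0):
    idx = np.indices(shape, dtype=float)
    c = (np.asarray(shape) - 1) / 2.0
    r2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
    data = (r2 <= (radius / spacing) ** 2).astype(np.uint8)
    origin = -spacing * c
    return BinaryMask(data, (spacing,) * 3, origin)


def random_volume(rng, shape=(12, 12, 12), spacing=1.0):
    origin = -spacing * (np.asarray(shape) - 1) / 2.0
    return Volume(rng.uniform(10, 100, shape), (spacing,) * 3, origin)


class TestApplyTransform:
    def test_identity_is_exact(self, rng):
        v = random_volume(rng)
        out = apply_transform(v, LinearTransform.identity())
        np.testing.assert_allclose(out.data, v.data, atol=1e-10)

    def test_integer_voxel_translation_matches_index_shift(self, rng):
        v = random_volume(rng, shape=(14, 10, 10), spacing=2.0)
        # transform maps fixed x -> x + 2 voxels along axis 0, so the output
        # at index i equals the input at index i + 2
        t = LinearTransform.translation(np.array([2 * v.spacing[0], 0, 0]))
        out = apply_transform(v, t)
        np.testing.assert_allclose(out.data[:-2], v.data[2:], atol=1e-9)

    def test_uniform_scale_halves_ball_radius(self):
        m = ball_mask()
        v = Volume(m.data.astype(float), m.spacing, m.origin)
        t = LinearTransform("similarity", 2.0 * np.eye(3), np.zeros(3),
                            np.zeros(3))  # fixed x -> 2x: shrink by half
        out = apply_transform(v, t, cval=0.0)
        ratio = (out.data > 0.5).sum() / m.voxel_count
        assert ratio == pytest.approx(1 / 8, rel=0.03)

    def test_singular_transform_rejected(self):
        M = np.eye(3)
        M[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            LinearTransform("affine", M, np.zeros(3), np.zeros(3))


class TestCompose:
    def test_translation_pair_collapses_to_identity(self):
        t = np.array([3.0, -1.0, 2.0])
        chain = TransformChain([LinearTransform.translation(t),
                                LinearTransform.translation(-t)])
        c = compose(chain)
        assert len(c) == 1
        np.testing.assert_allclose(c.transforms[0].matrix, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(c.transforms[0].offset, 0, atol=1e-10)

    def test_rigid_and_inverse_collapse_to_identity(self, rng):
        ang = rng.uniform(-0.5, 0.5, 3)
        t = LinearTransform.from_params("rigid", ang, rng.uniform(-5, 5, 3),
                                        1.0, rng.uniform(-10, 10, 3))
        c = compose(TransformChain([t, t.inverted()]))
        pts = rng.uniform(-20, 20, (3, 50))
        np.testing.assert_allclose(c.apply_points(pts), pts, atol=1e-10)

    def test_collapsed_chain_matches_original_pointwise(self, rng):
        members = [
            LinearTransform.translation(rng.uniform(-4, 4, 3)),
            LinearTransform.from_params("rigid", rng.uniform(-0.3, 0.3, 3),
                                        rng.uniform(-2, 2, 3), 1.0,
                                        rng.uniform(-5, 5, 3)),
            LinearTransform("affine", np.eye(3) + rng.uniform(-0.1, 0.1, (3, 3)),
                            rng.uniform(-2, 2, 3), rng.uniform(-5, 5, 3)),
        ]
        chain = TransformChain(members)
        collapsed = compose(chain)
        assert len(collapsed) == 1
        pts = rng.uniform(-30, 30, (3, 100))
        np.testing.assert_allclose(collapsed.apply_points(pts),
                                   chain.apply_points(pts), atol=1e-8)


def synthetic_bspline(geom, rng, amplitude=2.0, grid_vox=8.0):
    t0 = BSplineTransform.for_domain(geom, grid_vox * geom.spacing)
    coef = rng.normal(0.0, amplitude / 2.0, t0.coefficients.shape)
    coef = np.clip(coef, -amplitude, amplitude)
    return BSplineTransform(t0.grid_origin, t0.grid_spacing, coef, geom)


class TestInvert:
    def test_translation_closed_form(self):
        t = LinearTransform.translation(np.array([3.0, -1.0, 2.0]))
        np.testing.assert_allclose(invert(t).offset, [-3.0, 1.0, -2.0])

    def test_similarity_scale_inverts(self):
        t = LinearTransform("similarity", 1.25 * np.eye(3), np.zeros(3),
                            np.ones(3))
        s_inv = np.linalg.det(invert(t).matrix) ** (1 / 3)
        assert s_inv == pytest.approx(0.8, abs=1e-12)

    def test_bspline_inverse_matches_brute_force_roots(self, rng):
        geom = Geometry((24, 24, 24), np.ones(3), -11.5 * np.ones(3))
        t = synthetic_bspline(geom, rng, amplitude=2.0)  # max 2 voxels
        tol = 0.05  # mm (= 0.05 voxel here)
        inv = invert(t, tolerance=tol)
        pts = geom.voxel_centers_world()
        sel = rng.choice(pts.shape[1], 40, replace=False)
        for y in pts[:, sel].T:
            # brute-force root of t(x) = y, independently of the inverse
            sol = root(lambda x: t.apply_points(x[:, None])[:, 0] - y, y,
                       tol=1e-10)
            assert sol.success
            x_inv = inv.apply_points(y[:, None])[:, 0]
            np.testing.assert_allclose(x_inv, sol.x, atol=2 * tol)

    def test_double_inversion_restores_action(self, rng):
        geom = Geometry((20, 20, 20), np.ones(3), -9.5 * np.ones(3))
        t = synthetic_bspline(geom, rng, amplitude=1.5)
        tol = 0.05
        tt = invert(invert(t, tolerance=tol), tolerance=tol)
        pts = geom.voxel_centers_world()
        np.testing.assert_allclose(tt.apply_points(pts), t.apply_points(pts),
                                   atol=2 * tol)

    def test_chain_inverse_equals_reversed_member_inverses(self, rng):
        a = LinearTransform.translation(rng.uniform(-3, 3, 3))
        b = LinearTransform.from_params("similarity", rng.uniform(-0.2, 0.2, 3),
                                        rng.uniform(-2, 2, 3), 1.1,
                                        np.zeros(3))
        chain = TransformChain([a, b])
        inv_chain = invert(compose(chain))
        manual = TransformChain([b.inverted(), a.inverted()])
        pts = rng.uniform(-20, 20, (3, 60))
        np.testing.assert_allclose(inv_chain.apply_points(pts),
                                   manual.apply_points(pts), atol=1e-6)

    def test_invert_compose_round_trip_residual(self, rng):
        members = [LinearTransform.translation(rng.uniform(-4, 4, 3)),
                   LinearTransform.from_params("rigid", rng.uniform(-0.3, 0.3, 3),
                                               rng.uniform(-3, 3, 3), 1.0,
                                               np.zeros(3))]
        chain = TransformChain(members)
        inv = invert(compose(chain))
        pts = rng.uniform(-25, 25, (3, 80))
        back = inv.apply_points(chain.apply_points(pts))
        assert np.abs(back - pts).max() <= 0.05  # voxel-scale bound, mm


class TestWarpMask:
    def test_identity_preserves_mask(self):
        m = ball_mask()
        out = warp_mask(m, LinearTransform.identity())
        np.testing.assert_array_equal(out.data, m.data)

    def test_integer_translation_preserves_count(self):
        m = ball_mask(radius=10.0)
        t = LinearTransform.translation(np.array([3.0, -2.0, 1.0]))
        assert warp_mask(m, t).voxel_count == m.voxel_count

    def test_scale_changes_volume_analytically(self):
        m = ball_mask(shape=(52, 52, 52), radius=20.0)
        # fixed x -> x/1.2 samples a grown ball: volume ratio 1.2^3
        t = LinearTransform("similarity", np.eye(3) / 1.2, np.zeros(3),
                            np.zeros(3))
        ratio = warp_mask(m, t).voxel_count / m.voxel_count
        assert ratio == pytest.approx(1.2**3, rel=0.02)

    def test_rigid_volume_change_small(self, rng):
        m = ball_mask(radius=11.0)
        t = LinearTransform.from_params("rigid", rng.uniform(-0.3, 0.3, 3),
                                        rng.uniform(-2, 2, 3), 1.0, np.zeros(3))
        ratio = warp_mask(m, t).voxel_count / m.voxel_count
        assert abs(ratio - 1) < 0.02


def test_serialization_round_trip(tmp_path, rng):
    geom = Geometry((16, 16, 16), np.ones(3), np.zeros(3))
    chain = TransformChain([
        LinearTransform.from_params("similarity", rng.uniform(-0.2, 0.2, 3),
                                    rng.uniform(-3, 3, 3), 1.05,
                                    rng.uniform(-4, 4, 3)),
        synthetic_bspline(geom, rng, amplitude=1.0),
    ])
    path = save_transform(chain, tmp_path / "chain.json")
    back = load_transform(path)
    pts = rng.uniform(0, 15, (3, 50))
    np.testing.assert_allclose(back.apply_points(pts), chain.apply_points(pts),
                               atol=1e-12)
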