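"""Single-stage registration: blurring, metrics, recovery of known motions."""

import numpy as np
import pytest

from fetalicv import (LinearTransform, RegistrationParams, Volume,
                      apply_transform, blur, intensity_metric, invert,
                      register)
from conftest import fast_params, small_spec
from fetalicv.phantom import make_head_phantom
from fetalicv.volume import replace_zero_voxels


@pytest.fixture(scope="module")
def head():
    v, _, _ = make_head_phantom(small_spec())
    return replace_zero_voxels(v)


class TestBlur:
    def test_sigma_zero_is_identity(self, head):
        np.testing.assert_array_equal(blur(head, 0).data, head.data)

    @pytest.mark.parametrize("sigma", [0.5, 2.0, 4.0])
    def test_shape_unchanged_no_downsampling(self, head, sigma):
        assert blur(head, sigma).shape == head.shape

    def test_variance_decreases_on_speckle(self, head):
        assert blur(head, 2.0).data.var() < head.data.var()

    def test_negative_sigma_rejected(self, head):
        with pytest.raises(ValueError):
            blur(head, -1.0)


class TestIntensityMetric:
    def test_identical_volumes(self, head):
        assert intensity_metric(head, head, "ssd") == 0.0
        assert intensity_metric(head, head, "ncc") == pytest.approx(1.0)

    def test_constant_offset_affects_ssd_not_ncc(self, head):
        import dataclasses
        shifted = dataclasses.replace(head, data=head.data + 13.0)
        assert intensity_metric(head, shifted, "ssd") == pytest.approx(169.0)
        assert intensity_metric(head, shifted, "ncc") == pytest.approx(1.0)

    def test_matches_brute_force_loops(self, rng):
        a = rng.uniform(0, 50, (8, 8, 8))
        b = rng.uniform(0, 50, (8, 8, 8))
        va = Volume(a, (1, 1, 1), (0, 0, 0))
        vb = Volume(b, (1, 1, 1), (0, 0, 0))
        # independent triple-loop oracle
        n = a.size
        ssd = 0.0
        sa = sb = sab = saa = sbb = 0.0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    x, y = a[i, j, k], b[i, j, k]
                    ssd += (x - y) ** 2
                    sa += x; sb += y; sab += x * y
                    saa += x * x; sbb += y * y
        ssd /= n
        ncc = (sab - sa * sb / n) / np.sqrt((saa - sa**2 / n) * (sbb - sb**2 / n))
        assert intensity_metric(va, vb, "ssd") == pytest.approx(ssd, abs=1e-10)
        assert intensity_metric(va, vb, "ncc") == pytest.approx(ncc, abs=1e-10)

    def test_constant_image_ncc_fails(self):
        c = Volume(np.full((4, 4, 4), 7.0), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="constant"):
            intensity_metric(c, c, "ncc")

    def test_mismatched_grids_rejected(self, head):
        small = Volume(np.ones((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="grids"):
            intensity_metric(head, small, "ssd")


class TestParamsValidation:
    def test_pyramid_must_be_nonincreasing(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            RegistrationParams(family="rigid", pyramid_schedule=(1.0, 2.0))

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            RegistrationParams(family="warp")
        with pytest.raises(ValueError):
            RegistrationParams(family="rigid", sp_a=0.0)
        with pytest.raises(ValueError):
            RegistrationParams(family="rigid", max_iterations=0)


class TestRegistrationRecovery:
    @pytest.mark.parametrize("family", ["translation", "rigid", "similarity",
                                        "affine"])
    def test_identity_recovered_when_moving_equals_fixed(self, head, family):
        res = register(head, head, fast_params(family))
        pts = head.geometry().voxel_centers_world()
        moved = res.transform.apply_points(pts)
        # recovered transform within 0.1 voxel of identity
        assert np.abs(moved - pts).max() <= 0.1 * head.spacing.min()

    def test_known_translation_recovered(self, head):
        shift_vox = np.array([3.0, -2.0, 2.0])
        t_true = LinearTransform.translation(shift_vox * head.spacing)
        moving = apply_transform(head, invert(t_true))
        res = register(head, moving, fast_params("translation",
                                                 max_iterations=40))
        err = np.abs(res.transform.offset - shift_vox * head.spacing)
        assert err.max() <= 0.5 * head.spacing.min()

    def test_seeded_determinism(self, head):
        t_true = LinearTransform.translation(np.array([4.0, 0.0, -3.0]))
        moving = apply_transform(head, invert(t_true))
        p = fast_params("affine", seed=99)
        r1 = register(head, moving, p)
        r2 = register(head, moving, p)
        np.testing.assert_array_equal(r1.transform.matrix, r2.transform.matrix)
        np.testing.assert_array_equal(r1.transform.offset, r2.transform.offset)
        assert r1.final_metric == r2.final_metric
        assert r1.iterations_used == r2.iterations_used

    def test_final_metric_no_worse_than_initial(self, head):
        t_true = LinearTransform.translation(np.array([5.0, -2.5, 0.0]))
        moving = apply_transform(head, invert(t_true))
        for metric in ("ncc", "ssd"):
            res = register(head, moving, fast_params("rigid", metric=metric))
            initial = intensity_metric(head, moving, metric)
            if metric == "ncc":
                assert res.final_metric >= initial - 1e-12
            else:
                # reported on a voxel subsample, so compare loosely
                assert res.final_metric <= initial * 1.05

    def test_bspline_identity_stays_small(self, head):
        res = register(head, head, fast_params("bspline"))
        disp = res.transform.displacement(head.geometry().voxel_centers_world())
        assert np.abs(disp).max() <= 0.1 * head.spacing.min()
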