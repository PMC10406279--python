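"""QC gates: overlap similarity, SD agreement gate, mask smoothing, overlays."""

import numpy as np
import pytest

from fetalicv import (BinaryMask, Volume, overlap_similarity, render_overlay,
                      sd_gate, similarity_gate, smooth_mask, two_value_sd)


def vol(data):
    data = np.asarray(data, dtype=float)
    return Volume(data, (1, 1, 1), (0, 0, 0))


class TestOverlapSimilarity:
    def test_self_similarity_is_one(self, rng):
        a = vol(rng.uniform(0, 100, (8, 8, 8)))
        assert overlap_similarity(a, a) == pytest.approx(1.0, abs=1e-14)

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((8, 8, 8)); a[:4] = 5.0
        b = np.zeros((8, 8, 8)); b[4:] = 7.0
        assert overlap_similarity(vol(a), vol(b)) == 0.0

    def test_forced_small_example(self):
        # a = [1, 0], b = [1, 1]  ->  1 / sqrt(2)
        a = np.array([1.0, 0.0]).reshape(2, 1, 1)
        b = np.array([1.0, 1.0]).reshape(2, 1, 1)
        assert overlap_similarity(vol(a), vol(b)) == pytest.approx(
            1 / np.sqrt(2), abs=1e-15)

    def test_matches_brute_force_and_invariances(self, rng):
        for _ in range(10):
            a = rng.uniform(0, 50, (8, 8, 8))
            b = rng.uniform(0, 50, (8, 8, 8))
            num = den_a = den_b = 0.0
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        num += a[i, j, k] * b[i, j, k]
                        den_a += a[i, j, k] ** 2
                        den_b += b[i, j, k] ** 2
            expected = num / np.sqrt(den_a * den_b)
            s = overlap_similarity(vol(a), vol(b))
            assert s == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= s <= 1.0
            # symmetry and scale invariance
            assert overlap_similarity(vol(b), vol(a)) == pytest.approx(s, abs=1e-14)
            assert overlap_similarity(vol(a), vol(3.7 * b)) == pytest.approx(
                s, abs=1e-12)

    def test_error_cases(self, rng):
        z = vol(np.zeros((4, 4, 4)))
        a = vol(rng.uniform(0, 1, (4, 4, 4)))
        with pytest.raises(ValueError, match="all-zero"):
            overlap_similarity(a, z)
        with pytest.raises(ValueError, match="grids"):
            overlap_similarity(a, vol(np.ones((3, 3, 3))))
        with pytest.raises(ValueError, match="nonnegative"):
            overlap_similarity(a, vol(-np.ones((4, 4, 4))))


class TestSdGate:
    def test_equal_icvs_pass_any_rule(self):
        for rule, thr in (("absolute", 10.0), ("fraction_of_mean", 0.10)):
            d = sd_gate(85.0, 85.0, rule, thr)
            assert d.sd_value == 0.0
            assert d.verdict == "pass"

    def test_two_value_sd_is_sample_convention(self):
        assert two_value_sd(80.0, 90.0) == pytest.approx(7.0710678, abs=1e-6)

    def test_fraction_rule_example(self):
        d = sd_gate(80.0, 90.0, "fraction_of_mean", 0.10)
        assert d.sd_threshold == pytest.approx(8.5)
        assert d.sd_value == pytest.approx(7.071, abs=1e-3)
        assert d.verdict == "pass"

    def test_absolute_rule_example(self):
        d = sd_gate(240.0, 275.0, "absolute", 20.0)
        assert d.sd_value == pytest.approx(24.749, abs=1e-3)
        assert d.verdict == "retry"

    def test_verdict_monotone_in_disagreement(self):
        verdicts = [sd_gate(100.0, 100.0 + delta, "fraction_of_mean", 0.10).verdict
                    for delta in np.linspace(0, 40, 30)]
        # once retry appears it never flips back to pass
        first_retry = verdicts.index("retry")
        assert all(v == "retry" for v in verdicts[first_retry:])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd_gate(-1.0, 80.0, "absolute", 10.0)
        with pytest.raises(ValueError):
            sd_gate(80.0, 80.0, "absolute", 0.0)
        with pytest.raises(ValueError):
            sd_gate(80.0, 80.0, "bogus", 1.0)


class TestSimilarityGate:
    @pytest.mark.parametrize("sim,expected", [(0.71, True), (0.7, True),
                                              (0.42, False), (1.0, True)])
    def test_floor_is_inclusive(self, sim, expected):
        assert similarity_gate(sim) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            similarity_gate(1.5)


class TestSmoothMask:
    def mask(self, data):
        return BinaryMask(np.asarray(data, dtype=np.uint8), (1, 1, 1),
                          (0, 0, 0))

    def test_all_ones_unchanged_in_interior(self):
        m = self.mask(np.ones((10, 10, 10)))
        out = smooth_mask(m)
        # interior stays solid (boundary voxels may erode at the array edge)
        np.testing.assert_array_equal(out.data[2:-2, 2:-2, 2:-2], 1)

    def test_isolated_voxel_removed(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1
        assert smooth_mask(self.mask(data), repeats=1).voxel_count == 0

    def test_solid_cube_volume_stable(self):
        data = np.zeros((30, 30, 30))
        data[5:25, 5:25, 5:25] = 1  # 20^3 cube
        out = smooth_mask(self.mask(data), kernel=3, repeats=3)
        assert abs(out.voxel_count / 8000 - 1) < 0.05

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        data = (rng.uniform(size=(12, 12, 12)) > 0.4).astype(np.uint8)
        a = smooth_mask(self.mask(data))
        b = smooth_mask(self.mask(data))
        np.testing.assert_array_equal(a.data, b.data)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth_mask(self.mask(np.ones((5, 5, 5))), kernel=4)


class TestRenderOverlay:
    def _pair(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.uniform(0, 255, (16, 16, 16)), (1, 1, 1), (0, 0, 0))
        data = np.zeros((16, 16, 16), dtype=np.uint8)
        data[5:11, 5:11, 5:11] = 1
        return v, BinaryMask(data, (1, 1, 1), (0, 0, 0))

    def test_three_planes_written(self, tmp_path):
        v, m = self._pair()
        files = render_overlay(v, m, tmp_path, subject_id="s01")
        assert len(files) == 3
        assert all(p.exists() for p in files)
        assert {p.name for p in files} == {"s01_axial.png", "s01_coronal.png",
                                           "s01_sagittal.png"}

    def test_empty_mask_warns_but_writes(self, tmp_path):
        v, _ = self._pair()
        empty = BinaryMask(np.zeros((16, 16, 16), dtype=np.uint8), (1, 1, 1),
                           (0, 0, 0))
        with pytest.warns(UserWarning, match="empty mask"):
            files = render_overlay(v, empty, tmp_path, subject_id="s02")
        assert len(files) == 3

    def test_slice_out_of_range(self, tmp_path):
        v, m = self._pair()
        with pytest.raises(IndexError):
            render_overlay(v, m, tmp_path, slice_index=99)
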