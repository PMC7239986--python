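"""SBR quantification: reference scaling, ROI mean, hottest voxels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import datsbr as d
from datsbr.phantom import ROIMask, VolumeImage
from datsbr.quant import hv_voxel_count


def cube(values, voxel=2.0):
    return VolumeImage(np.asarray(values, dtype=float), voxel)


def mask_from(volume_shape, idx, voxel=2.0, name="m"):
    m = np.zeros(volume_shape, dtype=bool)
    m[idx] = True
    return ROIMask(m, voxel, name)


class TestScaleToReference:
    def test_hand_computed_percentile_and_scaling(self):
        # reference intensities {1,2,3,4}: 75th pct by linear interpolation
        data = np.zeros((4, 4, 4))
        data[0, 0, :4] = [1, 2, 3, 4]
        data[1, 1, 1] = 6.5
        vol = cube(data)
        ref = mask_from(vol.shape, (0, 0, slice(0, 4)), name="reference")
        out = d.scale_to_reference(vol, ref, 75.0)
        assert out.data[1, 1, 1] == pytest.approx(6.5 / 3.25)
        assert out.data[1, 1, 1] == pytest.approx(2.0)
        # the reference percentile of the output is exactly 1
        assert np.percentile(out.data[ref.data], 75.0) == pytest.approx(1.0)

    def test_uniform_volume_scales_to_one(self):
        vol = cube(np.full((3, 3, 3), 7.0))
        ref = mask_from(vol.shape, (slice(None),) * 3, name="reference")
        assert np.allclose(d.scale_to_reference(vol, ref).data, 1.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_global_rescaling_is_invisible(self, c):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.5, 3.0, size=(5, 5, 5))
        ref = mask_from(data.shape, (slice(0, 2),) * 3, name="reference")
        base = d.scale_to_reference(cube(data), ref)
        scaled = d.scale_to_reference(cube(c * data), ref)
        np.testing.assert_allclose(scaled.data, base.data, rtol=1e-12)

    def test_degenerate_reference_rejected(self):
        vol = cube(np.zeros((3, 3, 3)))
        ref = mask_from(vol.shape, (0, 0, 0), name="reference")
        with pytest.raises(ValueError, match="positive"):
            d.scale_to_reference(vol, ref)

    def test_grid_mismatch_rejected(self):
        vol = cube(np.ones((3, 3, 3)), voxel=2.0)
        ref = mask_from((3, 3, 3), (0, 0, 0), voxel=3.0, name="reference")
        with pytest.raises(ValueError, match="does not match"):
            d.scale_to_reference(vol, ref)


class TestRoiSbr:
    def test_arithmetic(self):
        data = np.ones((3, 3, 3))
        data[0, 0, :3] = [1, 2, 3]
        vol = cube(data)
        roi = mask_from(vol.shape, (0, 0, slice(0, 3)))
        assert d.roi_sbr(vol, roi) == pytest.approx(1.0)

    def test_reference_level_tissue_is_zero(self):
        vol = cube(np.ones((3, 3, 3)))
        roi = mask_from(vol.shape, (slice(None),) * 3)
        assert d.roi_sbr(vol, roi) == 0.0

    def test_constant_roi(self):
        vol = cube(np.full((2, 2, 2), 3.0))
        roi = mask_from(vol.shape, (0, 0, 0))
        assert d.roi_sbr(vol, roi) == pytest.approx(2.0)


class TestHvSbr:
    def test_matches_exhaustive_max_mean_subset_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            data = rng.uniform(0.0, 2.0, size=(4, 4, 4))
            vol = cube(data)
            m = np.zeros(vol.shape, dtype=bool)
            flat = rng.choice(64, size=12, replace=False)
            m.flat[flat] = True
            roi = ROIMask(m, 2.0, "big")
            k = 5
            target_ml = k * vol.voxel_volume_ml
            vals = vol.data[m]
            best = max(
                vals[list(combo)].mean()
                for combo in itertools.combinations(range(12), k)
            )
            assert d.hv_sbr(vol, roi, target_ml) == pytest.approx(best - 1.0)

    def test_full_roi_target_equals_roi_mean(self):
        rng = np.random.default_rng(1)
        vol = cube(rng.uniform(0.5, 2.0, size=(4, 4, 4)))
        roi = mask_from(vol.shape, (slice(0, 2),) * 3)
        target = roi.volume_ml
        assert d.hv_sbr(vol, roi, target) == pytest.approx(d.roi_sbr(vol, roi))

    def test_non_increasing_in_target_volume(self):
        rng = np.random.default_rng(2)
        vol = cube(rng.uniform(0.5, 2.0, size=(5, 5, 5)))
        roi = mask_from(vol.shape, (slice(None),) * 3)
        vv = vol.voxel_volume_ml
        sbrs = [d.hv_sbr(vol, roi, k * vv) for k in range(1, 126, 10)]
        assert all(a >= b - 1e-12 for a, b in zip(sbrs, sbrs[1:]))

    def test_tie_break_by_ascending_flat_index(self):
        data = np.ones((2, 2, 2))
        data.flat[[0, 3, 5]] = 2.0  # three tied hottest voxels
        vol = cube(data)
        roi = mask_from(vol.shape, (slice(None),) * 3)
        # k=4: three tied at 2.0 plus the lowest-index 1.0 voxel
        assert d.hv_sbr(vol, roi, 4 * vol.voxel_volume_ml) == pytest.approx(
            (2.0 + 2.0 + 2.0 + 1.0) / 4 - 1.0
        )

    def test_undersized_big_roi_rejected(self):
        vol = cube(np.ones((3, 3, 3)))
        roi = mask_from(vol.shape, (0, 0, 0), name="big")
        with pytest.raises(ValueError, match="smaller than"):
            d.hv_sbr(vol, roi, 10.0)

    def test_default_voxel_count_is_1250_on_2mm_grid(self):
        assert hv_voxel_count(10.0, 2.0) == 1250


class TestBilateralMin:
    @pytest.mark.parametrize("l, r, expect", [(2.1, 1.4, 1.4), (0.7, 0.7, 0.7),
                                              (1.4, 2.1, 1.4)])
    def test_returns_smaller_side(self, l, r, expect):
        assert d.bilateral_min(l, r) == expect

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="both"):
            d.bilateral_min(None, 1.0)

    def test_picks_contralateral_deficit_on_phantom(self, sharp_phantom):
        vol, masks = sharp_phantom  # putamen_L at 0.5, putamen_R at 1.5
        q = d.quantify_volume(vol, masks)
        assert q["aal"] == pytest.approx(0.5, abs=1e-12)
        assert q["aal"] == q["aal_L"] < q["aal_R"]
        assert q["hv"] == q["hv_L"] < q["hv_R"]
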