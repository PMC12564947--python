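"""Error maps, adaptive thresholding, ROI restriction, batch segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boluseg.preprocess import build_roi_mask
from boluseg.segmenter import (
    ThresholdCalibration,
    apply_threshold,
    calibrate_threshold,
    reconstruction_error,
    segment,
    segment_dataset,
)
from conftest import IdentityModel


class TestReconstructionError:
    def test_identity_reconstruction_gives_zero_map(self, identity_model, rng):
        x = rng.random((2, 16, 16, 5)).astype(np.float32)
        err = reconstruction_error(x, identity_model)
        assert err.shape == (2, 16, 16)
        assert np.all(err == 0.0)

    def test_single_channel_offset_divided_by_three(self, rng):
        class OneChannelOffset(IdentityModel):
            def predict(self, x, batch_size=16):
                r = x[..., :3].copy()
                r[..., 0] += 0.2
                return r

        x = rng.random((1, 8, 8, 5)).astype(np.float32) * 0.5
        err = reconstruction_error(x, OneChannelOffset())
        np.testing.assert_allclose(err, 0.2 / 3, rtol=1e-6)

    def test_matches_brute_force_per_pixel(self, rng):
        x = rng.random((1, 8, 8, 5)).astype(np.float32)
        model = IdentityModel(offset=0.0)
        recon = model.predict(x)
        err = reconstruction_error(x, model)[0]
        for i in range(8):
            for j in range(8):
                brute = np.mean([abs(float(x[0, i, j, c]) - float(recon[0, i, j, c])) for c in range(3)])
                assert err[i, j] == pytest.approx(brute, abs=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            reconstruction_error(rng.random((1, 8, 8, 4)), IdentityModel(in_channels=5))


class TestCalibrateThreshold:
    def test_constant_error_maps_give_their_level(self, rng):
        x = np.full((3, 8, 8, 5), 0.5, dtype=np.float32)
        model = IdentityModel(offset=0.05)  # every image channel off by 0.05
        cal = calibrate_threshold(model, x, multiplier=1.0)
        assert cal.tau == pytest.approx(0.05, rel=1e-6)
        assert cal.n_validation_frames == 3

    def test_multiplier_scales_linearly(self, rng):
        x = rng.random((4, 8, 8, 5)).astype(np.float32)
        model = IdentityModel(offset=0.1)
        tau1 = calibrate_threshold(model, x, multiplier=1.0).tau
        tau2 = calibrate_threshold(model, x, multiplier=2.0).tau
        assert tau2 == pytest.approx(2 * tau1, rel=1e-12)

    def test_pooled_mean_oracle_inside_roi(self, rng):
        x = rng.random((5, 16, 16, 5)).astype(np.float32)
        model = IdentityModel(offset=0.07)
        roi = build_roi_mask(16, 16, (0.1, 0.1, 0.1))
        cal = calibrate_threshold(model, x, roi=roi)
        errs = reconstruction_error(x, model)
        brute = float(np.mean([e[roi.mask] for e in errs]))
        assert cal.tau == pytest.approx(brute, rel=1e-12)

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(IdentityModel(), np.zeros((0, 8, 8, 5), dtype=np.float32))

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            ThresholdCalibration(tau=-0.1, multiplier=1.0, n_validation_frames=1)


class TestApplyThreshold:
    def test_zero_error_map_gives_empty_mask(self):
        assert not apply_threshold(np.zeros((16, 16)), tau=0.0).any()

    def test_square_above_tau_recovered_exactly(self):
        err = np.zeros((20, 20))
        err[8:13, 8:13] = 0.11
        roi = build_roi_mask(20, 20, (0.1, 0.1, 0.1))
        mask = apply_threshold(err, tau=0.1, roi=roi)
        expected = np.zeros((20, 20), dtype=bool)
        expected[8:13, 8:13] = True
        np.testing.assert_array_equal(mask, expected)

    def test_min_component_area_removes_small_blob(self):
        err = np.zeros((20, 20))
        err[8:13, 8:13] = 0.11  # 25-pixel component
        assert not apply_threshold(err, tau=0.1, min_component_area=30).any()
        assert apply_threshold(err, tau=0.1, min_component_area=25).sum() == 25

    @settings(deadline=None, max_examples=25)
    @given(tau_lo=st.floats(0, 0.5), dtau=st.floats(0.001, 0.5))
    def test_monotone_in_tau(self, tau_lo, dtau):
        err = np.random.default_rng(0).random((16, 16))
        lo = apply_threshold(err, tau=tau_lo)
        hi = apply_threshold(err, tau=tau_lo + dtau)
        assert not (hi & ~lo).any()  # raising tau never adds pixels

    def test_roi_containment(self, rng):
        err = rng.random((16, 16))
        roi = build_roi_mask(16, 16, (0.2, 0.2, 0.2))
        mask = apply_threshold(err, tau=0.1, roi=roi)
        assert not (mask & ~roi.mask).any()


class TestSegmentDataset:
    def test_ten_frames_split_one_to_nine(self, rng):
        x = rng.random((10, 16, 16, 5)).astype(np.float32)
        run = segment_dataset(x, IdentityModel(offset=0.05), seed=0)
        assert len(run.calibration_indices) == 1
        assert len(run.masks) == len(run.segmented_indices) == 9

    def test_same_seed_reproduces_split_and_masks(self, rng):
        x = rng.random((10, 16, 16, 5)).astype(np.float32)
        runs = [segment_dataset(x, IdentityModel(offset=0.05), seed=4) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].calibration_indices, runs[1].calibration_indices)
        for a, b in zip(runs[0].masks, runs[1].masks):
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_masks_written_to_disk(self, rng, tmp_path):
        x = rng.random((10, 16, 16, 5)).astype(np.float32)
        run = segment_dataset(x, IdentityModel(offset=0.05), seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.json").exists()
        assert len(list(tmp_path.glob("mask_*.png"))) == len(run.masks)

    def test_provenance_recorded(self, rng):
        x = rng.random((4, 16, 16, 5)).astype(np.float32)
        roi = build_roi_mask(16, 16, (0.1, 0.1, 0.1))
        cal = calibrate_threshold(IdentityModel(offset=0.05), x, roi=roi)
        sm = segment(x[0], IdentityModel(offset=0.05), cal, roi=roi)
        assert sm.roi_applied
        assert sm.provenance["tau"] == cal.tau
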