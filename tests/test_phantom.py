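"""Phantom generator: statistical fidelity, determinism, exact ground truth."""

import dataclasses

import numpy as np
import pytest
from skimage.measure import label

from boluseg.phantom import (
    AnomalySpec,
    PhantomFrame,
    PhantomSpec,
    build_mean_field,
    generate_dataset,
    inject_anomaly,
    sample_background_frame,
)


class TestMeanField:
    def test_no_blobs_gives_constant_base_intensity(self):
        spec = PhantomSpec(n_blobs=0, base_intensity=0.35)
        field = build_mean_field(spec)
        assert field.shape == (64, 64, 3)
        assert np.all(field == 0.35)

    def test_same_seed_is_bit_identical(self):
        spec = PhantomSpec(seed=7)
        np.testing.assert_array_equal(build_mean_field(spec), build_mean_field(spec))

    def test_channels_identical_and_in_range(self):
        field = build_mean_field(PhantomSpec(seed=3))
        np.testing.assert_array_equal(field[:, :, 0], field[:, :, 1])
        np.testing.assert_array_equal(field[:, :, 0], field[:, :, 2])
        assert field.min() >= 0.0 and field.max() <= 1.0

    def test_location_carries_information(self):
        # two disjoint regions must differ in mean appearance by >= 0.2
        field = build_mean_field(PhantomSpec(seed=11))
        assert field.max() - field.min() >= 0.2

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(height=4, width=64)

    def test_empirical_mean_recovers_field(self):
        # Monte-Carlo check against the generating field: with no jitter the
        # per-pixel mean over 500 frames has standard error sigma/sqrt(500);
        # ~99.7% of (unclipped) pixels must sit within 3 standard errors and
        # every pixel within 4.5 (the strict per-pixel 3-SE bound is expected
        # to fail on ~0.3% of several thousand pixels).
        spec = PhantomSpec(height=64, width=64, n_blobs=5, noise_sigma=0.05, jitter_px=0, amp_jitter=0.0, seed=1)
        field = build_mean_field(spec)
        rng = np.random.default_rng(42)
        n = 500
        acc = np.zeros_like(field)
        for _ in range(n):
            acc += sample_background_frame(field, spec, rng).image
        emp_mean = acc / n
        se = spec.noise_sigma / np.sqrt(n)
        interior = (field[:, :, 0] > 3 * spec.noise_sigma) & (field[:, :, 0] < 1 - 3 * spec.noise_sigma)
        assert interior.mean() > 0.5  # the check must cover most of the frame
        dev = np.abs(emp_mean[interior] - field[interior])
        assert (dev <= 3 * se).mean() > 0.99
        assert np.all(dev <= 4.5 * se)


class TestBackgroundFrames:
    def test_noiseless_limit_equals_field(self):
        # all stochastic ingredients off: the frame is exactly the mean field
        spec = PhantomSpec(noise_sigma=0.0, jitter_px=0, amp_jitter=0.0, seed=0)
        field = build_mean_field(spec)
        frame = sample_background_frame(field, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(frame.image, field)
        assert not frame.has_anomaly and not frame.mask.any()

    def test_noise_std_matches_parameter(self):
        spec = PhantomSpec(noise_sigma=0.05, jitter_px=0, seed=2, base_intensity=0.5, n_blobs=0)
        field = build_mean_field(spec)
        rng = np.random.default_rng(3)
        devs = [sample_background_frame(field, spec, rng).image[:, :, 0] - field[:, :, 0] for _ in range(200)]
        sd = np.std(np.stack(devs))
        assert abs(sd - 0.05) / 0.05 < 0.10

    def test_fixed_stream_replays_identically(self):
        spec = PhantomSpec(seed=5)
        field = build_mean_field(spec)
        f1 = sample_background_frame(field, spec, np.random.default_rng(99))
        f2 = sample_background_frame(field, spec, np.random.default_rng(99))
        np.testing.assert_array_equal(f1.image, f2.image)


class TestInjectAnomaly:
    @pytest.fixture
    def clean(self):
        spec = PhantomSpec(noise_sigma=0.0, jitter_px=0, amp_jitter=0.0, seed=4)
        field = build_mean_field(spec)
        return sample_background_frame(field, spec, np.random.default_rng(0)), field

    def test_null_anomaly_marks_mask_but_leaves_image(self, clean):
        frame, field = clean
        anomaly = AnomalySpec(semi_axes=(5, 3), delta=0.0, mode="additive")
        out = inject_anomaly(frame, anomaly, field, np.random.default_rng(1))
        np.testing.assert_array_equal(out.image, frame.image)
        assert out.has_anomaly and out.mask.any()

    def test_additive_delta_applied_exactly_on_mask(self, clean):
        frame, field = clean
        anomaly = AnomalySpec(semi_axes=(5, 3), delta=0.4, mode="additive")
        out = inject_anomaly(frame, anomaly, field, np.random.default_rng(1))
        diff = out.image - frame.image
        # exact where clipping cannot bite (field + 0.4 <= 1)
        safe = out.mask & (frame.image[:, :, 0] <= 0.6)
        assert safe.any()
        assert np.allclose(diff[safe], 0.4)
        assert np.all(diff[~out.mask] == 0.0)

    def test_transplanted_mean_matches_source_region(self):
        spec = PhantomSpec(noise_sigma=0.0, jitter_px=0, amp_jitter=0.0, seed=8)
        field = build_mean_field(spec)
        frame = sample_background_frame(field, spec, np.random.default_rng(0))
        anomaly = AnomalySpec(semi_axes=(5, 3), mode="transplanted")
        out = inject_anomaly(frame, anomaly, field, np.random.default_rng(2))
        # transplanted pixels are mean-field values read elsewhere: every
        # in-mask intensity must occur in the field, and on a noiseless frame
        # the in-mask image is not simply the local field
        vals = out.image[out.mask]
        assert np.all((vals >= field.min()) & (vals <= field.max()))
        assert not np.allclose(out.image[out.mask], field[out.mask])

    def test_anomalous_frame_rejected_as_input(self, clean):
        frame, field = clean
        anomaly = AnomalySpec(semi_axes=(5, 3))
        out = inject_anomaly(frame, anomaly, field, np.random.default_rng(1))
        with pytest.raises(ValueError):
            inject_anomaly(out, anomaly, field, np.random.default_rng(1))

    def test_oversized_anomaly_reports_error(self, clean):
        frame, field = clean
        anomaly = AnomalySpec(semi_axes=(40, 40), center_region=(30, 30, 34, 34))
        with pytest.raises(RuntimeError):
            inject_anomaly(frame, anomaly, field, np.random.default_rng(1))


class TestGenerateDataset:
    def test_training_split_is_anomaly_free(self, small_dataset):
        assert all(not f.has_anomaly and not f.mask.any() for f in small_dataset.train)

    def test_no_anomalous_test_frames_means_no_nonzero_masks(self):
        spec = PhantomSpec(height=32, width=32, seed=1)
        ds = generate_dataset(spec, AnomalySpec(semi_axes=(4, 3)), 10, 4, 0, seed=1)
        assert all(not f.mask.any() for f in ds.test)

    def test_anomalous_masks_have_one_component_each(self):
        spec = PhantomSpec(height=48, width=48, seed=2)
        anomaly = AnomalySpec(semi_axes=(5, 4), count_per_frame=1)
        ds = generate_dataset(spec, anomaly, 0, 0, 20, seed=2)
        masks = [f.mask for f in ds.test if f.has_anomaly]
        assert len(masks) == 20
        # independent component count via the standard labeling oracle
        assert all(label(m, connectivity=2).max() == 1 for m in masks)

    def test_same_seed_writes_byte_identical_datasets(self, tmp_path):
        spec = PhantomSpec(height=32, width=32, seed=3)
        anomaly = AnomalySpec(semi_axes=(4, 3))
        for d in ("a", "b"):
            generate_dataset(spec, anomaly, 3, 2, 2, seed=3, out_dir=tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*"))
        files_b = sorted((tmp_path / "b").rglob("*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            if fa.is_file():
                assert fa.read_bytes() == fb.read_bytes()

    def test_mask_invariant_enforced(self):
        with pytest.raises(ValueError):
            PhantomFrame(image=np.zeros((16, 16, 3)), mask=np.ones((16, 16), bool), has_anomaly=False)
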