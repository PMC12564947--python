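"""From trained model to binary masks: error maps, adaptive threshold, ROI.

The per-pixel reconstruction error (mean absolute input-reconstruction
difference over the image channels) is thresholded at tau = k * (pooled mean
error), where the pooled mean is computed over the ROI pixels of a seeded
validation subset of the evaluation frames.  Thresholded masks are restricted
to the ROI and, optionally, cleaned of connected components smaller than a
minimum area (8-connectivity).  Calibration frames are flagged so downstream
evaluation can exclude them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.morphology import remove_small_objects

from .nn import Autoencoder
from .preprocess import EncodedInput, RoiMask

__all__ = [
    "ThresholdCalibration",
    "SegmentationMask",
    "SegmentationRun",
    "reconstruction_error",
    "calibrate_threshold",
    "apply_threshold",
    "segment",
    "segment_dataset",
]


@dataclass(frozen=True)
class ThresholdCalibration:
    tau: float
    multiplier: float
    n_validation_frames: int

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")


@dataclass
class SegmentationMask:
    mask: np.ndarray  # (H, W) bool
    roi_applied: bool
    provenance: dict


def _as_batch(inputs) -> np.ndarray:
    if isinstance(inputs, EncodedInput):
        inputs = inputs.channels
    inputs = np.asarray(inputs, dtype=np.float32)
    if inputs.ndim == 3:
        return inputs[None]
    if inputs.ndim == 4:
        return inputs
    raise ValueError(f"expected (H,W,C) or (N,H,W,C) encoded input, got shape {inputs.shape}")


def reconstruction_error(encoded_input, model: Autoencoder) -> np.ndarray:
    """Per-pixel mean over the image channels of |input - reconstruction|.

    Accepts a single encoded frame or a batch; returns (H, W) or (N, H, W)
    nonnegative error maps.
    """
    raw = encoded_input.channels if isinstance(encoded_input, EncodedInput) else np.asarray(encoded_input)
    single = raw.ndim == 3
    batch = _as_batch(encoded_input)
    if batch.shape[-1] != model.in_channels:
        raise ValueError(f"model expects {model.in_channels} channels, input has {batch.shape[-1]}")
    recon = model.predict(batch)
    err = np.abs(batch[..., : model.out_channels].astype(np.float64) - recon.astype(np.float64)).mean(axis=-1)
    return err[0] if single else err


def calibrate_threshold(
    model: Autoencoder,
    validation_frames,
    multiplier: float = 1.0,
    roi: RoiMask | None = None,
) -> ThresholdCalibration:
    """tau = multiplier x pooled per-pixel mean error over the validation frames.

    Pooling is restricted to ROI pixels when a ROI mask is given, so border
    regions excluded from analysis do not bias the threshold.
    """
    batch = _as_batch(validation_frames)
    if len(batch) == 0:
        raise ValueError("validation set is empty")
    errs = reconstruction_error(batch, model)
    pooled = errs[:, roi.mask].mean() if roi is not None else errs.mean()
    return ThresholdCalibration(tau=float(multiplier * pooled), multiplier=multiplier, n_validation_frames=len(batch))


def apply_threshold(
    error_map: np.ndarray,
    tau: float,
    roi: RoiMask | None = None,
    min_component_area: int = 0,
) -> np.ndarray:
    """Binary mask = (error > tau) AND ROI, minus small connected components.

    Components are 8-connected; those with fewer than ``min_component_area``
    pixels are removed when the area is positive.  Deterministic, and
    monotone in tau: raising the threshold never adds pixels.
    """
    mask = np.asarray(error_map) > tau
    if roi is not None:
        mask &= roi.mask
    if min_component_area > 0:
        # keep components of at least min_component_area pixels
        mask = remove_small_objects(mask, max_size=min_component_area - 1, connectivity=2)
    return mask


def segment(
    frame,
    model: Autoencoder,
    calibration: ThresholdCalibration,
    roi: RoiMask | None = None,
    min_component_area: int = 0,
) -> SegmentationMask:
    """Segment one encoded frame with a calibrated threshold."""
    err = reconstruction_error(_as_batch(frame), model)[0]
    mask = apply_threshold(err, calibration.tau, roi, min_component_area)
    return SegmentationMask(
        mask=mask,
        roi_applied=roi is not None,
        provenance={
            "tau": calibration.tau,
            "multiplier": calibration.multiplier,
            "min_component_area": min_component_area,
            "roi_margins": list(roi.margins) if roi is not None else None,
        },
    )


@dataclass
class SegmentationRun:
    """Batch segmentation output: one mask per non-calibration frame."""

    calibration: ThresholdCalibration
    calibration_indices: np.ndarray  # frames consumed by threshold calibration
    segmented_indices: np.ndarray  # frames actually segmented (the rest)
    masks: list[SegmentationMask]


def segment_dataset(
    inputs,
    model: Autoencoder,
    roi: RoiMask | None = None,
    multiplier: float = 1.0,
    calibration_fraction: float = 0.1,
    min_component_area: int = 0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SegmentationRun:
    """Calibrate once on a seeded fraction of the frames, segment the rest.

    The calibration frames are excluded from the segmented output (and should
    be excluded from any downstream evaluation).  With the default fraction,
    10 frames yield exactly 1 calibration frame and 9 masks.
    """
    batch = _as_batch(inputs)
    n = len(batch)
    if n == 0:
        raise ValueError("no frames to segment")
    rng = np.random.default_rng(seed)
    n_cal = max(1, int(round(calibration_fraction * n))) if calibration_fraction > 0 else 0
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_cal])
    seg_idx = np.sort(perm[n_cal:])
    if len(seg_idx) == 0:
        raise ValueError("calibration fraction leaves no frames to segment")
    if n_cal == 0:
        raise ValueError("calibration requires a positive fraction of frames")

    calibration = calibrate_threshold(model, batch[cal_idx], multiplier=multiplier, roi=roi)
    masks = [segment(batch[i], model, calibration, roi, min_component_area) for i in seg_idx]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, sm in zip(seg_idx, masks):
            try:
                iio.imwrite(out_dir / f"mask_{i:06d}.png", sm.mask.astype(np.uint8) * 255)
            except OSError as exc:  # pragma: no cover - disk-dependent
                raise OSError(f"failed writing mask {i} under {out_dir}: {exc}") from exc
        manifest = {
            "tau": calibration.tau,
            "multiplier": multiplier,
            "seed": seed,
            "calibration_fraction": calibration_fraction,
            "min_component_area": min_component_area,
            "roi_margins": list(roi.margins) if roi is not None else None,
            "calibration_indices": [int(i) for i in cal_idx],
            "segmented_indices": [int(i) for i in seg_idx],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return SegmentationRun(
        calibration=calibration, calibration_indices=cal_idx, segmented_indices=seg_idx, masks=masks
    )
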