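"""Scikit-learn style estimator wrapping the full anomaly-segmentation pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .metrics import confusion, iou
from .model import LossConfig, ModelConfig, build_autoencoder
from .preprocess import PreprocessConfig, assemble_input, build_roi_mask
from .segmenter import apply_threshold, calibrate_threshold, reconstruction_error
from .trainer import TrainConfig, train

__all__ = ["AutoencoderAnomalySegmenter"]


class AutoencoderAnomalySegmenter(BaseEstimator):
    """Unsupervised reconstruction-anomaly segmenter.

    ``fit`` trains a convolutional autoencoder on anomaly-free frames;
    ``transform`` returns per-pixel reconstruction-error maps; ``predict``
    thresholds them into binary masks inside a geometric ROI.  The threshold
    is tau = multiplier x pooled mean error over a calibration subset — set
    it explicitly with :meth:`calibrate`, otherwise ``predict`` calibrates on
    a seeded ``calibration_fraction`` of the frames it is given.

    Frames are (N, H, W) or (N, H, W, 3) arrays of intensities in [0, 1]
    with H and W divisible by 8.  With ``use_pe`` the two sinusoidal
    positional channels are appended internally, giving the model the spatial
    context needed to flag appearance that is familiar but in the wrong
    place.

    Examples
    --------
    >>> seg = AutoencoderAnomalySegmenter(epochs=5, encoder_widths=(8, 16, 32))
    >>> seg.fit(clean_frames)                    # doctest: +SKIP
    >>> masks = seg.predict(test_frames)         # doctest: +SKIP
    """

    def __init__(
        self,
        use_pe: bool = True,
        encoder_widths: tuple[int, int, int] = (64, 128, 256),
        dropout_rate: float = 0.1,
        lambda_edge: float = 0.05,
        learning_rate: float = 0.01,
        batch_size: int = 16,
        epochs: int = 100,
        noise_aug_sigma: float = 0.02,
        validation_fraction: float = 0.1,
        threshold_multiplier: float = 1.0,
        roi_margins: tuple[float, float, float] = (0.10, 0.10, 0.10),
        min_component_area: int = 0,
        calibration_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.use_pe = use_pe
        self.encoder_widths = encoder_widths
        self.dropout_rate = dropout_rate
        self.lambda_edge = lambda_edge
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.noise_aug_sigma = noise_aug_sigma
        self.validation_fraction = validation_fraction
        self.threshold_multiplier = threshold_multiplier
        self.roi_margins = roi_margins
        self.min_component_area = min_component_area
        self.calibration_fraction = calibration_fraction
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim not in (3, 4):
            raise ValueError(f"expected (N,H,W) or (N,H,W,3) frames, got shape {X.shape}")
        cfg = PreprocessConfig(use_pe=self.use_pe)
        return np.stack([assemble_input(frame, cfg).channels for frame in X]).astype(np.float32)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("this AutoencoderAnomalySegmenter instance is not fitted yet")

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        """Train on anomaly-free frames; ``y`` is ignored (unsupervised)."""
        inputs = self._encode(X)
        model_cfg = ModelConfig(
            in_channels=5 if self.use_pe else 3,
            encoder_widths=tuple(self.encoder_widths),
            dropout_rate=self.dropout_rate,
        )
        self.model_ = build_autoencoder(model_cfg, seed=self.random_state + 1)
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            noise_aug_sigma=self.noise_aug_sigma,
            validation_fraction=self.validation_fraction,
            seed=self.random_state + 2,
            loss=LossConfig(lambda_edge=self.lambda_edge),
        )
        self.train_result_ = train(self.model_, inputs, train_cfg)
        h, w = inputs.shape[1:3]
        self.image_shape_ = (h, w)
        self.roi_ = build_roi_mask(h, w, tuple(self.roi_margins))
        return self

    def transform(self, X) -> np.ndarray:
        """Per-pixel reconstruction-error maps, shape (N, H, W)."""
        self._check_fitted()
        return reconstruction_error(self._encode(X), self.model_)

    def calibrate(self, X):
        """Set the threshold from a validation set of frames; returns self."""
        self._check_fitted()
        self.calibration_ = calibrate_threshold(
            self.model_, self._encode(X), multiplier=self.threshold_multiplier, roi=self.roi_
        )
        self.tau_ = self.calibration_.tau
        return self

    def predict(self, X) -> np.ndarray:
        """Binary anomaly masks, shape (N, H, W).

        If :meth:`calibrate` has not been called, a seeded
        ``calibration_fraction`` of ``X`` calibrates the threshold first (all
        frames are still segmented and returned).
        """
        self._check_fitted()
        if not hasattr(self, "calibration_"):
            rng = np.random.default_rng(self.random_state + 3)
            n = len(X)
            n_cal = max(1, int(round(self.calibration_fraction * n)))
            idx = rng.permutation(n)[:n_cal]
            self.calibrate(np.asarray(X)[idx])
        errs = self.transform(X)
        return np.stack(
            [apply_threshold(e, self.tau_, self.roi_, self.min_component_area) for e in errs]
        )

    def score(self, X, y) -> float:
        """Mean per-frame IoU against ground-truth masks (undefined frames excluded)."""
        preds = self.predict(X)
        vals = [iou(confusion(p, g, self.roi_)) for p, g in zip(preds, np.asarray(y))]
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            raise ValueError("IoU undefined on every frame (no positives anywhere)")
        return float(np.mean(vals))
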