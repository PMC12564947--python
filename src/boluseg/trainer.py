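"""Training loop: Adam, plateau scheduling, Gaussian-noise augmentation.

The model is trained only on anomaly-free frames so that it learns the
location-conditioned background appearance; anything it cannot reconstruct at
inference is a candidate anomaly.  Augmentation is denoising-style: light
Gaussian noise is added to the image channels of each input (never to the
positional channels, which encode coordinates rather than appearance) while
the target stays the clean frame.  Geometric augmentations are deliberately
absent — flipping or rotating a frame would break the pairing between image
content and the fixed positional encoding.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from .model import LossConfig, total_loss_grad
from .nn import Adam, Autoencoder, ReduceLROnPlateau

__all__ = ["TrainConfig", "TrainResult", "train", "add_gaussian_noise", "AUGMENTATIONS"]

# the complete augmentation registry: intensity noise only, no flips/rotations
AUGMENTATIONS: tuple[str, ...] = ("gaussian_noise",)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 16
    epochs: int = 100
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    noise_aug_sigma: float = 0.02
    validation_fraction: float = 0.1  # held-out share of the *training* frames
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if not 0.0 <= self.noise_aug_sigma < 1.0:
            raise ValueError("noise_aug_sigma must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


@dataclass
class TrainResult:
    """Weights of the lowest monitored-loss epoch plus the full history."""

    best_weights: dict[str, np.ndarray]
    history: dict[str, list[float]]  # train_loss, monitored_loss, lr per epoch
    best_epoch: int  # 0-based index into the history


def add_gaussian_noise(images: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. N(0, sigma^2) per element, clipped back to [0, 1].

    ``sigma=0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return images
    noise = rng.normal(0.0, sigma, size=images.shape)
    return np.clip(images + noise, 0.0, 1.0).astype(images.dtype, copy=False)


def _epoch_loss(model: Autoencoder, inputs: np.ndarray, lam: float, batch_size: int) -> float:
    """Evaluation-mode hybrid loss of clean inputs against their image channels."""
    total, n = 0.0, 0
    for i in range(0, len(inputs), batch_size):
        batch = inputs[i : i + batch_size]
        recon = model.forward(batch, training=False)
        value, _ = total_loss_grad(batch[..., :3], recon, lam)
        total += value * len(batch)
        n += len(batch)
    return total / n


def train(
    model: Autoencoder,
    inputs: np.ndarray,
    config: TrainConfig,
    masks: np.ndarray | None = None,
) -> TrainResult:
    """Fit the autoencoder to anomaly-free encoded frames.

    ``inputs`` is (N, H, W, C) with image channels first and any positional
    channels last; ``masks``, when provided, asserts the anomaly-free training
    contract (any nonzero mask aborts).  A seeded fraction of the training
    frames is held out to monitor the plateau scheduler, which halves the
    learning rate after ``plateau_patience`` epochs without improvement.  The
    model is left holding (and the result records) the weights of the epoch
    with the lowest monitored loss.  Fully reproducible given the seed.
    """
    inputs = np.ascontiguousarray(inputs, dtype=np.float32)
    if inputs.ndim != 4 or len(inputs) == 0:
        raise ValueError("inputs must be a nonempty (N, H, W, C) array")
    if masks is not None and np.any(masks):
        raise ValueError("training frames must be anomaly-free (nonzero mask found)")

    rng = np.random.default_rng(config.seed)
    n = len(inputs)
    n_val = int(round(config.validation_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("validation split consumed every training frame")
    x_train, x_val = inputs[tr_idx], inputs[val_idx]

    optimizer = Adam(model, lr=config.learning_rate)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor, patience=config.plateau_patience)
    lam = config.loss.lambda_edge
    n_img = model.out_channels

    history: dict[str, list[float]] = {"train_loss": [], "monitored_loss": [], "lr": []}
    best_loss = np.inf
    best_weights: dict[str, np.ndarray] = model.state_dict()
    best_epoch = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = x_train[order[start : start + config.batch_size]]
            target = batch[..., :n_img]
            noisy = batch.copy()
            noisy[..., :n_img] = add_gaussian_noise(target, config.noise_aug_sigma, rng)
            recon = model.forward(noisy, training=True)
            value, grad = total_loss_grad(target, recon, lam)
            model.backward(grad)
            optimizer.step()
            epoch_loss += value * len(batch)
            seen += len(batch)
        train_loss = epoch_loss / seen
        monitored = _epoch_loss(model, x_val, lam, config.batch_size) if n_val else train_loss

        history["train_loss"].append(train_loss)
        history["monitored_loss"].append(monitored)
        history["lr"].append(optimizer.lr)
        logger.info(
            "epoch %d/%d train_loss=%.6f monitored_loss=%.6f lr=%.2e",
            epoch + 1, config.epochs, train_loss, monitored, optimizer.lr,
        )
        if monitored < best_loss:
            best_loss = monitored
            best_weights = model.state_dict()
            best_epoch = epoch
        scheduler.step(monitored)

    model.load_state_dict(best_weights)
    return TrainResult(best_weights=copy.deepcopy(best_weights), history=history, best_epoch=best_epoch)
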