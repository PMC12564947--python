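"""Autoencoder construction and the hybrid reconstruction loss.

The loss is L = L_MSE + lambda * L_edge, where L_MSE is the mean squared
pixel difference and L_edge penalizes the absolute difference between the
forward finite-difference gradients of target and reconstruction along both
spatial axes.  Both terms are normalized by their element counts so that the
edge weight lambda keeps the same meaning at any image size; the default
lambda = 0.05.  The edge term is blind to constant offsets (a gradient kills
constants) — it rewards boundary sharpness, not brightness fidelity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Autoencoder

__all__ = [
    "ModelConfig",
    "LossConfig",
    "build_autoencoder",
    "count_parameters",
    "mse_loss",
    "edge_loss",
    "total_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters; in_channels is 5 with positional encoding, 3 without."""

    in_channels: int = 5
    out_channels: int = 3
    encoder_widths: tuple[int, int, int] = (64, 128, 256)
    kernel: int = 3
    dropout_rate: float = 0.1
    # "zeros" is conventional; "circular" removes the absolute-position cue
    # that zero borders leak into deep features, making a no-PE model truly
    # location-blind (used by the phantom benchmark)
    padding: str = "zeros"

    def __post_init__(self):
        if self.in_channels not in (3, 5):
            raise ValueError("in_channels must be 3 (no PE) or 5 (with PE)")
        if len(self.encoder_widths) != 3:
            raise ValueError("encoder_widths must list three block widths")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.padding not in ("zeros", "circular"):
            raise ValueError("padding must be 'zeros' or 'circular'")


@dataclass(frozen=True)
class LossConfig:
    """Weight of the edge-preservation term in the hybrid loss."""

    lambda_edge: float = 0.05

    def __post_init__(self):
        if self.lambda_edge < 0:
            raise ValueError("lambda_edge must be nonnegative")


# trainable parameter budget of the published architecture family
PARAMETER_BUDGET = 1_710_000


def build_autoencoder(config: ModelConfig, seed: int = 0) -> Autoencoder:
    """Instantiate the encoder-decoder with seeded weight initialization."""
    return Autoencoder(
        in_channels=config.in_channels,
        widths=config.encoder_widths,
        out_channels=config.out_channels,
        kernel=config.kernel,
        dropout_rate=config.dropout_rate,
        seed=seed,
        pad_mode=config.padding,
    )


def count_parameters(model: Autoencoder) -> int:
    """Number of trainable scalars (convolution weights/biases, batchnorm affines)."""
    return model.count_parameters()


def _canon(a: np.ndarray) -> np.ndarray:
    """Accept (H,W), (H,W,C) or (N,H,W,C); return (N,H,W,C) float64."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 2:
        a = a[None, :, :, None]
    elif a.ndim == 3:
        a = a[None]
    elif a.ndim != 4:
        raise ValueError(f"expected a 2-4 dimensional array, got shape {a.shape}")
    return a


def _check_pair(target: np.ndarray, reconstruction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t, r = _canon(target), _canon(reconstruction)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch: target {t.shape} vs reconstruction {r.shape}")
    return t, r


def mse_loss(target: np.ndarray, reconstruction: np.ndarray) -> float:
    """Mean over all elements of the squared difference."""
    t, r = _check_pair(target, reconstruction)
    return float(np.mean((t - r) ** 2))


def edge_loss(target: np.ndarray, reconstruction: np.ndarray) -> float:
    """Mean absolute difference between forward-difference image gradients.

    Gradients are taken along rows and columns (the boundary row/column drops
    out of each direction); the two directions and all channels pool into a
    single mean.
    """
    t, r = _check_pair(target, reconstruction)
    gx_t = np.diff(t, axis=2)
    gx_r = np.diff(r, axis=2)
    gy_t = np.diff(t, axis=1)
    gy_r = np.diff(r, axis=1)
    total = np.abs(gx_t - gx_r).sum() + np.abs(gy_t - gy_r).sum()
    return float(total / (gx_t.size + gy_t.size))


def total_loss(
    target: np.ndarray, reconstruction: np.ndarray, loss_config: LossConfig = LossConfig()
) -> float:
    """Hybrid objective: mse_loss + lambda_edge * edge_loss."""
    return mse_loss(target, reconstruction) + loss_config.lambda_edge * edge_loss(target, reconstruction)


def total_loss_grad(
    target: np.ndarray, reconstruction: np.ndarray, lambda_edge: float
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the reconstruction (float32, NHWC).

    Used by the training loop; matches :func:`total_loss` exactly up to
    float32 arithmetic.
    """
    t = np.asarray(target, dtype=np.float32)
    r = np.asarray(reconstruction, dtype=np.float32)
    diff = r - t
    n = diff.size
    grad = (2.0 / n) * diff

    gx = np.diff(diff, axis=2)  # gx(r) - gx(t)
    gy = np.diff(diff, axis=1)
    n_edge = gx.size + gy.size
    sx = np.sign(gx) * np.float32(lambda_edge / n_edge)
    sy = np.sign(gy) * np.float32(lambda_edge / n_edge)
    grad[:, :, 1:, :] += sx
    grad[:, :, :-1, :] -= sx
    grad[:, 1:, :, :] += sy
    grad[:, :-1, :, :] -= sy

    value = float(np.mean(diff**2, dtype=np.float64)) + lambda_edge * float(
        (np.abs(gx).sum(dtype=np.float64) + np.abs(gy).sum(dtype=np.float64)) / n_edge
    )
    return value, grad.astype(np.float32)


def save_checkpoint(path: str | Path, model: Autoencoder, config: ModelConfig, extra: dict | None = None) -> None:
    """Serialize weights plus the embedded model configuration (npz)."""
    meta = {"config": asdict(config), "seed": model.seed}
    if extra:
        meta["extra"] = extra
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[Autoencoder, ModelConfig, dict]:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = dict(meta["config"])
    cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
    config = ModelConfig(**cfg_dict)
    model = build_autoencoder(config, seed=meta.get("seed", 0))
    model.load_state_dict(state)
    return model, config, meta.get("extra", {})
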