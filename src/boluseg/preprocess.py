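"""Frame preprocessing: border crop, resize, normalization, positional encoding, ROI.

The model input is the preprocessed image replicated to three channels, with
two fixed sinusoidal positional-encoding channels appended when location
awareness is enabled:

    v(x, y) = [R, G, B, sin(2*pi*x / W), cos(2*pi*y / H)]

where x indexes columns (width) and y indexes rows (height), both 0-based.
The encoding channels are functions of position only — channel 0 is constant
down each column, channel 1 constant along each row — and are fed to the
network in their natural [-1, 1] range.  Note sin/cos over one full period is
not injective: two columns (or rows) can share an encoding value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.util import img_as_float

__all__ = [
    "PreprocessConfig",
    "EncodedInput",
    "RoiMask",
    "crop_black_borders",
    "minmax_normalize",
    "positional_encoding",
    "assemble_input",
    "build_roi_mask",
    "preprocess_frame",
    "load_frame",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 256
    border_threshold: float = 0.02
    use_pe: bool = True
    roi_margins: tuple[float, float, float] = (0.10, 0.10, 0.10)  # left, right, top fractions

    def __post_init__(self):
        if self.target_size < 16:
            raise ValueError("target_size must be >= 16")
        if not 0.0 <= self.border_threshold <= 1.0:
            raise ValueError("border_threshold must lie in [0, 1]")


@dataclass
class EncodedInput:
    """Model-ready channels: 3 image channels (+2 encoding channels when enabled)."""

    channels: np.ndarray  # (H, W, C), C in {3, 5}
    crop_box: tuple[int, int, int, int]  # (row0, col0, row1, col1) kept from the original frame

    @property
    def image(self) -> np.ndarray:
        return self.channels[:, :, :3]


@dataclass
class RoiMask:
    """Rectangular region of interest excluding left/right/top frame margins.

    The bottom border is never excluded: in swallowing studies the anatomy of
    interest extends to the lower frame edge.
    """

    mask: np.ndarray  # (H, W) bool
    margins: tuple[float, float, float]


def crop_black_borders(
    image: np.ndarray, threshold: float = 0.02
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Remove maximal contiguous near-black border rows/columns.

    A border row or column qualifies when its mean intensity is at most
    ``threshold`` times the frame's maximum intensity.  Returns the cropped
    image and the retained (row0, col0, row1, col1) box; a frame with no
    qualifying border comes back unchanged with the full-frame box.
    """
    if image.size == 0:
        raise ValueError("empty image")
    intensity = image.mean(axis=2) if image.ndim == 3 else np.asarray(image, dtype=np.float64)
    h, w = intensity.shape
    cutoff = threshold * float(intensity.max())
    if float(intensity.max()) == 0.0:
        raise ValueError("entire frame is black; nothing to analyze")

    row_dark = intensity.mean(axis=1) <= cutoff
    col_dark = intensity.mean(axis=0) <= cutoff

    def leading(dark: np.ndarray) -> int:
        n = 0
        while n < len(dark) and dark[n]:
            n += 1
        return n

    r0, r1 = leading(row_dark), h - leading(row_dark[::-1])
    c0, c1 = leading(col_dark), w - leading(col_dark[::-1])
    if r0 >= r1 or c0 >= c1:
        raise ValueError("entire frame qualifies as border; frame unusable")
    return image[r0:r1, c0:c1], (r0, c0, r1, c1)


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Per-frame (I - min) / (max - min); a constant frame maps to all zeros."""
    if image.size == 0:
        raise ValueError("empty image")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def positional_encoding(height: int, width: int) -> np.ndarray:
    """(H, W, 2) grid: channel 0 = sin(2*pi*x/W), channel 1 = cos(2*pi*y/H)."""
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    x = np.arange(width, dtype=np.float64)
    y = np.arange(height, dtype=np.float64)
    pe = np.empty((height, width, 2), dtype=np.float64)
    pe[:, :, 0] = np.sin(2.0 * np.pi * x / width)[None, :]
    pe[:, :, 1] = np.cos(2.0 * np.pi * y / height)[:, None]
    return pe


def assemble_input(
    image: np.ndarray,
    config: PreprocessConfig,
    crop_box: tuple[int, int, int, int] | None = None,
) -> EncodedInput:
    """Stack model input channels from an already cropped/resized/normalized image.

    Grayscale input is replicated to three channels; the two positional
    channels are appended when ``config.use_pe``.
    """
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    elif image.ndim == 3 and image.shape[2] == 1:
        image = np.repeat(image, 3, axis=2)
    elif image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected a grayscale or 3-channel image, got shape {image.shape}")
    h, w = image.shape[:2]
    channels = np.concatenate([image, positional_encoding(h, w)], axis=2) if config.use_pe else image
    return EncodedInput(channels=channels, crop_box=crop_box or (0, 0, h, w))


def build_roi_mask(
    height: int, width: int, margins: tuple[float, float, float] = (0.10, 0.10, 0.10)
) -> RoiMask:
    """Ones except the left/right margin columns and top margin rows."""
    left, right, top = margins
    for m in margins:
        if not 0.0 <= m < 0.5:
            raise ValueError("each margin fraction must lie in [0, 0.5)")
    if left + right >= 1.0:
        raise ValueError("left and right margins cover the whole width")
    mask = np.ones((height, width), dtype=bool)
    nl, nr, nt = int(left * width), int(right * width), int(top * height)
    if nl:
        mask[:, :nl] = False
    if nr:
        mask[:, width - nr :] = False
    if nt:
        mask[:nt, :] = False
    return RoiMask(mask=mask, margins=tuple(margins))


def preprocess_frame(image: np.ndarray, config: PreprocessConfig) -> EncodedInput:
    """Full pipeline: to-float, crop borders, resize, min-max normalize, encode."""
    image = img_as_float(image)
    cropped, box = crop_black_borders(image, config.border_threshold)
    size = (config.target_size, config.target_size)
    if cropped.shape[:2] != size:
        cropped = _sk_resize(cropped, size, order=1, anti_aliasing=False, preserve_range=True)
    return assemble_input(minmax_normalize(cropped), config, crop_box=box)


def load_frame(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF frame (8- or 16-bit, grayscale or RGB) as float in [0, 1]."""
    img = iio.imread(Path(path))
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return img_as_float(img)
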