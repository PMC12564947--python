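"""Synthetic fluoroscopy-like phantom generator with exact ground truth.

Frames are drawn from a location-conditioned Gaussian model: a fixed smooth
mean field mu(x, y) built from Gaussian intensity bumps (anatomy-like
structure), plus isotropic per-pixel Gaussian noise and a small rigid jitter
of the structures that stands in for physiologic motion (hyoid excursion,
head movement) which an anomaly detector must tolerate.  Anomalies are
ellipses that are either additive intensity offsets (bolus-like contrast) or
"transplants" of the mean field copied from a disjoint source location —
appearance that is globally familiar but spatially inconsistent, the case
that separates a location-aware model from a purely local one.

Every operation is a pure function of its spec and seeded generator, so the
same seed reproduces a dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "PhantomSpec",
    "AnomalySpec",
    "PhantomFrame",
    "PhantomDataset",
    "build_mean_field",
    "sample_background_frame",
    "inject_anomaly",
    "generate_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the background frame model.

    noise_sigma is the per-pixel Gaussian standard deviation in intensity
    units (images live in [0, 1]); jitter_px bounds the rigid per-frame
    translation of the background structures in pixels.
    """

    height: int = 64
    width: int = 64
    n_blobs: int = 5
    blob_amplitude: float = 0.4
    base_intensity: float = 0.35
    noise_sigma: float = 0.005
    jitter_px: int = 1
    # per-frame multiplicative amplitude factor for each blob, drawn from
    # U(1 - amp_jitter, 1): emulates cross-subject anatomy and exposure
    # variability, so that a bright smooth region is a *plausible local
    # appearance* anywhere while its expected location stays informative
    amp_jitter: float = 0.5
    # "fixed": one seeded constellation shared by all frames (amplitudes may
    # still vary per frame).  "scatter": blob centers are redrawn every frame
    # with rows confined to structure_zone — location-conditioned statistics
    # that cannot be inferred from a single frame, emulating a cohort of
    # different subjects imaged under the same framing.  "hybrid": a fixed
    # zone-confined constellation (shared skeleton, predictable from
    # position) plus n_scatter per-frame clutter blobs (individual
    # variation, defeating single-frame scene completion)
    layout: str = "fixed"
    n_scatter: int = 0  # per-frame clutter blobs (hybrid layout)
    structure_zone: tuple[float, float] = (0.0, 0.55)  # row-fraction band holding structure
    blob_sigma_range: tuple[float, float] | None = None  # None -> (min(h,w)/12, min(h,w)/6)
    # periodic=True builds the field on a torus and realizes jitter as a
    # circular shift: the world is then exactly translation-symmetric, so
    # location information exists only where it is deliberately injected
    periodic: bool = True
    seed: int = 0

    def __post_init__(self):
        # YAML round-trips deliver lists; tuples keep the spec hashable
        object.__setattr__(self, "structure_zone", tuple(self.structure_zone))
        if self.blob_sigma_range is not None:
            object.__setattr__(self, "blob_sigma_range", tuple(self.blob_sigma_range))
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom frames must be at least 16x16 pixels")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be nonnegative")
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("base_intensity must lie in [0, 1]")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be nonnegative")
        if not 0.0 <= self.amp_jitter < 1.0:
            raise ValueError("amp_jitter must lie in [0, 1)")
        if self.layout not in ("fixed", "scatter", "hybrid"):
            raise ValueError("layout must be 'fixed', 'scatter' or 'hybrid'")
        if self.n_scatter < 0:
            raise ValueError("n_scatter must be nonnegative")
        lo, hi = self.structure_zone
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("structure_zone must be an increasing pair of row fractions")


@dataclass(frozen=True)
class AnomalySpec:
    """Elliptical anomaly model.

    mode "additive" shifts intensity inside the ellipse by ``delta``;
    mode "transplanted" copies mean-field values from a disjoint source
    location (``delta`` is ignored).  ``center_region`` is a
    (row0, col0, row1, col1) rectangle from which centers are drawn;
    ``None`` means the central 60% of the frame.
    """

    shape: str = "ellipse"
    semi_axes: tuple[int, int] = (7, 5)  # (row semi-axis, col semi-axis), pixels
    center_region: tuple[int, int, int, int] | None = None
    mode: str = "additive"
    delta: float = 0.3
    count_per_frame: int = 1
    # transplanted mode only: the source patch must differ from the
    # destination by at least this mean absolute field contrast, otherwise
    # the "anomaly" would carry no detectable signal
    min_source_contrast: float = 0.15
    # transplanted mode only: blend width (px) at the ellipse rim, so the
    # anomaly is detectable by its misplaced appearance rather than by a
    # sharp pasting seam; ground truth remains the hard ellipse
    feather_px: float = 1.5

    def __post_init__(self):
        object.__setattr__(self, "semi_axes", tuple(self.semi_axes))
        if self.center_region is not None:
            object.__setattr__(self, "center_region", tuple(self.center_region))
        if self.shape != "ellipse":
            raise ValueError(f"unsupported anomaly shape {self.shape!r}")
        if self.mode not in ("additive", "transplanted"):
            raise ValueError(f"unsupported anomaly mode {self.mode!r}")
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [-1, 1]")
        if self.count_per_frame < 1:
            raise ValueError("count_per_frame must be >= 1")
        if min(self.semi_axes) < 1:
            raise ValueError("semi_axes must be >= 1 pixel")


@dataclass
class PhantomFrame:
    """A single frame with its exact anomaly ground truth."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray  # (H, W) bool, True on anomaly pixels
    frame_id: int = 0
    has_anomaly: bool = False

    def __post_init__(self):
        # a null (delta=0) anomaly leaves the image unchanged but keeps its
        # mask, so the invariant is on the mask, not on the pixels
        if bool(self.mask.any()) != self.has_anomaly:
            raise ValueError("mask must be all-zero iff has_anomaly is false")


def _sigma_range(spec: PhantomSpec) -> tuple[float, float]:
    if spec.blob_sigma_range is not None:
        return spec.blob_sigma_range
    scale = min(spec.height, spec.width)
    return (scale / 12, scale / 6)


def _periodic_delta(n: int, c: float, periodic: bool) -> np.ndarray:
    d = np.abs(np.arange(n, dtype=np.float64) - c)
    return np.minimum(d, n - d) if periodic else d


@lru_cache(maxsize=8)
def _scatter_mean_profile(spec: PhantomSpec) -> np.ndarray:
    """Analytic row profile mu(y) of the per-frame scatter blobs (x-average uniform).

    Averages the Gaussian bump over the uniform center distribution (rows in
    the structure zone, columns uniform on the torus) and the sigma range.
    The profile is per blob; callers scale by the blob count.
    """
    h, w = spec.height, spec.width
    lo, hi = _sigma_range(spec)
    r0, r1 = spec.structure_zone[0] * h, spec.structure_zone[1] * h
    sigmas = np.linspace(lo, hi, 17)
    centers = np.linspace(r0, r1, max(int(round(r1 - r0)) * 2, 2), endpoint=False) + 0.25
    y = np.arange(h, dtype=np.float64)
    acc = np.zeros(h)
    for sig in sigmas:
        # exact discrete x-mass of the bump on the torus row
        x_mass = np.exp(-_periodic_delta(w, 0.0, spec.periodic) ** 2 / (2 * sig**2)).sum() / w
        for cy in centers:
            dy = _periodic_delta(h, cy, spec.periodic)
            acc += np.exp(-(dy**2) / (2 * sig**2)) * x_mass
    return acc / (len(sigmas) * len(centers))


@lru_cache(maxsize=8)
def _blob_bumps(spec: PhantomSpec) -> np.ndarray:
    """Unit-amplitude Gaussian bump stack (n_blobs, H, W) placed by the seeded stream.

    Placement is redrawn (bounded attempts) until the resulting mean field has
    at least 0.2 of intensity contrast, so that location carries information.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    lo, hi = _sigma_range(spec)
    mean_factor = 1.0 - spec.amp_jitter / 2.0
    r0, r1 = (
        (spec.structure_zone[0] * h, spec.structure_zone[1] * h)
        if spec.layout == "hybrid"
        else (0.0, float(h))
    )
    for _ in range(10):
        bumps = np.empty((spec.n_blobs, h, w), dtype=np.float64)
        for i in range(spec.n_blobs):
            cy = rng.uniform(r0, r1)
            cx = rng.uniform(0, w)
            sig = rng.uniform(lo, hi)
            dy = _periodic_delta(h, cy, spec.periodic)[:, None]
            dx = _periodic_delta(w, cx, spec.periodic)[None, :]
            bumps[i] = np.exp(-(dy**2 + dx**2) / (2 * sig**2))
        mean2d = np.clip(
            spec.base_intensity + spec.blob_amplitude * mean_factor * bumps.sum(axis=0), 0.0, 1.0
        )
        if mean2d.max() - mean2d.min() >= 0.2:
            return bumps
    raise RuntimeError("could not draw a mean field with >= 0.2 intensity contrast")


def build_mean_field(spec: PhantomSpec) -> np.ndarray:
    """Deterministic smooth mean field mu(x, y), shape (H, W, 3), values in [0, 1].

    The field is a base intensity plus ``n_blobs`` Gaussian bumps placed by
    the spec's seeded stream, each at its *expected* per-frame amplitude
    ``blob_amplitude * (1 - amp_jitter/2)``, replicated identically across
    the three channels (grayscale anatomy).
    """
    h, w = spec.height, spec.width
    mean_factor = 1.0 - spec.amp_jitter / 2.0
    n_scatter = spec.n_blobs if spec.layout == "scatter" else spec.n_scatter
    n_fixed = 0 if spec.layout == "scatter" else spec.n_blobs
    if n_fixed == 0 and n_scatter == 0:
        return np.full((h, w, 3), spec.base_intensity, dtype=np.float64)
    field2d = np.full((h, w), spec.base_intensity, dtype=np.float64)
    if n_fixed:
        field2d += spec.blob_amplitude * mean_factor * _blob_bumps(spec).sum(axis=0)
    if n_scatter:
        field2d += (n_scatter * spec.blob_amplitude * mean_factor * _scatter_mean_profile(spec))[:, None]
    field2d = np.clip(field2d, 0.0, 1.0)
    if field2d.max() - field2d.min() < 0.2:
        raise RuntimeError("mean field has < 0.2 intensity contrast; location carries too little information")
    return np.repeat(field2d[:, :, None], 3, axis=2)


def _rigid_shift(field: np.ndarray, dy: int, dx: int, periodic: bool) -> np.ndarray:
    """Integer translation; circular on a periodic field, edge-replicated otherwise."""
    if dy == 0 and dx == 0:
        return field
    if periodic:
        return np.roll(field, (dy, dx), axis=(0, 1))
    h, w = field.shape[:2]
    pad_y = abs(dy)
    pad_x = abs(dx)
    padded = np.pad(field, ((pad_y, pad_y), (pad_x, pad_x), (0, 0)), mode="edge")
    return padded[pad_y - dy : pad_y - dy + h, pad_x - dx : pad_x - dx + w]


def sample_background_frame(
    field: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    frame_id: int = 0,
) -> PhantomFrame:
    """Draw one anomaly-free frame.

    The frame is the base intensity plus each blob at a per-frame amplitude
    factor U(1 - amp_jitter, 1), rigidly jittered, plus clipped Gaussian
    noise.  With amp_jitter = 0, jitter_px = 0 and noise_sigma = 0 the frame
    equals the mean field exactly.
    """
    if field.shape[:2] != (spec.height, spec.width):
        raise ValueError("field dimensions do not match spec")
    h, w = spec.height, spec.width
    n_scatter = spec.n_blobs if spec.layout == "scatter" else spec.n_scatter
    n_fixed = 0 if spec.layout == "scatter" else spec.n_blobs
    if n_fixed == 0 and n_scatter == 0:
        img = field
    elif n_scatter == 0 and spec.amp_jitter == 0:
        img = field
    else:
        frame2d = np.full((h, w), spec.base_intensity, dtype=np.float64)
        if n_fixed:
            factors = spec.blob_amplitude * rng.uniform(1.0 - spec.amp_jitter, 1.0, size=n_fixed)
            frame2d += np.tensordot(factors, _blob_bumps(spec), axes=1)
        if n_scatter:
            lo, hi = _sigma_range(spec)
            r0, r1 = spec.structure_zone[0] * h, spec.structure_zone[1] * h
            for _ in range(n_scatter):
                cy = rng.uniform(r0, r1)
                cx = rng.uniform(0, w)
                sig = rng.uniform(lo, hi)
                factor = spec.blob_amplitude * rng.uniform(1.0 - spec.amp_jitter, 1.0)
                dy = _periodic_delta(h, cy, spec.periodic)[:, None]
                dx = _periodic_delta(w, cx, spec.periodic)[None, :]
                frame2d += factor * np.exp(-(dy**2 + dx**2) / (2 * sig**2))
        img = np.repeat(np.clip(frame2d, 0.0, 1.0)[:, :, None], 3, axis=2)
    if spec.jitter_px > 0:
        dy, dx = rng.integers(-spec.jitter_px, spec.jitter_px + 1, size=2)
        img = _rigid_shift(img, int(dy), int(dx), spec.periodic)
    if spec.noise_sigma > 0:
        # one grayscale noise draw replicated across channels keeps frames achromatic
        noise = rng.normal(0.0, spec.noise_sigma, size=img.shape[:2])
        img = np.clip(img + noise[:, :, None], 0.0, 1.0)
    else:
        img = img.copy()
    return PhantomFrame(
        image=img,
        mask=np.zeros(img.shape[:2], dtype=bool),
        frame_id=frame_id,
        has_anomaly=False,
    )


def _ellipse_rho(h: int, w: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    """Normalized elliptical radius grid (1.0 on the ellipse boundary)."""
    yy, xx = np.mgrid[0:h, 0:w]
    return np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    return _ellipse_rho(h, w, cy, cx, ay, ax) <= 1.0


def _fits(cy: int, cx: int, ay: int, ax: int, h: int, w: int) -> bool:
    return cy - ay >= 0 and cy + ay < h and cx - ax >= 0 and cx + ax < w


def inject_anomaly(
    frame: PhantomFrame,
    anomaly: AnomalySpec,
    field: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> PhantomFrame:
    """Place ``count_per_frame`` elliptical anomalies on a clean frame.

    Additive mode adds ``delta`` inside the ellipse (clipped afterwards);
    transplanted mode copies the mean-field appearance from a seeded, disjoint
    source ellipse, producing an anomaly whose intensities are familiar but in
    the wrong place.  Returns a new frame; ground truth is exact: the mask is
    1 on ellipse pixels and only there.
    """
    if frame.has_anomaly:
        raise ValueError("frame already contains an anomaly")
    h, w = frame.image.shape[:2]
    ay, ax = anomaly.semi_axes
    region = anomaly.center_region or (int(0.2 * h), int(0.2 * w), int(0.8 * h), int(0.8 * w))
    r0, c0, r1, c1 = region

    img = frame.image.copy()
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(anomaly.count_per_frame):
        for _ in range(max_attempts):
            cy = int(rng.integers(r0, r1))
            cx = int(rng.integers(c0, c1))
            if _fits(cy, cx, ay, ax, h, w):
                rho = _ellipse_rho(h, w, cy, cx, ay, ax)
                emask = (rho <= 1.0) & ~mask
                break
        else:
            raise RuntimeError(
                f"could not place a {ay}x{ax} ellipse inside center_region {region} "
                f"of a {h}x{w} frame after {max_attempts} attempts"
            )
        if anomaly.mode == "additive":
            img[emask] = np.clip(img[emask] + anomaly.delta, 0.0, 1.0)
        else:  # transplanted
            ys, xs = np.nonzero(emask)
            for _ in range(max_attempts):
                sy = int(rng.integers(ay, h - ay))
                sx = int(rng.integers(ax, w - ax))
                smask = _ellipse_mask(h, w, sy, sx, ay, ax)
                if (smask & (emask | mask)).any():
                    continue
                src_vals = field[ys + (sy - cy), xs + (sx - cx)]
                if np.mean(np.abs(src_vals - field[ys, xs])) >= anomaly.min_source_contrast:
                    break
            else:
                raise RuntimeError(
                    "could not find a disjoint transplant source with "
                    f">= {anomaly.min_source_contrast} mean field contrast"
                )
            if anomaly.feather_px > 0:
                # linear ramp from full transplant in the interior to the
                # untouched background at the rim
                alpha = np.clip((1.0 - rho[ys, xs]) * min(ay, ax) / anomaly.feather_px, 0.0, 1.0)
                img[ys, xs] = alpha[:, None] * src_vals + (1.0 - alpha[:, None]) * img[ys, xs]
            else:
                img[ys, xs] = src_vals
        mask |= emask
    return PhantomFrame(image=img, mask=mask, frame_id=frame.frame_id, has_anomaly=True)


@dataclass
class PhantomDataset:
    """Train/test phantom splits plus the generating field and specs."""

    train: list[PhantomFrame]
    test: list[PhantomFrame]
    field: np.ndarray
    spec: PhantomSpec
    anomaly: AnomalySpec
    seed: int


def generate_dataset(
    spec: PhantomSpec,
    anomaly: AnomalySpec,
    n_train: int,
    n_test_clean: int,
    n_test_anom: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PhantomDataset:
    """Generate a phantom dataset: anomaly-free training split, mixed test split.

    The test split interleaves clean and anomalous frames in a seeded random
    order.  When ``out_dir`` is given the dataset is also written to disk in
    the frame-directory layout (8-bit PNGs plus a ``manifest.yaml``).
    """
    if min(n_train, n_test_clean, n_test_anom) < 0:
        raise ValueError("frame counts must be nonnegative")
    field = build_mean_field(spec)
    rng = np.random.default_rng(seed)

    train = [sample_background_frame(field, spec, rng, frame_id=i) for i in range(n_train)]

    test: list[PhantomFrame] = []
    for _ in range(n_test_clean):
        test.append(sample_background_frame(field, spec, rng))
    for _ in range(n_test_anom):
        clean = sample_background_frame(field, spec, rng)
        test.append(inject_anomaly(clean, anomaly, field, rng))
    order = rng.permutation(len(test))
    test = [dataclasses.replace(test[j], frame_id=i) for i, j in enumerate(order)]

    ds = PhantomDataset(train=train, test=test, field=field, spec=spec, anomaly=anomaly, seed=seed)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)


def _write_split(frames: list[PhantomFrame], root: Path) -> None:
    (root / "frames").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    for f in frames:
        try:
            iio.imwrite(root / "frames" / f"frame_{f.frame_id:06d}.png", _to_uint8(f.image))
            iio.imwrite(root / "masks" / f"frame_{f.frame_id:06d}.png", (f.mask * np.uint8(255)))
        except OSError as exc:  # pragma: no cover - disk-dependent
            raise OSError(f"failed writing frame {f.frame_id} under {root}: {exc}") from exc


def _write_dataset(ds: PhantomDataset, out_dir: Path) -> None:
    _write_split(ds.train, out_dir / "train")
    _write_split(ds.test, out_dir / "test")
    manifest = {
        "spec": dataclasses.asdict(ds.spec),
        "anomaly": dataclasses.asdict(ds.anomaly),
        "seed": ds.seed,
        "splits": {
            "train": [{"frame_id": f.frame_id, "has_anomaly": f.has_anomaly} for f in ds.train],
            "test": [{"frame_id": f.frame_id, "has_anomaly": f.has_anomaly} for f in ds.test],
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_dataset(path: str | Path) -> PhantomDataset:
    """Read a dataset previously written by :func:`generate_dataset`."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    spec = PhantomSpec(**manifest["spec"])
    anomaly_kwargs = dict(manifest["anomaly"])
    for key in ("semi_axes", "center_region"):
        if anomaly_kwargs.get(key) is not None:
            anomaly_kwargs[key] = tuple(anomaly_kwargs[key])
    anomaly = AnomalySpec(**anomaly_kwargs)

    def read_split(name: str) -> list[PhantomFrame]:
        frames = []
        for entry in manifest["splits"][name]:
            fid = entry["frame_id"]
            img = iio.imread(path / name / "frames" / f"frame_{fid:06d}.png").astype(np.float64) / 255.0
            msk = iio.imread(path / name / "masks" / f"frame_{fid:06d}.png") > 127
            frames.append(PhantomFrame(image=img, mask=msk, frame_id=fid, has_anomaly=entry["has_anomaly"]))
        return frames

    return PhantomDataset(
        train=read_split("train"),
        test=read_split("test"),
        field=build_mean_field(spec),
        spec=spec,
        anomaly=anomaly,
        seed=manifest["seed"],
    )
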