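"""Synthetic phantoms and paired limited-angle sinogram datasets.

This module is the stand-in for clinical training data. It reproduces the
published dataset construction procedure: value-normalise each image to
``[0, 0.255]``, project it to a 180-degree sinogram, normalise the sinogram to
``[0, 1]``, add zero-mean Gaussian noise (variance ``2e-6`` by default), and
delete a contiguous angular window of views (five 120-degree windows per image
for training: 1-120, 16-135, 31-150, 46-165 and 61-180 degrees, which at
512 views removes 341 views each).

Deleted views are represented as zero-filled values plus an explicit per-view
mask; measured views are kept bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .geometry import ImageGrid, ScanGeometry, Sinogram
from .projection import forward_project

__all__ = [
    "EllipseSpec",
    "NoiseModel",
    "DeletionWindow",
    "PairedSample",
    "TRAINING_WINDOWS",
    "make_phantom",
    "random_ellipse_specs",
    "rasterize_ellipses",
    "normalize_image",
    "normalize_sinogram",
    "analytic_ellipse_sinogram",
    "add_noise",
    "views_in_window",
    "make_limited_angle",
    "build_dataset",
]

IMAGE_VALUE_RANGE = 0.255  # images are rescaled to [0, 0.255]
DEFAULT_NOISE_VARIANCE = 2e-6


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse: centre/axes in physical units, attenuation value."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive zero-mean Gaussian sinogram noise."""

    variance: float = DEFAULT_NOISE_VARIANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be non-negative")


@dataclass(frozen=True)
class DeletionWindow:
    """Contiguous block of deleted views, labelled in 1-based degrees.

    ``start_deg=1, span_deg=120`` is the published first training window
    (views 0..340 of a 512-view, 180-degree sinogram).
    """

    start_deg: float = 1.0
    span_deg: float = 120.0

    def __post_init__(self) -> None:
        if self.span_deg < 0:
            raise ValueError("span must be non-negative")
        if self.start_deg < 1:
            raise ValueError("window start is a 1-based degree label")


TRAINING_WINDOWS = tuple(DeletionWindow(s, 120.0) for s in (1, 16, 31, 46, 61))


@dataclass
class PairedSample:
    """One training pair: limited-angle input, full 180-degree label."""

    input_sino: Sinogram
    label_sino: Sinogram
    source_image: np.ndarray
    window: DeletionWindow | None = None
    sino_scale: float = 1.0   # label = raw sinogram / sino_scale
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def random_ellipse_specs(seed: int, n_ellipses: int | None = None,
                         fov_radius: float = 1.0) -> list[EllipseSpec]:
    """Seeded random phantom description: 5-12 positive additive ellipses."""
    rng = np.random.default_rng(seed)
    if n_ellipses is None:
        n_ellipses = int(rng.integers(5, 13))
    specs = []
    if n_ellipses > 0:
        # enclosing "body" ellipse plus smaller internal structures
        specs.append(EllipseSpec(
            center=(0.0, 0.0),
            semi_axes=(0.75 * fov_radius * rng.uniform(0.85, 1.0),
                       0.75 * fov_radius * rng.uniform(0.85, 1.0)),
            rotation_deg=float(rng.uniform(0, 180)),
            intensity=float(rng.uniform(0.3, 0.6)),
        ))
    for _ in range(n_ellipses - 1):
        r = 0.45 * fov_radius
        specs.append(EllipseSpec(
            center=(float(rng.uniform(-r, r)), float(rng.uniform(-r, r))),
            semi_axes=(float(rng.uniform(0.04, 0.35) * fov_radius),
                       float(rng.uniform(0.04, 0.35) * fov_radius)),
            rotation_deg=float(rng.uniform(0, 180)),
            intensity=float(rng.uniform(0.1, 0.8)),
        ))
    return specs


def rasterize_ellipses(specs: list[EllipseSpec], grid: ImageGrid,
                       supersample: int = 2) -> np.ndarray:
    """Sum-of-ellipses raster with ``supersample``^2 sub-pixel anti-aliasing."""
    ss = max(1, int(supersample))
    fine = ImageGrid(grid.n_rows * ss, grid.n_cols * ss, grid.pixel_size / ss,
                     grid.origin)
    X, Y = fine.pixel_centers()
    img = np.zeros(fine.shape)
    for e in specs:
        phi = np.deg2rad(e.rotation_deg)
        dx, dy = X - e.center[0], Y - e.center[1]
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        img += e.intensity * (((u / e.semi_axes[0]) ** 2
                               + (v / e.semi_axes[1]) ** 2) <= 1.0)
    if ss == 1:
        return img
    return img.reshape(grid.n_rows, ss, grid.n_cols, ss).mean(axis=(1, 3))


def make_phantom(kind: str, grid: ImageGrid, seed: int = 0,
                 n_ellipses: int | None = None) -> np.ndarray:
    """Deterministic non-negative phantom image on ``grid``.

    ``shepp_logan`` is the canonical 10-ellipse head phantom (resampled to the
    grid); ``random_ellipses`` draws a seeded 5-12 ellipse phantom.
    """
    if kind == "shepp_logan":
        base = shepp_logan_phantom()
        return resize(base, grid.shape, order=1, anti_aliasing=True,
                      preserve_range=True)
    if kind == "random_ellipses":
        fov = 0.5 * min(grid.width, grid.height)
        specs = random_ellipse_specs(seed, n_ellipses, fov_radius=fov)
        return rasterize_ellipses(specs, grid)
    raise ValueError(f"unknown phantom kind {kind!r}")


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Affine min-max rescale to ``[0, 0.255]``; a constant image maps to zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) * (IMAGE_VALUE_RANGE / (hi - lo))


def normalize_sinogram(sino: Sinogram) -> tuple[Sinogram, float]:
    """Scale sinogram values into ``[0, 1]`` by the (positive) maximum."""
    m = float(sino.values.max())
    scale = m if m > 0 else 1.0
    return sino.with_values(sino.values / scale), scale


# ---------------------------------------------------------------------------
# Analytic sinogram oracle
# ---------------------------------------------------------------------------

def analytic_ellipse_sinogram(ellipses: list[EllipseSpec],
                              geometry: ScanGeometry) -> Sinogram:
    """Exact parallel-beam line integrals of a sum of ellipses (closed form).

    For an ellipse with semi-axes (a, b) rotated by phi, the projection at
    view angle theta and signed detector offset s is
    ``2 rho a b sqrt(w^2 - (s - s0)^2) / w^2`` with
    ``w^2 = a^2 cos^2(theta-phi) + b^2 sin^2(theta-phi)`` and ``s0`` the
    centre's projection onto the detector axis.
    """
    if geometry.mode != "parallel":
        raise ValueError("analytic ellipse projections support parallel mode only")
    thetas = np.deg2rad(geometry.angles_deg)[:, None]
    s = geometry.bin_offsets[None, :]
    out = np.zeros(geometry.shape)
    for e in ellipses:
        a, b = e.semi_axes
        beta = thetas - np.deg2rad(e.rotation_deg)
        w2 = (a * np.cos(beta)) ** 2 + (b * np.sin(beta)) ** 2
        s0 = e.center[0] * np.cos(thetas) + e.center[1] * np.sin(thetas)
        d2 = w2 - (s - s0) ** 2
        out += 2.0 * e.intensity * a * b * np.sqrt(np.maximum(d2, 0.0)) / w2
    return Sinogram(out, geometry)


# ---------------------------------------------------------------------------
# Noise and deletion windows
# ---------------------------------------------------------------------------

def add_noise(sino: Sinogram, noise: NoiseModel) -> Sinogram:
    """Independent zero-mean Gaussian noise per entry; mask unchanged."""
    if noise.variance == 0:
        return sino.copy()
    rng = np.random.default_rng(noise.seed)
    out = sino.values + rng.normal(0.0, np.sqrt(noise.variance), sino.values.shape)
    return sino.with_values(out)


def _check_window(geometry: ScanGeometry, window: DeletionWindow) -> None:
    if window.span_deg >= geometry.angular_range_deg and window.span_deg > 0:
        raise ValueError("deletion span must be smaller than the angular range")
    if window.start_deg - 1 + window.span_deg > geometry.angular_range_deg:
        raise ValueError("deletion window exceeds the scanned range")


def views_in_window(geometry: ScanGeometry, window: DeletionWindow) -> int:
    """Number of contiguous views removed: round(n_views * span / range).

    512 views over 180 degrees: a 120-degree window removes 341 views, a
    100-degree window removes 284.
    """
    _check_window(geometry, window)
    x = geometry.n_views * window.span_deg / geometry.angular_range_deg
    return int(np.floor(x + 0.5))


def window_view_slice(geometry: ScanGeometry, window: DeletionWindow) -> slice:
    """Half-open view-index range deleted by ``window``.

    The 1-based degree label maps to view index
    ``round((start_deg - 1) * n_views / range)``, which reproduces both
    printed anchors: window 1-120 starts at view 0 and window 61-180 covers
    exactly the last 341 of 512 views.
    """
    _check_window(geometry, window)
    start = int(np.floor((window.start_deg - 1) * geometry.n_views
                         / geometry.angular_range_deg + 0.5))
    return slice(start, start + views_in_window(geometry, window))


def make_limited_angle(sino: Sinogram, window: DeletionWindow) -> Sinogram:
    """Zero-fill the deleted view block and mark it invalid in the mask.

    Measured views are bit-identical to the input; the input must be a
    complete (all-valid) sinogram.
    """
    if not sino.valid_mask.all():
        raise ValueError("make_limited_angle expects a complete sinogram")
    sl = window_view_slice(sino.geometry, window)
    out = sino.copy()
    out.values[sl] = 0.0
    out.valid_mask[sl] = False
    return out


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def build_dataset(images: list[np.ndarray], geometry: ScanGeometry,
                  windows: list[DeletionWindow], noise: NoiseModel,
                  grid: ImageGrid | None = None) -> list[PairedSample]:
    """Paired limited-angle/full sinograms: ``len(images) * len(windows)`` pairs.

    Per image: normalise to [0, 0.255], forward-project, normalise the
    sinogram to [0, 1], add noise (seed derived from the root seed and the
    image index), then emit one deleted copy per window. The noisy full
    sinogram is the label; inputs equal the label on all measured views.
    """
    if len(images) == 0:
        raise ValueError("build_dataset needs at least one image")
    if len(windows) == 0:
        raise ValueError("build_dataset needs at least one deletion window")
    samples: list[PairedSample] = []
    for i, raw in enumerate(images):
        img = normalize_image(np.asarray(raw, dtype=np.float64))
        g = grid or ImageGrid(img.shape[0], img.shape[1])
        label, scale = normalize_sinogram(forward_project(img, geometry, g))
        label = add_noise(label, NoiseModel(noise.variance,
                                            seed=int(noise.seed) + i))
        for w in windows:
            samples.append(PairedSample(
                input_sino=make_limited_angle(label, w),
                label_sino=label.copy(),
                source_image=img,
                window=w,
                sino_scale=scale,
                meta={"image_index": i, "noise_seed": int(noise.seed) + i},
            ))
    return samples
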