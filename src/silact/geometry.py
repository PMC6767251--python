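"""Scan geometry and core containers for 2D CT.

Conventions
-----------
* The image grid is an ``n_rows x n_cols`` pixel array. Row 0 is the top of
  the image; physical ``y`` decreases with the row index, ``x`` increases
  with the column index. The grid is centred on ``origin`` (default the
  physical origin).
* View angles are ``theta_k = k * angular_range / n_views`` for
  ``k = 0 .. n_views-1`` — a half-open ``[0, 180)`` degree sweep by default.
* Detector bin centres are symmetric about the projection of the rotation
  centre: offset ``s_j = (j - (n_bins - 1)/2) * bin_size``.
* For a view at angle ``theta`` the detector axis is
  ``e_s = (cos t, sin t)`` and rays travel along ``e_t = (-sin t, cos t)``.
  In fan mode the source sits at ``-SOD * e_t`` and the flat detector line
  passes through ``(SDD - SOD) * e_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageGrid", "ScanGeometry", "Sinogram", "RayTrace",
           "SCANNER_TRAINING_GEOMETRY"]


@dataclass(frozen=True)
class ImageGrid:
    """Discretised 2D reconstruction domain."""

    n_rows: int = 512
    n_cols: int = 512
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def width(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def height(self) -> float:
        return self.n_rows * self.pixel_size

    @property
    def x_min(self) -> float:
        return self.origin[0] - self.width / 2.0

    @property
    def y_min(self) -> float:
        return self.origin[1] - self.height / 2.0

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) centre coordinates as 2D arrays of grid shape."""
        xs = self.x_min + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.y_min + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


@dataclass(frozen=True)
class ScanGeometry:
    """Parallel- or fan-beam acquisition geometry defining the system matrix."""

    mode: str = "parallel"
    n_views: int = 512
    angular_range_deg: float = 180.0
    n_bins: int = 512
    bin_size: float = 0.831
    source_to_object: float = 483.41
    source_to_detector: float = 796.49

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "fan"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be >= 1")
        if self.bin_size <= 0 or self.angular_range_deg <= 0:
            raise ValueError("bin_size and angular_range_deg must be positive")
        if self.mode == "fan":
            if self.source_to_object <= 0 or self.source_to_detector <= 0:
                raise ValueError("fan distances must be positive")
            if self.source_to_detector <= self.source_to_object:
                raise ValueError("source_to_detector must exceed source_to_object")

    @property
    def angles_deg(self) -> np.ndarray:
        k = np.arange(self.n_views)
        return k * self.angular_range_deg / self.n_views

    @property
    def bin_offsets(self) -> np.ndarray:
        j = np.arange(self.n_bins)
        return (j - (self.n_bins - 1) / 2.0) * self.bin_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_bins)

    def ray_endpoints(self, extent: float) -> np.ndarray:
        """Endpoints of every (view, bin) ray, shape ``(n_views*n_bins, 4)``.

        ``extent`` is a physical radius that the parallel rays must safely
        clear on both sides (typically the grid half-diagonal).
        """
        thetas = np.deg2rad(self.angles_deg)
        cs, sn = np.cos(thetas), np.sin(thetas)
        e_s = np.stack([cs, sn], axis=1)          # (V, 2) detector axis
        e_t = np.stack([-sn, cs], axis=1)         # (V, 2) ray direction
        s = self.bin_offsets                      # (B,)
        if self.mode == "parallel":
            half = 2.0 * (extent + float(np.abs(s).max(initial=0.0)))
            mid = e_s[:, None, :] * s[None, :, None]          # (V, B, 2)
            p0 = mid - half * e_t[:, None, :]
            p1 = mid + half * e_t[:, None, :]
        else:
            src = -self.source_to_object * e_t                # (V, 2)
            det = (self.source_to_detector - self.source_to_object) * e_t
            hit = det[:, None, :] + e_s[:, None, :] * s[None, :, None]
            p0 = np.broadcast_to(src[:, None, :], hit.shape).copy()
            # extend past the detector so both endpoints clear the grid
            p1 = p0 + 1.5 * (hit - p0)
        out = np.concatenate([p0, p1], axis=2).reshape(-1, 4)
        return np.ascontiguousarray(out, dtype=np.float64)


# Real-scanner training profile: 512 detector elements of 0.831 mm,
# source-object 483.41 mm, source-detector 796.49 mm, 512 views over 180 deg.
SCANNER_TRAINING_GEOMETRY = ScanGeometry(
    mode="fan", n_views=512, angular_range_deg=180.0, n_bins=512,
    bin_size=0.831, source_to_object=483.41, source_to_detector=796.49,
)


@dataclass
class Sinogram:
    """Projection data: ``n_views x n_bins`` values plus a per-view validity mask.

    ``valid_mask[k]`` is True for measured views and False for views that were
    deleted (limited-angle) or filled in by the inpainting network.
    """

    values: np.ndarray
    geometry: ScanGeometry
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    angles_deg: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.geometry.n_views, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.geometry.n_views,):
            raise ValueError("valid_mask must have one entry per view")
        if self.angles_deg is None:
            self.angles_deg = self.geometry.angles_deg
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)

    @property
    def n_views(self) -> int:
        return self.geometry.n_views

    @property
    def n_bins(self) -> int:
        return self.geometry.n_bins

    def copy(self) -> "Sinogram":
        return Sinogram(
            self.values.copy(), self.geometry, self.valid_mask.copy(),
            self.angles_deg.copy(),
        )

    def with_values(self, values: np.ndarray) -> "Sinogram":
        return Sinogram(values, self.geometry, self.valid_mask.copy(),
                        self.angles_deg.copy())


@dataclass
class RayTrace:
    """Exact intersection of one ray with the pixel grid (one system-matrix row)."""

    pixel_indices: np.ndarray      # (n, 2) int (row, col)
    intersection_lengths: np.ndarray  # (n,) float

    def __post_init__(self) -> None:
        self.pixel_indices = np.asarray(self.pixel_indices, dtype=np.int64).reshape(-1, 2)
        self.intersection_lengths = np.asarray(self.intersection_lengths, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.intersection_lengths)
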