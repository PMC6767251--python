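"""Discrete CT imaging model: Siddon ray tracing, forward/back projection, FBP.

The forward projector realises the linear system ``g = A u``: every sinogram
entry is the exact line integral of the pixel image along one ray, with the
system-matrix row given by Siddon's algorithm (pixel intersection lengths).
``A`` is materialised once per (geometry, grid) pair as a scipy CSR matrix, so
forward and adjoint applications are sparse mat-vecs and the adjoint is the
transpose by construction.

Filtered back-projection is ``back_project(ramp_filter(g))`` with angular
weight ``pi / n_views``; the ramp (Ram-Lak) filter is applied per view in the
frequency domain after zero-padding to the next power of two >= 2 * n_bins,
with no apodisation window. Because the Siddon adjoint deposits intersection
*lengths* (not unit interpolation weights), an additional physical factor
``bin_size^2 / pixel_size^2`` converts the adjoint sum into the continuous
back-projection integral; with detector bins matching the pixel pitch the
overall weight reduces to the textbook ``pi / n_views``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit, prange

from .geometry import ImageGrid, RayTrace, ScanGeometry, Sinogram

__all__ = [
    "siddon_trace",
    "Projector",
    "forward_project",
    "back_project",
    "ramp_kernel",
    "ramp_filter",
    "filtered_back_project",
]


# ---------------------------------------------------------------------------
# Siddon ray tracing
# ---------------------------------------------------------------------------

@njit(cache=True)
def _siddon_ray(x0, y0, x1, y1, n_cols, n_rows, x_min, y_min, h,
                out_rows, out_cols, out_lens):  # pragma: no cover - jitted
    """Trace one segment through the grid; returns the number of cells hit.

    Walks plane crossings in increasing ray parameter t and assigns each
    inter-crossing interval to the cell containing its midpoint, which is
    robust for rays passing exactly along pixel boundaries or corners.
    """
    dx = x1 - x0
    dy = y1 - y0
    length = np.sqrt(dx * dx + dy * dy)
    x_max = x_min + n_cols * h
    y_max = y_min + n_rows * h

    t_lo = 0.0
    t_hi = 1.0
    # clip against the x-slab
    if dx != 0.0:
        ta = (x_min - x0) / dx
        tb = (x_max - x0) / dx
        if ta > tb:
            ta, tb = tb, ta
        t_lo = max(t_lo, ta)
        t_hi = min(t_hi, tb)
    elif x0 <= x_min or x0 >= x_max:
        return 0
    # clip against the y-slab
    if dy != 0.0:
        ta = (y_min - y0) / dy
        tb = (y_max - y0) / dy
        if ta > tb:
            ta, tb = tb, ta
        t_lo = max(t_lo, ta)
        t_hi = min(t_hi, tb)
    elif y0 <= y_min or y0 >= y_max:
        return 0
    if t_hi <= t_lo:
        return 0

    # first plane crossings strictly after t_lo
    if dx > 0.0:
        m = np.floor((x0 + t_lo * dx - x_min) / h) + 1.0
        t_next_x = (x_min + m * h - x0) / dx
        dt_x = h / dx
    elif dx < 0.0:
        m = np.ceil((x0 + t_lo * dx - x_min) / h) - 1.0
        t_next_x = (x_min + m * h - x0) / dx
        dt_x = -h / dx
    else:
        t_next_x = 1e30
        dt_x = 0.0
    if dy > 0.0:
        m = np.floor((y0 + t_lo * dy - y_min) / h) + 1.0
        t_next_y = (y_min + m * h - y0) / dy
        dt_y = h / dy
    elif dy < 0.0:
        m = np.ceil((y0 + t_lo * dy - y_min) / h) - 1.0
        t_next_y = (y_min + m * h - y0) / dy
        dt_y = -h / dy
    else:
        t_next_y = 1e30
        dt_y = 0.0

    eps = 1e-12
    n = 0
    t = t_lo
    while t < t_hi - eps:
        t_exit = t_hi
        if t_next_x < t_exit:
            t_exit = t_next_x
        if t_next_y < t_exit:
            t_exit = t_next_y
        if t_exit > t + eps:
            t_mid = 0.5 * (t + t_exit)
            col = int(np.floor((x0 + t_mid * dx - x_min) / h))
            j = int(np.floor((y0 + t_mid * dy - y_min) / h))
            if 0 <= col < n_cols and 0 <= j < n_rows:
                out_rows[n] = n_rows - 1 - j   # image row 0 at top
                out_cols[n] = col
                out_lens[n] = (t_exit - t) * length
                n += 1
        if t_next_x <= t_exit + eps:
            t_next_x += dt_x
        if t_next_y <= t_exit + eps:
            t_next_y += dt_y
        t = t_exit
    return n


@njit(cache=True, parallel=True)
def _build_matrix(endpoints, n_cols, n_rows, x_min, y_min, h,
                  indptr, indices, data, cap):  # pragma: no cover - jitted
    n_rays = endpoints.shape[0]
    counts = np.zeros(n_rays, dtype=np.int64)
    for r in prange(n_rays):
        base = r * cap
        rows = np.empty(cap, dtype=np.int64)
        cols = np.empty(cap, dtype=np.int64)
        lens = np.empty(cap, dtype=np.float64)
        n = _siddon_ray(endpoints[r, 0], endpoints[r, 1],
                        endpoints[r, 2], endpoints[r, 3],
                        n_cols, n_rows, x_min, y_min, h, rows, cols, lens)
        counts[r] = n
        for k in range(n):
            indices[base + k] = rows[k] * n_cols + cols[k]
            data[base + k] = lens[k]
    total = 0
    for r in range(n_rays):
        indptr[r + 1] = indptr[r] + counts[r]
    # compact in place
    for r in range(n_rays):
        base = r * cap
        dst = indptr[r]
        for k in range(counts[r]):
            indices[dst + k] = indices[base + k]
            data[dst + k] = data[base + k]
        total += counts[r]
    return total


def siddon_trace(grid: ImageGrid, ray_start, ray_end) -> RayTrace:
    """Exact pixel intersection lengths of the segment ``ray_start -> ray_end``.

    Pixels not crossed by the segment are absent from the trace. A degenerate
    ray (coincident endpoints) raises ``ValueError``.
    """
    x0, y0 = float(ray_start[0]), float(ray_start[1])
    x1, y1 = float(ray_end[0]), float(ray_end[1])
    if x0 == x1 and y0 == y1:
        raise ValueError("degenerate ray: start and end coincide")
    cap = grid.n_rows + grid.n_cols + 2
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    lens = np.empty(cap, dtype=np.float64)
    n = _siddon_ray(x0, y0, x1, y1, grid.n_cols, grid.n_rows,
                    grid.x_min, grid.y_min, grid.pixel_size, rows, cols, lens)
    idx = np.stack([rows[:n], cols[:n]], axis=1)
    return RayTrace(idx, lens[:n])


# ---------------------------------------------------------------------------
# System matrix / projector
# ---------------------------------------------------------------------------

class Projector:
    """Materialised system matrix ``A`` for one (geometry, grid) pair."""

    def __init__(self, geometry: ScanGeometry, grid: ImageGrid):
        self.geometry = geometry
        self.grid = grid
        self._matrix: sp.csr_matrix | None = None

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            grid, geom = self.grid, self.geometry
            extent = grid.diagonal / 2.0 + float(np.hypot(*grid.origin))
            endpoints = geom.ray_endpoints(extent)
            n_rays = endpoints.shape[0]
            cap = grid.n_rows + grid.n_cols + 2
            indptr = np.zeros(n_rays + 1, dtype=np.int64)
            indices = np.empty(n_rays * cap, dtype=np.int64)
            data = np.empty(n_rays * cap, dtype=np.float64)
            total = _build_matrix(endpoints, grid.n_cols, grid.n_rows,
                                  grid.x_min, grid.y_min, grid.pixel_size,
                                  indptr, indices, data, cap)
            self._matrix = sp.csr_matrix(
                (data[:total], indices[:total], indptr),
                shape=(n_rays, grid.n_rows * grid.n_cols),
            )
        return self._matrix

    def forward(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.shape != self.grid.shape:
            raise ValueError(
                f"image shape {image.shape} does not match grid {self.grid.shape}")
        g = self.matrix @ image.ravel()
        return g.reshape(self.geometry.shape)

    def adjoint(self, sino_values: np.ndarray) -> np.ndarray:
        v = np.asarray(sino_values, dtype=np.float64)
        if v.shape != self.geometry.shape:
            raise ValueError(
                f"sinogram shape {v.shape} does not match geometry "
                f"{self.geometry.shape}")
        u = self.matrix.T @ v.ravel()
        return u.reshape(self.grid.shape)


_projector_cache: dict[tuple, Projector] = {}


def get_projector(geometry: ScanGeometry, grid: ImageGrid) -> Projector:
    """Cached projector lookup (system matrices are expensive to rebuild)."""
    key = (geometry, grid)
    if key not in _projector_cache:
        _projector_cache[key] = Projector(geometry, grid)
    return _projector_cache[key]


def forward_project(image: np.ndarray, geometry: ScanGeometry,
                    grid: ImageGrid | None = None) -> Sinogram:
    """Siddon-weighted line integrals of ``image`` for every (view, bin) ray."""
    image = np.asarray(image, dtype=np.float64)
    if grid is None:
        grid = ImageGrid(image.shape[0], image.shape[1])
    proj = get_projector(geometry, grid)
    return Sinogram(proj.forward(image), geometry)


def back_project(sino: Sinogram, grid: ImageGrid) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (unfiltered smearing)."""
    proj = get_projector(sino.geometry, grid)
    return proj.adjoint(sino.values)


# ---------------------------------------------------------------------------
# Ramp filtering and FBP
# ---------------------------------------------------------------------------

def _pad_length(n_bins: int) -> int:
    p = 1
    while p < 2 * n_bins:
        p *= 2
    return p


def ramp_kernel(n_pad: int, bin_size: float) -> np.ndarray:
    """Discrete Ram-Lak kernel arranged circularly on ``n_pad`` points.

    ``h[0] = 1/(4 tau^2)``, ``h[n] = -1/(pi^2 n^2 tau^2)`` for odd ``n`` and 0
    for even ``n`` (tau = bin_size), the band-limited inverse transform of
    ``|omega|`` sampled at the detector pitch.
    """
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * bin_size ** 2)
    n = np.arange(1, n_pad // 2 + 1)
    vals = np.where(n % 2 == 1, -1.0 / (np.pi ** 2 * n ** 2 * bin_size ** 2), 0.0)
    h[1:n_pad // 2 + 1] = vals
    h[n_pad // 2 + 1:] = vals[-2::-1] if n_pad % 2 == 0 else vals[::-1]
    return h


def ramp_filter(sino: Sinogram) -> Sinogram:
    """Convolve each view with the Ram-Lak kernel (frequency-domain, zero-padded).

    The composite operator (zero-pad, circular convolution with the symmetric
    kernel, crop) is exactly self-adjoint, which the differentiable
    reconstruction loss relies on.
    """
    n_bins = sino.n_bins
    if n_bins < 2:
        raise ValueError("ramp filtering needs at least two detector bins")
    n_pad = _pad_length(n_bins)
    h = ramp_kernel(n_pad, sino.geometry.bin_size)
    H = np.fft.rfft(h).real  # symmetric kernel -> real spectrum
    spec = np.fft.rfft(sino.values, n=n_pad, axis=1)
    filtered = np.fft.irfft(spec * H[None, :], n=n_pad, axis=1)[:, :n_bins]
    return sino.with_values(filtered)


def _fbp_scale(geometry: ScanGeometry, grid: ImageGrid) -> float:
    tau = geometry.bin_size
    if geometry.mode == "fan":
        # magnification maps the detector pitch to the isocentre
        tau = tau * geometry.source_to_object / geometry.source_to_detector
    ang = np.deg2rad(geometry.angular_range_deg)
    return ang / geometry.n_views * tau ** 2 / grid.pixel_size ** 2


def filtered_back_project(sino: Sinogram, grid: ImageGrid) -> np.ndarray:
    """FBP reconstruction: ramp filter each view, back-project, angular weight.

    Deleted views must be zero-filled beforehand (``Sinogram`` stores them so).
    In fan mode the views are cosine pre-weighted for the flat detector before
    ramp filtering; back-projection reuses the Siddon adjoint, a short-scan
    approximation adequate for preview reconstructions.
    """
    work = sino
    if sino.geometry.mode == "fan":
        geom = sino.geometry
        s = geom.bin_offsets
        cosw = geom.source_to_detector / np.sqrt(geom.source_to_detector ** 2 + s ** 2)
        work = sino.with_values(sino.values * cosw[None, :])
    filtered = ramp_filter(work)
    img = back_project(filtered, grid)
    return _fbp_scale(sino.geometry, grid) * img


class FBPOperator:
    """Linear FBP ``phi`` and its adjoint for one (geometry, grid) pair.

    Because FBP is linear, its gradient is its adjoint
    ``phi^T = scale * ramp(A .)``; this is what backs the differentiable
    reconstruction loss used in GAN training.
    """

    def __init__(self, geometry: ScanGeometry, grid: ImageGrid):
        if geometry.mode != "parallel":
            raise ValueError("the training FBP operator supports parallel mode")
        self.geometry = geometry
        self.grid = grid
        self.projector = get_projector(geometry, grid)
        self.scale = _fbp_scale(geometry, grid)

    def __call__(self, sino_values: np.ndarray) -> np.ndarray:
        s = Sinogram(sino_values, self.geometry)
        return self.scale * self.projector.adjoint(ramp_filter(s).values)

    def adjoint(self, image: np.ndarray) -> np.ndarray:
        g = Sinogram(self.projector.forward(image), self.geometry)
        return self.scale * ramp_filter(g).values
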