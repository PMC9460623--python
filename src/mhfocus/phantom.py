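"""Synthetic heterogeneously dense breast dielectric phantoms.

A phantom is a pair of maps on a regular 2D grid — relative permittivity
``eps_r`` and electrical conductivity ``sigma`` (S/m) — together with a
boolean ``breast_mask``. The generator emulates a heterogeneously dense
breast at 2.45 GHz: an elliptical breast with a thin skin rim and a
smoothed Gaussian-random-field glandular texture whose conductivity spans
1.00–1.88 S/m. A tumor inclusion is a disc with eps_r=40, sigma=2.0 S/m,
deliberately just above the densest glandular tissue so that heating
potential is naturally elevated there.

Grid convention: row index increases with -y, column index with +x,
coordinates in mm relative to the grid center. A point maps to the pixel
containing it under the half-open convention [x, x + pixel) on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GridSpec",
    "PhantomGrid",
    "generate_phantom",
    "insert_tumor",
    "save_phantom",
    "load_phantom",
]

# In-breast glandular ranges at 2.45 GHz.
SIGMA_MIN = 1.00  # S/m
SIGMA_MAX = 1.88  # S/m
EPS_MIN = 10.0
EPS_MAX = 55.0
TUMOR_EPS = 40.0
TUMOR_SIGMA = 2.0  # S/m
SKIN_EPS = 38.0
SKIN_SIGMA = 1.5  # S/m
SKIN_RIM_MM = 2.0


@dataclass(frozen=True)
class GridSpec:
    """Regular 2D pixel grid centered on the origin."""

    n_rows: int = 71
    n_cols: int = 91
    pixel_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def half_width_mm(self) -> float:
        return 0.5 * self.n_cols * self.pixel_mm

    @property
    def half_height_mm(self) -> float:
        return 0.5 * self.n_rows * self.pixel_mm

    def pixel_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates in mm, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = (cols + 0.5) * self.pixel_mm - self.half_width_mm
        y = self.half_height_mm - (rows + 0.5) * self.pixel_mm
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def point_to_pixel(self, x_mm: float, y_mm: float) -> Tuple[int, int]:
        """Map a point to the (row, col) of the pixel containing it."""
        col = int(np.floor((x_mm + self.half_width_mm) / self.pixel_mm))
        row = int(np.floor((self.half_height_mm - y_mm) / self.pixel_mm))
        return row, col


@dataclass(frozen=True)
class PhantomGrid:
    """Dielectric maps of one axial breast slice."""

    grid: GridSpec
    eps_r: np.ndarray
    sigma: np.ndarray
    breast_mask: np.ndarray
    tumor: Optional[Tuple[Tuple[float, float], float]] = None
    seed: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("eps_r", "sigma", "breast_mask"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if np.any(self.eps_r[self.breast_mask] < 1):
            raise ValueError("eps_r must be >= 1 inside the breast")
        if np.any(self.sigma[~self.breast_mask] != 0):
            raise ValueError("sigma must be 0 outside the breast mask")


def _breast_ellipse(grid: GridSpec) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Breast mask and normalized elliptic radius for a grid.

    The semi-axes fill most of the grid, leaving a margin so antennas fit
    outside the breast: a_x = 0.92 * half-width, a_y = 0.90 * half-height.
    """
    ax = 0.92 * grid.half_width_mm
    ay = 0.90 * grid.half_height_mm
    if ax < 3 * SKIN_RIM_MM or ay < 3 * SKIN_RIM_MM:
        raise ValueError("grid too small to contain the breast ellipse")
    x, y = grid.pixel_centers()
    rho = np.sqrt((x / ax) ** 2 + (y / ay) ** 2)
    return rho <= 1.0, rho, ax, ay


def generate_phantom(
    seed: int,
    grid: Optional[GridSpec] = None,
    heterogeneity: float = 6.0,
) -> PhantomGrid:
    """Generate a synthetic heterogeneously dense breast slice.

    Parameters
    ----------
    seed
        Seed for the glandular texture; same seed gives bit-identical maps.
    grid
        Pixel grid; defaults to 71 x 91 at 1 mm.
    heterogeneity
        Gaussian smoothing length of the glandular texture in mm. Larger
        values give smoother tissue; in the constant-field limit the
        interior conductivity collapses to the 1.44 S/m midpoint.

    Returns
    -------
    PhantomGrid
        Interior sigma rescaled exactly onto [1.00, 1.88] S/m with eps_r
        co-varying linearly on [10, 55]; a 2 mm skin rim at
        eps_r=38, sigma=1.5 S/m; sigma=0 outside the breast.
    """
    if heterogeneity <= 0:
        raise ValueError("heterogeneity must be positive")
    grid = grid or GridSpec()
    breast_mask, rho, ax, ay = _breast_ellipse(grid)

    rim_frac = SKIN_RIM_MM / min(ax, ay)
    interior = rho <= 1.0 - rim_frac
    skin = breast_mask & ~interior

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    smooth = gaussian_filter(noise, sigma=heterogeneity / grid.pixel_mm, mode="reflect")

    sigma = np.zeros(grid.shape)
    eps_r = np.ones(grid.shape)
    vals = smooth[interior]
    span = vals.max() - vals.min()
    raw_span = noise.max() - noise.min()
    if span <= 1e-6 * raw_span:
        # Degenerate (infinitely smooth) texture: the smoothed field is flat
        # to within numerical residue, so rescaling would only amplify noise;
        # the closed-form limit is the constant midpoint.
        sig_in = np.full(vals.shape, 0.5 * (SIGMA_MIN + SIGMA_MAX))
    else:
        sig_in = SIGMA_MIN + (vals - vals.min()) / span * (SIGMA_MAX - SIGMA_MIN)
    sigma[interior] = sig_in
    eps_r[interior] = EPS_MIN + (sig_in - SIGMA_MIN) / (SIGMA_MAX - SIGMA_MIN) * (
        EPS_MAX - EPS_MIN
    )
    sigma[skin] = SKIN_SIGMA
    eps_r[skin] = SKIN_EPS
    return PhantomGrid(grid=grid, eps_r=eps_r, sigma=sigma, breast_mask=breast_mask, seed=seed)


def insert_tumor(
    phantom: PhantomGrid,
    center: Tuple[float, float],
    radius_mm: float = 5.0,
) -> PhantomGrid:
    """Insert a disc tumor (eps_r=40, sigma=2.0 S/m) into a phantom.

    Pixels whose centers lie within ``radius_mm`` of ``center`` are
    overwritten; the operation is idempotent and fails if the disc would
    extend outside the breast mask.
    """
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    x, y = phantom.grid.pixel_centers()
    disc = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius_mm**2
    if np.any(disc & ~phantom.breast_mask):
        raise ValueError("tumor disc extends outside the breast")
    eps_r = phantom.eps_r.copy()
    sigma = phantom.sigma.copy()
    eps_r[disc] = TUMOR_EPS
    sigma[disc] = TUMOR_SIGMA
    return replace(phantom, eps_r=eps_r, sigma=sigma, tumor=(tuple(center), radius_mm))


def save_phantom(phantom: PhantomGrid, path) -> None:
    """Write a phantom to an HDF5 container (datasets eps_r/sigma/breast_mask)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("eps_r", data=phantom.eps_r)
        f.create_dataset("sigma", data=phantom.sigma)
        f.create_dataset("breast_mask", data=phantom.breast_mask)
        f.attrs["pixel_mm"] = phantom.grid.pixel_mm
        if phantom.seed is not None:
            f.attrs["seed"] = phantom.seed
        if phantom.tumor is not None:
            (cx, cy), r = phantom.tumor
            f.attrs["tumor_center_mm"] = (cx, cy)
            f.attrs["tumor_radius_mm"] = r


def load_phantom(path) -> PhantomGrid:
    with h5py.File(path, "r") as f:
        eps_r = f["eps_r"][()]
        sigma = f["sigma"][()]
        mask = f["breast_mask"][()].astype(bool)
        grid = GridSpec(
            n_rows=eps_r.shape[0],
            n_cols=eps_r.shape[1],
            pixel_mm=float(f.attrs["pixel_mm"]),
        )
        tumor = None
        if "tumor_center_mm" in f.attrs:
            cx, cy = f.attrs["tumor_center_mm"]
            tumor = ((float(cx), float(cy)), float(f.attrs["tumor_radius_mm"]))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    return PhantomGrid(
        grid=grid, eps_r=eps_r, sigma=sigma, breast_mask=mask, tumor=tumor, seed=seed
    )


def export_csv(phantom: PhantomGrid, sigma_path, eps_path) -> None:
    """Dump the sigma and eps_r matrices as CSV for inspection."""
    np.savetxt(sigma_path, phantom.sigma, delimiter=",")
    np.savetxt(eps_path, phantom.eps_r, delimiter=",")
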