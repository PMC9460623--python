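"""Focusing-quality metrics: Omega_target, Omega_hotspot, Psi, P_av.

Omega_region is the percentage of the sigma-weighted total-field energy
deposited in a region relative to the whole breast,

    Omega = 100 * sum_region sigma |E_tot|^2 / sum_breast sigma |E_tot|^2,

equivalently a ratio of heating-potential sums (the 1/2 cancels). The
dominant hotspot is the 10 mm square window, disjoint from the target
square, that maximizes deposited energy in healthy tissue; the
hotspot-to-target ratio Psi = Omega_hotspot / Omega_target (lower is
better) penalizes plans that focus well but heat healthy tissue. P_av is
the mean heating potential over the target square, reported in kW/m^3 at
the 6 W total-input-power convention, so unlike the Omega ratios it is
scale-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .dataset import TargetSpec, build_mask
from .errors import ContractError, GeometryError, MetricError
from .excitation import (
    Excitation,
    HPMap,
    heating_potential,
    scale_to_total_power,
    superpose,
    TOTAL_POWER_W,
)
from .fieldsim import FieldSet
from .phantom import PhantomGrid

__all__ = [
    "MetricsReport",
    "omega_region",
    "find_dominant_hotspot",
    "psi",
    "p_av",
    "evaluate",
]


@dataclass(frozen=True)
class MetricsReport:
    """Per-case evaluation mirroring one excitation row of a results table."""

    omega_target: float  # percent
    omega_hotspot: float  # percent
    psi: float
    p_av_kw_m3: float
    hotspot_center_mm: Tuple[float, float]
    excitation: Excitation

    def __post_init__(self) -> None:
        for name in ("omega_target", "omega_hotspot"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise MetricError(f"{name}={v} outside [0, 100]%")
        if self.psi < 0:
            raise MetricError("psi must be non-negative")

    def as_dict(self) -> dict:
        return {
            "scheme": self.excitation.scheme,
            "phases_deg": [round(float(p), 2) for p in self.excitation.phases],
            "antenna_powers_w": [round(float(p), 3) for p in self.excitation.antenna_powers_w()],
            "omega_target_pct": self.omega_target,
            "omega_hotspot_pct": self.omega_hotspot,
            "psi": self.psi,
            "p_av_kw_m3": self.p_av_kw_m3,
            "hotspot_center_mm": list(self.hotspot_center_mm),
        }


def omega_region(hp: HPMap, phantom: PhantomGrid, region_mask: np.ndarray) -> float:
    """Percentage of in-breast deposited energy falling inside a region.

    Pixels outside the breast mask contribute to neither sum.
    """
    if hp.grid.shape != phantom.grid.shape:
        raise ContractError("heating potential and phantom grids differ")
    region = np.asarray(region_mask, dtype=bool) & phantom.breast_mask
    total = float(hp.q0[phantom.breast_mask].sum())
    if total <= 0:
        raise MetricError("zero breast-wide deposited energy")
    return 100.0 * float(hp.q0[region].sum()) / total


def _window_sums(q0: np.ndarray, w: int) -> np.ndarray:
    """Sum of q0 over every w x w window (integral-image trick)."""
    s = np.zeros((q0.shape[0] + 1, q0.shape[1] + 1))
    s[1:, 1:] = q0.cumsum(axis=0).cumsum(axis=1)
    return s[w:, w:] - s[:-w, w:] - s[w:, :-w] + s[:-w, :-w]


def find_dominant_hotspot(
    hp: HPMap, phantom: PhantomGrid, target: TargetSpec
) -> Tuple[np.ndarray, float]:
    """Best-scoring target-sized window disjoint from the target square.

    Slides a window congruent to the target square over every placement
    fully inside the grid, forbids any overlap with the target square, and
    returns (window mask, Omega over that window). Ties break toward the
    smallest row, then column.
    """
    grid = hp.grid
    w = max(1, int(round(target.side_mm / grid.pixel_mm)))
    tmask = build_mask(target, grid, phantom.breast_mask).astype(bool)
    rows, cols = np.nonzero(tmask)
    rt, ct = rows.min(), cols.min()
    sums = _window_sums(hp.q0, w)
    n_r, n_c = sums.shape
    rr = np.arange(n_r)[:, None]
    cc = np.arange(n_c)[None, :]
    overlap = (np.abs(rr - rt) < w) & (np.abs(cc - ct) < w)
    allowed = ~overlap
    if not allowed.any():
        raise GeometryError("breast too small to host a window disjoint from the target")
    scores = np.where(allowed, sums, -np.inf)
    best = int(np.argmax(scores))  # row-major argmax = smallest row, then col
    r0, c0 = divmod(best, n_c)
    window = np.zeros(grid.shape, dtype=bool)
    window[r0 : r0 + w, c0 : c0 + w] = True
    return window, omega_region(hp, phantom, window)


def psi(omega_hotspot: float, omega_target: float) -> float:
    """Hotspot-to-target ratio Psi = Omega_hotspot / Omega_target."""
    if omega_target <= 0:
        raise MetricError("psi undefined for zero target energy")
    return omega_hotspot / omega_target


def p_av(
    e_tot: np.ndarray,
    phantom: PhantomGrid,
    target: TargetSpec,
    include_half: bool = True,
) -> float:
    """Mean power deposition over the target square, in kW/m^3.

    Computed as the mean heating potential 0.5 sigma |E|^2 over the target
    pixels. ``include_half=False`` gives the variant without the 1/2
    factor (sum of sigma |E|^2 over the target area).
    """
    tmask = build_mask(target, phantom.grid, phantom.breast_mask).astype(bool)
    factor = 0.5 if include_half else 1.0
    q = factor * phantom.sigma * (np.abs(e_tot) ** 2).sum(axis=0)
    return float(q[tmask].mean()) / 1000.0


def evaluate(
    exc: Excitation,
    fs: FieldSet,
    phantom: PhantomGrid,
    target: TargetSpec,
    total_w: Optional[float] = TOTAL_POWER_W,
) -> MetricsReport:
    """Full per-case evaluation of an excitation.

    Scales the excitation to the 6 W total-input-power convention (P_av is
    scale-dependent; the Omega ratios are not), superposes the channel
    fields, computes the heating potential, and assembles the metric row.
    """
    if total_w is not None:
        exc = scale_to_total_power(exc, total_w)
    e_tot = superpose(fs, exc)
    hp = heating_potential(e_tot, phantom)
    tmask = build_mask(target, phantom.grid, phantom.breast_mask).astype(bool)
    om_t = omega_region(hp, phantom, tmask)
    window, om_h = find_dominant_hotspot(hp, phantom, target)
    x, y = phantom.grid.pixel_centers()
    center = (float(x[window].mean()), float(y[window].mean()))
    return MetricsReport(
        omega_target=om_t,
        omega_hotspot=om_h,
        psi=psi(om_h, om_t),
        p_av_kw_m3=p_av(e_tot, phantom, target),
        hotspot_center_mm=center,
        excitation=exc,
    )


def render_hp(
    hp: HPMap,
    phantom: PhantomGrid,
    target: TargetSpec,
    path,
    hotspot_window: Optional[np.ndarray] = None,
) -> None:
    """Save an HP map image with the target (and hotspot) squares outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    grid = hp.grid
    extent = [
        -grid.half_width_mm, grid.half_width_mm,
        -grid.half_height_mm, grid.half_height_mm,
    ]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(hp.q0, extent=extent, cmap="inferno")
    fig.colorbar(im, ax=ax, label="Q0 (W/m^3)")
    cx, cy = target.center
    h = target.side_mm / 2
    ax.add_patch(Rectangle((cx - h, cy - h), target.side_mm, target.side_mm,
                           fill=False, edgecolor="cyan", lw=1.5))
    if hotspot_window is not None and hotspot_window.any():
        x, y = grid.pixel_centers()
        hx = x[hotspot_window]
        hy = y[hotspot_window]
        side = hotspot_window.any(axis=0).sum() * grid.pixel_mm
        ax.add_patch(Rectangle((hx.min() - grid.pixel_mm / 2, hy.min() - grid.pixel_mm / 2),
                               side, side, fill=False, edgecolor="lime", lw=1.5))
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
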