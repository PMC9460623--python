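"""Brute-force look-up-table baselines.

The baseline optimizer enumerates excitation grids exhaustively and keeps
the cell maximizing the target energy fraction Omega_target: all integer
degree pairs of the linear scheme's two free phases (360 x 360 = 129,600
cells), and, at the phase optimum, all per-channel voltages on a
0-1 V grid with 0.025 V increments (41^4 = 2,825,761 cells). Hotspots are
deliberately not part of this objective — that asymmetry versus the
CNN planner is the point of the comparison.

Because Omega_target is a ratio of two Hermitian quadratic forms in the
channel coefficients,

    Omega(w) = 100 * (w^H M_target w) / (w^H M_breast w),
    M_region[i, j] = sum_{r in region} sigma(r) sum_c conj(E_ic) E_jc,

each cell costs O(N^2) after the two N x N Gram matrices are precomputed,
so the full printed tables evaluate in seconds. Evaluation runs in
configurable blocks and is verified against a scalar per-pixel loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .dataset import TargetSpec, build_mask
from .errors import MetricError
from .excitation import expand_free_phases, free_phase_count, wrap_phase
from .fieldsim import FieldSet
from .phantom import PhantomGrid

__all__ = ["LookupResult", "region_gram", "phase_lookup", "voltage_lookup"]

MAX_CELLS = 10_000_000


@dataclass(frozen=True)
class LookupResult:
    """Best cell of an exhaustive excitation search."""

    free_values: np.ndarray  # winning free phases (deg) or voltages (V)
    phases: np.ndarray  # full phase vector of the winning cell (deg)
    omega_target: float  # percent
    n_cells: int
    top_k: Optional[list] = None


def region_gram(fs: FieldSet, phantom: PhantomGrid, region_mask: np.ndarray) -> np.ndarray:
    """Hermitian N x N Gram matrix of the channel fields over a region.

    gram[i, j] = sum_{r in region} sigma(r) * sum_c conj(E_ic(r)) E_jc(r),
    so that sigma-weighted total-field energy in the region equals
    w^H gram w for channel coefficients w.
    """
    region = np.asarray(region_mask, dtype=bool) & phantom.breast_mask
    sig = phantom.sigma[region]
    # (N, C, P) with P region pixels
    e = fs.fields[:, :, region]
    weighted = e * sig
    return np.einsum("icp,jcp->ij", np.conj(e), weighted)


def omega_from_grams(
    w: np.ndarray, gram_target: np.ndarray, gram_breast: np.ndarray
) -> np.ndarray:
    """Omega_target (%) for a batch of coefficient vectors (K, N)."""
    num = np.einsum("ki,ij,kj->k", np.conj(w), gram_target, w).real
    den = np.einsum("ki,ij,kj->k", np.conj(w), gram_breast, w).real
    if np.any(den <= 0):
        raise MetricError("zero breast-wide energy in a look-up cell")
    return 100.0 * num / den


def _expand_batch(scheme: str, free: np.ndarray) -> np.ndarray:
    """Vectorized scheme-constraint expansion of (K, n_free) free phases."""
    free = np.asarray(free, dtype=float)
    k = free.shape[0]
    if scheme == "linear":
        full = np.zeros((k, 4))
        full[:, 1] = wrap_phase(free[:, 0])
        full[:, 2] = wrap_phase(free[:, 1])
        full[:, 3] = wrap_phase(free[:, 0] + free[:, 1])
        return full
    full = np.zeros((k, 12))
    full[:, 1::2] = wrap_phase(free)
    for idx in (2, 4, 6, 8, 10):  # 0-based odd antennas 3..11
        full[:, idx] = wrap_phase(full[:, idx - 1] + full[:, idx + 1])
    return full


def _grams(fs: FieldSet, phantom: PhantomGrid, target: TargetSpec):
    tmask = build_mask(target, fs.grid, phantom.breast_mask).astype(bool)
    return region_gram(fs, phantom, tmask), region_gram(fs, phantom, phantom.breast_mask)


def phase_lookup(
    fs: FieldSet,
    phantom: PhantomGrid,
    target: TargetSpec,
    step_deg: float = 1.0,
    block: int = 65536,
    top_k: int = 0,
) -> LookupResult:
    """Exhaustive integer-degree search over the scheme's free phases.

    Enumerates the Cartesian grid {0, step, ..., 360-step}^n_free at unit
    voltages, scores every cell by Omega_target, and returns the first
    occurrence of the maximum in lexicographic free-phase order. Refuses
    projected enumerations above ten million cells.
    """
    n_free = free_phase_count(fs.layout.scheme)
    levels = int(round(360.0 / step_deg))
    n_cells = levels**n_free
    if n_cells > MAX_CELLS:
        raise MetricError(
            f"phase table would need {n_cells:,} cells (> {MAX_CELLS:,}); "
            "use a coarser step"
        )
    gram_t, gram_b = _grams(fs, phantom, target)
    values = np.arange(levels) * step_deg
    grids = np.meshgrid(*([values] * n_free), indexing="ij")
    free = np.stack([g.ravel() for g in grids], axis=1)  # lexicographic

    best_idx, best_omega = -1, -np.inf
    scores = np.empty(n_cells) if top_k else None
    for start in range(0, n_cells, block):
        fp = free[start : start + block]
        full = _expand_batch(fs.layout.scheme, fp)
        w = np.exp(1j * np.deg2rad(full))
        om = omega_from_grams(w, gram_t, gram_b)
        if scores is not None:
            scores[start : start + len(om)] = om
        i = int(np.argmax(om))
        if om[i] > best_omega:
            best_omega, best_idx = float(om[i]), start + i
    top = None
    if top_k:
        order = np.argsort(scores)[::-1][:top_k]
        top = [(free[i].tolist(), float(scores[i])) for i in order]
    return LookupResult(
        free_values=free[best_idx],
        phases=expand_free_phases(fs.layout.scheme, free[best_idx]),
        omega_target=best_omega,
        n_cells=n_cells,
        top_k=top,
    )


def voltage_lookup(
    fs: FieldSet,
    phantom: PhantomGrid,
    target: TargetSpec,
    fixed_phases: np.ndarray,
    v_min: float = 0.0,
    v_max: float = 1.0,
    v_step: float = 0.025,
    block: int = 200_000,
    top_k: int = 0,
) -> LookupResult:
    """Exhaustive per-channel voltage search at a fixed phase vector.

    Enumerates ``levels`` voltage values per channel (41 for the default
    0-1 V / 0.025 V grid, i.e. 41^4 cells for the linear scheme), skips the
    all-zero cell (Omega undefined), and returns the argmax of
    Omega_target. Omega is invariant to uniform voltage scaling, so the
    winning voltages are conventionally reported after 6 W scaling.
    """
    levels = int(round((v_max - v_min) / v_step)) + 1
    n = fs.n_channels
    n_cells = levels**n
    if n_cells > MAX_CELLS:
        raise MetricError(
            f"voltage table would need {n_cells:,} cells (> {MAX_CELLS:,})"
        )
    gram_t, gram_b = _grams(fs, phantom, target)
    fixed_phases = np.asarray(fixed_phases, dtype=float)
    u = np.exp(1j * np.deg2rad(fixed_phases))
    # Real symmetric forms: Omega(v) = 100 (v^T A v) / (v^T B v).
    a_t = (np.conj(u)[:, None] * gram_t * u[None, :]).real
    a_b = (np.conj(u)[:, None] * gram_b * u[None, :]).real

    values = v_min + np.arange(levels) * v_step
    grids = np.meshgrid(*([values] * n), indexing="ij")
    volts = np.stack([g.ravel() for g in grids], axis=1)

    best_idx, best_omega = -1, -np.inf
    scores = np.full(n_cells, -np.inf) if top_k else None
    for start in range(0, n_cells, block):
        v = volts[start : start + block]
        num = np.einsum("ki,ij,kj->k", v, a_t, v)
        den = np.einsum("ki,ij,kj->k", v, a_b, v)
        om = np.full(len(v), -np.inf)
        ok = den > 0  # the all-zero cell (and only it) has zero energy
        om[ok] = 100.0 * num[ok] / den[ok]
        if scores is not None:
            scores[start : start + len(om)] = om
        i = int(np.argmax(om))
        if om[i] > best_omega:
            best_omega, best_idx = float(om[i]), start + i
    top = None
    if top_k:
        order = np.argsort(scores)[::-1][:top_k]
        top = [(volts[i].tolist(), float(scores[i])) for i in order]
    return LookupResult(
        free_values=volts[best_idx],
        phases=fixed_phases,
        omega_target=best_omega,
        n_cells=n_cells,
        top_k=top,
    )
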