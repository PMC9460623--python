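"""Training-corpus generation by field superposition, and masked-target inputs.

The two-stage optimizer is trained entirely on synthetic corpora built from
the N unit-drive channel fields: the phase stage on normalized
heating-potential maps produced by random integer free phases at unit
voltages, the voltage stage on maps produced by random integer voltages
(0-9 V) at a fixed phase vector. Phase labels are (sin, cos) pairs of each
free phase — a continuous encoding without the 360-degree wrap
discontinuity; voltage labels are rescaled onto [0, 1] by /9.

At inference time the desired (unknown) heating map is replaced by a binary
mask: 1 on a 10 mm square centred at the target point, 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import h5py
import numpy as np

from . import excitation as exc_mod
from .errors import GeometryError
from .excitation import expand_free_phases, free_phase_count
from .fieldsim import FieldSet, N_CHANNELS
from .phantom import GridSpec, PhantomGrid

__all__ = [
    "TargetSpec",
    "TrainingSet",
    "sample_free_phases",
    "sample_voltages",
    "build_phase_dataset",
    "build_voltage_dataset",
    "build_mask",
    "encode_phases",
    "decode_phases",
    "save_training_set",
    "load_training_set",
]

DEFAULT_M = {"linear": 2000, "circular": 50000}
VOLTAGE_LEVELS = 10  # integer voltages 0..9 V
TRAIN_FRACTION = 0.8
_CHUNK = 256


@dataclass(frozen=True)
class TargetSpec:
    """Desired focus region: a square of side_mm centred at ``center`` (mm)."""

    center: Tuple[float, float]
    side_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.side_mm <= 0:
            raise ValueError("target side must be positive")


@dataclass(frozen=True)
class TrainingSet:
    """Normalized HP inputs with phase or voltage labels and an 80-20 split."""

    inputs: np.ndarray  # (M, n_rows, n_cols) float32, each min 0 / max 1
    labels: np.ndarray  # (M, L) float
    train_idx: np.ndarray
    val_idx: np.ndarray
    scheme: str
    kind: str  # "phase" | "voltage"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.inputs.shape[0] != self.labels.shape[0]:
            raise ValueError("inputs and labels must align")
        both = np.concatenate([self.train_idx, self.val_idx])
        if len(np.unique(both)) != self.inputs.shape[0]:
            raise ValueError("split must be disjoint and exhaustive")

    @property
    def m(self) -> int:
        return self.inputs.shape[0]


def _split_indices(m: int, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    n_train = int(round(TRAIN_FRACTION * m))
    return perm[:n_train], perm[n_train:]


def sample_free_phases(seed: int, m: int, scheme: str) -> np.ndarray:
    """Uniform integer-degree free phases in {0, ..., 359}, (m, n_free)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 360, size=(m, free_phase_count(scheme)))


def sample_voltages(seed: int, m: int, scheme: str) -> np.ndarray:
    """Uniform integer voltages in {0, ..., 9} V per channel, (m, N).

    All-zero vectors are degenerate (no field to normalize) and are
    re-drawn.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.integers(0, VOLTAGE_LEVELS, size=(m, N_CHANNELS[scheme]))
    while True:
        zero = ~v.any(axis=1)
        if not zero.any():
            return v
        v[zero] = rng.integers(0, VOLTAGE_LEVELS, size=(int(zero.sum()), v.shape[1]))


def _normalized_hp_batch(
    fs: FieldSet, phantom: PhantomGrid, coeffs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized HP maps for a (m, N) complex coefficient batch.

    Returns (maps float32 (m, H, W), keep mask) — constant (zero-span) maps
    are flagged rather than normalized.
    """
    m = coeffs.shape[0]
    out = np.empty((m,) + fs.grid.shape, dtype=np.float32)
    keep = np.ones(m, dtype=bool)
    sigma = phantom.sigma
    for start in range(0, m, _CHUNK):
        c = coeffs[start : start + _CHUNK]
        e_tot = np.tensordot(c, fs.fields, axes=(1, 0))  # (chunk, C, H, W)
        q0 = 0.5 * sigma * (np.abs(e_tot) ** 2).sum(axis=1)
        lo = q0.min(axis=(1, 2), keepdims=True)
        hi = q0.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        flat = span[:, 0, 0] <= 0
        keep[start : start + c.shape[0]] = ~flat
        span[span <= 0] = 1.0
        out[start : start + c.shape[0]] = ((q0 - lo) / span).astype(np.float32)
    return out, keep


def build_phase_dataset(
    fs: FieldSet,
    phantom: PhantomGrid,
    free_phases: np.ndarray,
    seed: int = 0,
) -> TrainingSet:
    """Phase-stage corpus: unit voltages, random free phases, sin/cos labels.

    Each sample expands its free phases through the scheme constraint,
    superposes the channel fields, converts to heating potential and
    min-max normalizes. Constant maps (which cannot occur for unit
    voltages unless the fields are degenerate) are rejected.
    """
    free_phases = np.asarray(free_phases, dtype=float)
    scheme = fs.layout.scheme
    full = np.stack([expand_free_phases(scheme, fp) for fp in free_phases])
    coeffs = np.exp(1j * np.deg2rad(full))  # unit voltages on all channels
    inputs, keep = _normalized_hp_batch(fs, phantom, coeffs)
    if not keep.all():
        inputs = inputs[keep]
        free_phases = free_phases[keep]
    labels = encode_phases(free_phases)
    train_idx, val_idx = _split_indices(inputs.shape[0], seed)
    return TrainingSet(
        inputs=inputs, labels=labels, train_idx=train_idx, val_idx=val_idx,
        scheme=scheme, kind="phase", seed=seed,
    )


def build_voltage_dataset(
    fs: FieldSet,
    phantom: PhantomGrid,
    fixed_phases: np.ndarray,
    voltages: np.ndarray,
    seed: int = 0,
) -> TrainingSet:
    """Voltage-stage corpus: fixed phases, random voltages, labels = V/9."""
    fixed_phases = np.asarray(fixed_phases, dtype=float)
    scheme = fs.layout.scheme
    # Validate the fixed phases against the scheme constraint.
    exc_mod.Excitation(scheme=scheme, voltages=np.ones(fs.n_channels), phases=fixed_phases)
    voltages = np.asarray(voltages, dtype=float)
    coeffs = voltages * np.exp(1j * np.deg2rad(fixed_phases))[None, :]
    inputs, keep = _normalized_hp_batch(fs, phantom, coeffs)
    if not keep.all():
        inputs = inputs[keep]
        voltages = voltages[keep]
    labels = voltages / (VOLTAGE_LEVELS - 1)
    train_idx, val_idx = _split_indices(inputs.shape[0], seed)
    return TrainingSet(
        inputs=inputs, labels=labels, train_idx=train_idx, val_idx=val_idx,
        scheme=scheme, kind="voltage", seed=seed,
    )


def build_mask(
    target: TargetSpec,
    grid: GridSpec,
    breast_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary masked-target input: 1 on the target square, 0 elsewhere.

    The square covers pixels whose centers fall in the half-open box
    [cx - s/2, cx + s/2) x [cy - s/2, cy + s/2). If ``breast_mask`` is
    given, the square must lie wholly inside the breast.
    """
    x, y = grid.pixel_centers()
    cx, cy = target.center
    h = target.side_mm / 2.0
    inside = (x >= cx - h) & (x < cx + h) & (y >= cy - h) & (y < cy + h)
    if not inside.any():
        raise GeometryError("target square contains no pixel centers")
    if breast_mask is not None and np.any(inside & ~breast_mask):
        raise GeometryError("target square crosses the breast boundary")
    return inside.astype(np.float32)


def encode_phases(phases_deg: np.ndarray) -> np.ndarray:
    """Interleaved (sin, cos) encoding of phases in degrees.

    For input (..., K) the output is (..., 2K) laid out as
    [sin p1, cos p1, sin p2, cos p2, ...].
    """
    p = np.deg2rad(np.asarray(phases_deg, dtype=float))
    out = np.empty(p.shape[:-1] + (2 * p.shape[-1],))
    out[..., 0::2] = np.sin(p)
    out[..., 1::2] = np.cos(p)
    return out


def decode_phases(vector: np.ndarray) -> np.ndarray:
    """Invert the sin/cos encoding via atan2, projecting off-circle pairs.

    Accepts (..., 2K) regression outputs; (0, 0) pairs have no defined
    angle and raise.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] % 2:
        raise ValueError("sin/cos vector length must be even")
    s = v[..., 0::2]
    c = v[..., 1::2]
    if np.any((s == 0) & (c == 0)):
        raise ValueError("(0, 0) sin/cos pair has no defined phase")
    from .excitation import wrap_phase

    return np.atleast_1d(wrap_phase(np.rad2deg(np.arctan2(s, c))))


def save_training_set(ts: TrainingSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ts.inputs, compression="gzip")
        f.create_dataset("labels", data=ts.labels)
        f.create_dataset("train_idx", data=ts.train_idx)
        f.create_dataset("val_idx", data=ts.val_idx)
        f.attrs["scheme"] = ts.scheme
        f.attrs["kind"] = ts.kind
        if ts.seed is not None:
            f.attrs["seed"] = ts.seed


def load_training_set(path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        return TrainingSet(
            inputs=f["inputs"][()],
            labels=f["labels"][()],
            train_idx=f["train_idx"][()],
            val_idx=f["val_idx"][()],
            scheme=str(f.attrs["scheme"]),
            kind=str(f.attrs["kind"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
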