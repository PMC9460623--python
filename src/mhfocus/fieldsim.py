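"""Per-antenna unit-excitation fields on the phantom grid.

Each applicator channel is simulated with a deterministic cylindrical-wave
model: a channel's complex vector field is the sum over its member antennas
of

    s(r) = A * exp(-j * kbar(r) * d(r)) / sqrt(max(d(r), d_min))

where ``d`` is the antenna-to-pixel distance and ``kbar`` the complex
wavenumber k = omega * sqrt(mu0*eps0*(eps_r - j*sigma/(omega*eps0)))
averaged along the straight ray from the antenna to the pixel. The scalar
``s`` is assigned to the in-plane unit vector transverse to the ray, giving
two field components per pixel. The model captures the two features the
excitation optimizer exploits — phase accumulation and lossy attenuation
through heterogeneous tissue — while ignoring scattering and multipath
(a documented fidelity limit). Time convention is e^{+j omega t}, so lossy
media have Im(k) < 0 and e^{-j k d} decays.

Externally computed fields (e.g., FEM exports) can be dropped in through
the HDF5 container contract implemented by :func:`save_fieldset` /
:func:`load_fieldset`; every downstream module depends only on the
:class:`FieldSet` contract, never on how the fields were produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import h5py
import numpy as np

from .errors import ContractError, FormatError, GeometryError
from .phantom import GridSpec, PhantomGrid

__all__ = [
    "AntennaLayout",
    "FieldSet",
    "make_layout",
    "antenna_field",
    "simulate_unit_fields",
    "save_fieldset",
    "load_fieldset",
    "complex_wavenumber",
]

FREQUENCY_HZ = 2.45e9
PORT_RESISTANCE_OHM = 50.0
MU0 = 4e-7 * np.pi
EPS0 = 8.8541878128e-12

#: Source calibration constant (V/m * sqrt(mm) per volt of drive): fixes the
#: absolute field scale of the synthetic model; all Omega/Psi metrics are
#: scale-invariant, only P_av depends on it.
SOURCE_AMPLITUDE = 150.0

#: Samples used for the ray average of the complex wavenumber.
_RAY_SAMPLES = 48

N_CHANNELS = {"linear": 4, "circular": 12}
N_ANTENNAS = 12


@dataclass(frozen=True)
class AntennaLayout:
    """Applicator geometry: 12 antennas grouped into N excitation channels."""

    scheme: str
    positions: np.ndarray  # (12, 2) mm
    channel_index: np.ndarray  # (12,) 0-based channel of each antenna

    def __post_init__(self) -> None:
        if self.scheme not in N_CHANNELS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.positions.shape != (N_ANTENNAS, 2):
            raise ValueError("expected 12 antenna positions")

    @property
    def n_antennas(self) -> int:
        return N_ANTENNAS

    @property
    def n_channels(self) -> int:
        return N_CHANNELS[self.scheme]

    @property
    def antennas_per_channel(self) -> int:
        return N_ANTENNAS // self.n_channels

    def channel_of_antenna(self, antenna_no: int) -> int:
        """1-based antenna number -> 1-based channel number."""
        if not 1 <= antenna_no <= N_ANTENNAS:
            raise ValueError("antenna number must be in 1..12")
        return int(self.channel_index[antenna_no - 1]) + 1

    def channel_members(self, channel: int) -> List[int]:
        """0-based antenna indices driven by 0-based ``channel``."""
        return [int(i) for i in np.flatnonzero(self.channel_index == channel)]


@dataclass(frozen=True)
class FieldSet:
    """N per-channel unit-drive complex vector fields on one grid."""

    grid: GridSpec
    layout: AntennaLayout
    fields: np.ndarray  # (N, n_components, n_rows, n_cols) complex
    frequency_hz: float = FREQUENCY_HZ
    port_resistance_ohm: float = PORT_RESISTANCE_OHM

    def __post_init__(self) -> None:
        n, c = self.fields.shape[:2]
        if n != self.layout.n_channels:
            raise ContractError(
                f"{n} fields but layout has {self.layout.n_channels} channels"
            )
        if c not in (1, 2, 3):
            raise FormatError("fields must have 1-3 spatial components")
        if self.fields.shape[2:] != self.grid.shape:
            raise FormatError("field maps do not match the grid shape")
        if not np.all(np.isfinite(self.fields.view(float))):
            raise FormatError("fields must be finite everywhere")

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels


def make_layout(scheme: str, grid: GridSpec, phantom: PhantomGrid | None = None) -> AntennaLayout:
    """Build the linear or circular applicator geometry for a grid.

    linear: two rows of 6 antennas 20 mm apart above and below the breast,
    grouped into 4 channels of 3 contiguous antennas (1-3, 4-6, 7-9, 10-12).
    circular: 12 antennas at 30 degree separation on a circle concentric
    with the grid, one channel each.
    """
    if scheme == "linear":
        xs = (np.arange(6) - 2.5) * 20.0
        y_off = 0.97 * grid.half_height_mm
        top = np.column_stack([xs, np.full(6, y_off)])
        bottom = np.column_stack([xs, np.full(6, -y_off)])
        positions = np.vstack([top, bottom])
        channel_index = np.repeat(np.arange(4), 3)
    elif scheme == "circular":
        radius = 1.15 * max(0.92 * grid.half_width_mm, 0.90 * grid.half_height_mm)
        angles = np.deg2rad(90.0 - 30.0 * np.arange(12))
        positions = radius * np.column_stack([np.cos(angles), np.sin(angles)])
        channel_index = np.arange(12)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if phantom is not None:
        for x, y in positions:
            r, c = grid.point_to_pixel(x, y)
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols and phantom.breast_mask[r, c]:
                raise GeometryError(f"antenna at ({x:.1f}, {y:.1f}) mm lies inside the breast")
    return AntennaLayout(scheme=scheme, positions=positions, channel_index=channel_index)


def complex_wavenumber(eps_r: np.ndarray, sigma: np.ndarray, frequency_hz: float = FREQUENCY_HZ) -> np.ndarray:
    """Complex wavenumber map (rad/m) with the Im(k) < 0 lossy convention."""
    omega = 2 * np.pi * frequency_hz
    eps_c = eps_r - 1j * sigma / (omega * EPS0)
    return omega * np.sqrt(MU0 * EPS0 * eps_c)


def antenna_field(
    phantom: PhantomGrid,
    position: Sequence[float],
    frequency_hz: float = FREQUENCY_HZ,
    amplitude: float = SOURCE_AMPLITUDE,
) -> np.ndarray:
    """Unit-drive field (2, n_rows, n_cols) of a single antenna."""
    grid = phantom.grid
    x, y = grid.pixel_centers()
    xa, ya = float(position[0]), float(position[1])
    dx = x - xa
    dy = y - ya
    d_mm = np.hypot(dx, dy)
    d_eff = np.maximum(d_mm, grid.pixel_mm)  # guards the source singularity

    kmap = complex_wavenumber(phantom.eps_r, phantom.sigma, frequency_hz)

    # Average k along straight rays from the antenna to every pixel center.
    t = ((np.arange(_RAY_SAMPLES) + 0.5) / _RAY_SAMPLES)[:, None, None]
    px = xa + t * dx
    py = ya + t * dy
    cols = np.clip(
        np.floor((px + grid.half_width_mm) / grid.pixel_mm).astype(np.intp),
        0,
        grid.n_cols - 1,
    )
    rows = np.clip(
        np.floor((grid.half_height_mm - py) / grid.pixel_mm).astype(np.intp),
        0,
        grid.n_rows - 1,
    )
    kbar = kmap[rows, cols].mean(axis=0)

    s = amplitude * np.exp(-1j * kbar * (d_mm / 1000.0)) / np.sqrt(d_eff)

    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(d_mm > 0, dx / np.where(d_mm > 0, d_mm, 1.0), 1.0)
        uy = np.where(d_mm > 0, dy / np.where(d_mm > 0, d_mm, 1.0), 0.0)
    # In-plane unit vector transverse to the ray carries the scalar wave.
    return np.stack([-uy * s, ux * s])


def simulate_unit_fields(phantom: PhantomGrid, layout: AntennaLayout) -> FieldSet:
    """Simulate the per-channel unit-excitation fields for an applicator.

    Each channel field is the coherent sum of its member antennas' single
    antenna fields (3 antennas per channel for the linear scheme, 1 for
    the circular scheme), all driven at 1 V and zero phase.
    """
    grid = phantom.grid
    per_antenna = np.stack(
        [antenna_field(phantom, pos) for pos in layout.positions]
    )  # (12, 2, H, W)
    fields = np.stack(
        [per_antenna[layout.channel_members(ch)].sum(axis=0) for ch in range(layout.n_channels)]
    )
    return FieldSet(grid=grid, layout=layout, fields=fields)


def save_fieldset(fs: FieldSet, path) -> None:
    """Write a FieldSet to its HDF5 container.

    Contract: complex datasets ``field_000`` ... ``field_{N-1}`` shaped
    (components, n_rows, n_cols); attributes ``frequency_hz``,
    ``port_resistance_ohm``, ``pixel_mm``, ``scheme``; datasets
    ``antenna_positions`` (12, 2) mm and ``channel_index`` (12,).
    Fields follow the e^{+j omega t} convention (Im(k) < 0 in lossy media).
    """
    with h5py.File(path, "w") as f:
        for i in range(fs.n_channels):
            f.create_dataset(f"field_{i:03d}", data=fs.fields[i])
        f.attrs["frequency_hz"] = fs.frequency_hz
        f.attrs["port_resistance_ohm"] = fs.port_resistance_ohm
        f.attrs["pixel_mm"] = fs.grid.pixel_mm
        f.attrs["scheme"] = fs.layout.scheme
        f.create_dataset("antenna_positions", data=fs.layout.positions)
        f.create_dataset("channel_index", data=fs.layout.channel_index)


def load_fieldset(path) -> FieldSet:
    """Load a FieldSet container, validating the contract."""
    with h5py.File(path, "r") as f:
        try:
            scheme = str(f.attrs["scheme"])
            pixel_mm = float(f.attrs["pixel_mm"])
            frequency = float(f.attrs["frequency_hz"])
            resistance = float(f.attrs["port_resistance_ohm"])
            positions = f["antenna_positions"][()]
            channel_index = f["channel_index"][()]
        except KeyError as exc:
            raise FormatError(f"missing dataset/attribute: {exc}") from exc
        if scheme not in N_CHANNELS:
            raise FormatError(f"unknown scheme {scheme!r}")
        n = N_CHANNELS[scheme]
        names = [f"field_{i:03d}" for i in range(n)]
        missing = [nm for nm in names if nm not in f]
        if missing:
            raise FormatError(
                f"container has fewer fields than the {n}-channel {scheme} scheme "
                f"requires (missing {missing[0]})"
            )
        fields = np.stack([np.asarray(f[nm], dtype=complex) for nm in names])
    if fields.ndim != 4:
        raise FormatError("field datasets must be (components, n_rows, n_cols)")
    grid = GridSpec(n_rows=fields.shape[2], n_cols=fields.shape[3], pixel_mm=pixel_mm)
    layout = AntennaLayout(
        scheme=scheme, positions=np.asarray(positions, dtype=float),
        channel_index=np.asarray(channel_index, dtype=int),
    )
    return FieldSet(
        grid=grid, layout=layout, fields=fields,
        frequency_hz=frequency, port_resistance_ohm=resistance,
    )


def export_magnitude_csv(fs: FieldSet, directory) -> None:
    """CSV dump of |E_i| (root-sum-square over components) per channel."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(fs.n_channels):
        mag = np.sqrt((np.abs(fs.fields[i]) ** 2).sum(axis=0))
        np.savetxt(directory / f"field_{i:03d}_mag.csv", mag, delimiter=",")
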