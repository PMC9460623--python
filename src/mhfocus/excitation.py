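"""Antenna excitations: phase-constraint schemes, superposition, heating potential.

An excitation is the complex drive of each applicator channel — a voltage
amplitude a_i (V) and a phase phi_i (degrees). The total field at a single
frequency is the superposition

    E_tot(r) = sum_i a_i * E_i(r) * exp(j * phi_i)

over the per-channel unit-drive fields, and the heating potential is

    Q0(r) = 0.5 * sigma(r) * |E_tot(r)|^2   (W/m^3),

with |.|^2 the sum over components of squared complex moduli (no
real-field simplification). Phase-constraint schemes reduce the search
space: phi_1 = 0 is the reference in both applicators; the linear scheme
ties phi_4 = phi_2 + phi_3, and the circular scheme assigns each
odd-numbered antenna the wrapped sum of its two even neighbours.

Port power accounting uses P = V^2 / R at R = 50 ohm (so a 1 V drive is
0.02 W), and the reporting convention fixes the total input power over all
12 physical antennas to 6 W: a linear channel drives 3 antennas, so its
voltage counts three times in the power budget.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from .errors import ContractError, DegenerateExcitationError, MetricError
from .fieldsim import FieldSet, N_CHANNELS, PORT_RESISTANCE_OHM
from .phantom import GridSpec, PhantomGrid

__all__ = [
    "Excitation",
    "HPMap",
    "wrap_phase",
    "linear_phase_vector",
    "circular_phase_vector",
    "free_phase_count",
    "expand_free_phases",
    "superpose",
    "superpose_coefficients",
    "heating_potential",
    "port_power",
    "scale_to_total_power",
    "normalize_hp",
    "save_excitation",
    "load_excitation",
]

TOTAL_POWER_W = 6.0

#: Free (independently chosen) phases per scheme: linear -> (phi2, phi3);
#: circular -> even-numbered antennas (2, 4, 6, 8, 10, 12).
FREE_PHASES = {"linear": 2, "circular": 6}

_ANTENNAS_PER_CHANNEL = {"linear": 3, "circular": 1}


def wrap_phase(deg):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    deg = np.asarray(deg, dtype=float)
    if not np.all(np.isfinite(deg)):
        raise ValueError("phase must be finite")
    wrapped = 180.0 - np.mod(180.0 - deg, 360.0)
    return wrapped if wrapped.ndim else float(wrapped)


def linear_phase_vector(phi2: float, phi3: float) -> np.ndarray:
    """Full 4-channel phase vector of the linear applicator.

    phi1 is the 0-degree reference and phi4 = phi2 + phi3 (wrapped).
    """
    return np.array([0.0, wrap_phase(phi2), wrap_phase(phi3), wrap_phase(phi2 + phi3)])


def circular_phase_vector(even_phases: Sequence[float]) -> np.ndarray:
    """Full 12-antenna phase vector of the circular applicator.

    ``even_phases`` are the six free phases of antennas 2, 4, 6, 8, 10, 12;
    each odd antenna k in {3, 5, 7, 9, 11} gets wrap(phi_{k-1} + phi_{k+1})
    and antenna 1 is the 0-degree reference.
    """
    ev = np.asarray(even_phases, dtype=float)
    if ev.shape != (6,):
        raise ValueError("expected 6 even-antenna phases")
    phases = np.zeros(12)
    phases[1::2] = wrap_phase(ev)  # antennas 2,4,6,8,10,12 (0-based odd indices)
    for k in (3, 5, 7, 9, 11):  # 1-based odd antennas
        phases[k - 1] = wrap_phase(phases[k - 2] + phases[k])
    return phases


def free_phase_count(scheme: str) -> int:
    return FREE_PHASES[scheme]


def expand_free_phases(scheme: str, free: Sequence[float]) -> np.ndarray:
    """Expand a free-phase vector to the scheme's full phase vector."""
    free = np.asarray(free, dtype=float)
    if scheme == "linear":
        if free.shape != (2,):
            raise ValueError("linear scheme has 2 free phases")
        return linear_phase_vector(free[0], free[1])
    if scheme == "circular":
        return circular_phase_vector(free)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass(frozen=True)
class Excitation:
    """Per-channel voltage amplitudes (V) and phases (degrees)."""

    scheme: str
    voltages: np.ndarray
    phases: np.ndarray
    port_resistance_ohm: float = PORT_RESISTANCE_OHM

    def __post_init__(self) -> None:
        n = N_CHANNELS[self.scheme]
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))
        object.__setattr__(
            self, "phases", np.atleast_1d(wrap_phase(np.asarray(self.phases, dtype=float)))
        )
        if self.voltages.shape != (n,) or self.phases.shape != (n,):
            raise ContractError(f"{self.scheme} scheme needs {n} voltages and phases")
        if np.any(self.voltages < 0):
            raise ValueError("voltages must be non-negative")
        self.validate_phases()

    @property
    def n_channels(self) -> int:
        return N_CHANNELS[self.scheme]

    @property
    def antennas_per_channel(self) -> int:
        return _ANTENNAS_PER_CHANNEL[self.scheme]

    def validate_phases(self, tol_deg: float = 0.05) -> None:
        """Check the scheme's phase constraints (reference + tied sums)."""
        p = self.phases
        if abs(wrap_phase(p[0])) > tol_deg:
            raise ValueError("phi1 must be the 0-degree reference")
        if self.scheme == "linear":
            resid = wrap_phase(p[3] - p[1] - p[2])
        else:
            odd = np.array([2, 4, 6, 8, 10])  # 0-based indices of antennas 3..11
            resid = wrap_phase(p[odd] - p[odd - 1] - p[odd + 1])
        if np.any(np.abs(np.atleast_1d(resid)) > tol_deg):
            raise ValueError("phases violate the scheme's tied-sum constraint")

    def coefficients(self) -> np.ndarray:
        """Complex channel coefficients a_i * exp(j phi_i)."""
        return self.voltages * np.exp(1j * np.deg2rad(self.phases))

    def total_antenna_power_w(self) -> float:
        """Total input power summed over all 12 physical antennas."""
        per_channel = port_power(self.voltages, self.port_resistance_ohm)
        return float(self.antennas_per_channel * np.sum(per_channel))

    def antenna_powers_w(self) -> np.ndarray:
        """Per-antenna input powers (12 values, channel value repeated)."""
        per_channel = port_power(self.voltages, self.port_resistance_ohm)
        return np.repeat(per_channel, self.antennas_per_channel)


@dataclass(frozen=True)
class HPMap:
    """Heating potential Q0 (W/m^3) on a grid."""

    grid: GridSpec
    q0: np.ndarray

    def __post_init__(self) -> None:
        if self.q0.shape != self.grid.shape:
            raise ContractError("q0 shape does not match grid")
        if np.any(self.q0 < 0):
            raise ValueError("heating potential must be non-negative")

    @property
    def normalized(self) -> np.ndarray:
        """Min-max scaled map: highest level 1, lowest 0."""
        return normalize_hp(self).q0


def superpose_coefficients(fields: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Superpose raw field maps (N, C, H, W) with complex coefficients (N,)."""
    fields = np.asarray(fields)
    coefficients = np.asarray(coefficients, dtype=complex)
    if coefficients.shape != (fields.shape[0],):
        raise ContractError(
            f"{coefficients.shape[0] if coefficients.ndim else 1} coefficients "
            f"for {fields.shape[0]} fields"
        )
    return np.tensordot(coefficients, fields, axes=(0, 0))


def superpose(fs: FieldSet, exc: Excitation) -> np.ndarray:
    """Total complex vector field sum_i a_i e^{j phi_i} E_i(r)."""
    if exc.scheme != fs.layout.scheme or exc.n_channels != fs.n_channels:
        raise ContractError("excitation and field set schemes do not match")
    return superpose_coefficients(fs.fields, exc.coefficients())


def heating_potential(e_tot: np.ndarray, phantom: PhantomGrid) -> HPMap:
    """Q0(r) = 0.5 sigma(r) sum_c |E_c(r)|^2 from a total field."""
    if e_tot.shape[1:] != phantom.grid.shape:
        raise ContractError("field and phantom grids do not match")
    q0 = 0.5 * phantom.sigma * (np.abs(e_tot) ** 2).sum(axis=0)
    return HPMap(grid=phantom.grid, q0=q0)


def port_power(voltage, resistance_ohm: float = PORT_RESISTANCE_OHM):
    """Port input power P = V^2 / R (0.02 W for 1 V into 50 ohm)."""
    v = np.asarray(voltage, dtype=float)
    if np.any(v < 0):
        raise ValueError("voltage must be non-negative")
    p = v**2 / resistance_ohm
    return p if p.ndim else float(p)


def scale_to_total_power(exc: Excitation, total_w: float = TOTAL_POWER_W) -> Excitation:
    """Rescale voltages so all 12 antennas' input powers sum to ``total_w``.

    Phases are unchanged; for the linear scheme each channel's voltage
    feeds 3 physical antennas and therefore counts three times.
    """
    current = exc.total_antenna_power_w()
    if current <= 0:
        raise DegenerateExcitationError("cannot scale an all-zero excitation")
    factor = np.sqrt(total_w / current)
    return replace(exc, voltages=exc.voltages * factor)


def normalize_hp(hp: HPMap) -> HPMap:
    """Min-max normalize a heating-potential map onto [0, 1]."""
    lo = float(hp.q0.min())
    hi = float(hp.q0.max())
    if hi - lo <= 0:
        raise MetricError("constant heating-potential map cannot be normalized")
    return HPMap(grid=hp.grid, q0=(hp.q0 - lo) / (hi - lo))


def save_excitation(exc: Excitation, path) -> None:
    """Serialize an excitation as YAML (scheme, voltages V, phases deg)."""
    doc = {
        "scheme": exc.scheme,
        "voltages_v": [float(v) for v in exc.voltages],
        "phases_deg": [float(p) for p in exc.phases],
        "port_resistance_ohm": float(exc.port_resistance_ohm),
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_excitation(path) -> Excitation:
    with open(path) as f:
        doc = yaml.safe_load(f)
    return Excitation(
        scheme=doc["scheme"],
        voltages=np.array(doc["voltages_v"], dtype=float),
        phases=np.array(doc["phases_deg"], dtype=float),
        port_resistance_ohm=float(doc.get("port_resistance_ohm", PORT_RESISTANCE_OHM)),
    )
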