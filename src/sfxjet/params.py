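"""Domain types for jet sample delivery at an XFEL.

All quantities are SI unless a field name says otherwise; the polymer bond
geometry is carried in nanometres because every empirical relation it feeds
(contour length, radius-of-gyration scaling laws, shell census) is quoted in
nm in the polymer-physics literature.

Dataclasses validate their physical invariants at construction so that
downstream formulas can assume well-posed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


class ValidationError(ValueError):
    """A physically inadmissible parameter value."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class PulseTrain:
    """XFEL pulse structure.

    European-XFEL-style delivery: ``trains_per_second`` trains (10 Hz at the
    facility), each carrying ``pulses_per_train`` pulses at the MHz
    ``intra_train_rate``.
    """

    trains_per_second: float  # 1/s
    pulses_per_train: int
    intra_train_rate: float  # 1/s

    def __post_init__(self) -> None:
        _require(self.trains_per_second > 0, "trains_per_second must be > 0")
        _require(self.pulses_per_train > 0, "pulses_per_train must be > 0")
        _require(self.intra_train_rate > 0, "intra_train_rate must be > 0")
        _require(
            self.intra_train_rate >= self.trains_per_second,
            "intra_train_rate cannot be below the train repetition rate",
        )

    @property
    def pulses_per_second(self) -> float:
        return self.trains_per_second * self.pulses_per_train


@dataclass(frozen=True)
class BeamSpec:
    """X-ray focus geometry; energies are carried for reporting only."""

    width_x: float  # m
    width_y: float  # m
    photon_energy_kev: Optional[float] = None
    effective_pulse_energy_j: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.width_x > 0 and self.width_y > 0, "beam widths must be > 0")


@dataclass(frozen=True)
class JetSpec:
    """Liquid-jet geometry and flows.

    ``Q_i`` is the sample (core) flow, ``Q_o`` the sheath flow; ``Q_o = 0``
    corresponds to single-liquid GDVN operation.
    """

    d_j: float  # m, jet diameter
    v_j: float  # m/s, jet velocity
    Q_i: float  # m³/s
    Q_o: float = 0.0  # m³/s
    gas_mass_flow: float = 0.0  # kg/s

    def __post_init__(self) -> None:
        _require(self.d_j > 0, "jet diameter must be > 0")
        _require(self.Q_i >= 0 and self.Q_o >= 0, "flows must be non-negative")
        _require(self.Q_i + self.Q_o > 0, "total flow must be > 0")

    @property
    def Q_total(self) -> float:
        return self.Q_i + self.Q_o

    @property
    def cross_section(self) -> float:
        """Jet cross-sectional area π d_j²/4 (m²)."""
        import math

        return math.pi * self.d_j**2 / 4.0

    @property
    def dilution(self) -> float:
        """Total-to-sample flow ratio (Q_i+Q_o)/Q_i."""
        _require(self.Q_i > 0, "dilution undefined for zero sample flow")
        return self.Q_total / self.Q_i


@dataclass(frozen=True)
class CrystalSlurry:
    """Monodisperse crystal suspension."""

    number_density: float  # 1/m³
    crystal_diameter: float  # m

    def __post_init__(self) -> None:
        _require(self.number_density >= 0, "number density must be >= 0")
        _require(self.crystal_diameter > 0, "crystal diameter must be > 0")


@dataclass(frozen=True)
class GasSpec:
    """Ideal-gas and Sutherland-viscosity parameters of the focusing gas."""

    gamma: float  # cp/cv
    R_specific: float  # J/(kg K)
    mu0: float  # Pa s, reference viscosity
    T0_ref: float  # K, reference temperature for mu0
    sutherland_S: float  # K

    def __post_init__(self) -> None:
        _require(self.gamma > 1, "gamma must exceed 1")
        for name in ("R_specific", "mu0", "T0_ref", "sutherland_S"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


#: Helium: gamma = 5/3, R = 2077 J/(kg K), Sutherland mu0 = 1.98e-5 Pa s at 298 K, S = 80 K.
HELIUM = GasSpec(gamma=5.0 / 3.0, R_specific=2077.0, mu0=1.98e-5, T0_ref=298.0, sutherland_S=80.0)


@dataclass(frozen=True)
class NozzleSpec:
    """Gas-dynamic virtual nozzle geometry."""

    D_gas: float  # m, gas orifice diameter
    D_liquid: float  # m, liquid orifice diameter
    H_ig: float  # m, liquid-orifice-to-gas-orifice distance
    discharge_coefficient: float = 0.7

    def __post_init__(self) -> None:
        for name in ("D_gas", "D_liquid", "H_ig"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 < self.discharge_coefficient <= 1, "C_g must be in (0, 1]")


@dataclass(frozen=True)
class LiquidSpec:
    density: float  # kg/m³
    shear_viscosity: float  # Pa s

    def __post_init__(self) -> None:
        _require(self.density > 0, "density must be > 0")
        _require(self.shear_viscosity > 0, "viscosity must be > 0")


WATER = LiquidSpec(density=1000.0, shear_viscosity=1e-3)


@dataclass(frozen=True)
class PolymerSpec:
    """Linear polymer description (defaults model PEO/PEG).

    Bond lengths are in nm (see module docstring).  ``lambda_r_dilute`` is the
    dilute-solution Zimm relaxation time; ``lambda_r_concentrated`` the
    effective relaxation time at the working concentration (26.2 µs for 1 %
    w/v PEO100k).  ``rho0_hofmann`` and ``nu`` parameterize the
    R_g = rho0 · L^nu scaling option.
    """

    molar_mass: float  # g/mol
    monomer_mass: float = 44.05  # g/mol, ethylene oxide
    bond_CC: float = 0.154  # nm
    bond_CO: float = 0.143  # nm
    angle_CCO: float = 109.5  # degrees
    angle_COC: float = 112.0  # degrees
    lambda_r_dilute: float = 7e-9  # s
    lambda_r_concentrated: float = 26.2e-6  # s
    rho0_hofmann: float = 1.2
    nu: float = 0.5

    def __post_init__(self) -> None:
        _require(self.molar_mass >= self.monomer_mass, "molar mass below one monomer")
        for name in ("angle_CCO", "angle_COC"):
            _require(0 < getattr(self, name) < 180, f"{name} must be in (0, 180) degrees")
        for name in ("monomer_mass", "bond_CC", "bond_CO", "lambda_r_dilute",
                     "lambda_r_concentrated", "rho0_hofmann"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")


def peo100k() -> PolymerSpec:
    """100 kg/mol poly(ethylene oxide), the jet-sheathing polymer."""
    return PolymerSpec(molar_mass=100_000.0)


def peg4000() -> PolymerSpec:
    """PEG4000, the common crystal-buffer precipitant."""
    return PolymerSpec(molar_mass=4000.0)


@dataclass(frozen=True)
class CountsRecord:
    """Raw frame/hit/index counts of one SFX run.

    ``indexed`` may legitimately exceed ``hits`` when frames contain several
    crystals, so only ``indexed <= crystals_found`` is enforced (when the
    crystal count is reported at all).
    """

    total_frames: int
    hits: int
    indexed: int
    crystals_found: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("total_frames", "hits", "indexed"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")
        _require(self.hits <= self.total_frames, "hits cannot exceed total frames")
        if self.crystals_found is not None:
            _require(self.crystals_found >= 0, "crystals_found must be non-negative")
            _require(
                self.indexed <= self.crystals_found,
                "indexed crystals cannot exceed crystals found",
            )


# ---------------------------------------------------------------------------
# Configuration files (YAML; nested sections for gas / polymer / nozzle / liquid)
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "gas": GasSpec,
    "polymer": PolymerSpec,
    "nozzle": NozzleSpec,
    "liquid": LiquidSpec,
    "slurry": CrystalSlurry,
}

_PRESETS = {
    "gas": {"helium": HELIUM},
    "liquid": {"water": WATER},
    "polymer": {"peo100k": peo100k(), "peg4000": peg4000()},
}


def load_config(path: str | Path) -> dict:
    """Read a YAML configuration into spec objects.

    Each top-level section maps to a domain type; a section may be the name of
    a shipped preset (``gas: helium``) or a mapping of field overrides, where
    ``preset: <name>`` pulls defaults first.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    for section, value in raw.items():
        if section not in _SECTION_TYPES:
            out[section] = value
            continue
        cls = _SECTION_TYPES[section]
        presets = _PRESETS.get(section, {})
        if isinstance(value, str):
            if value not in presets:
                raise ValidationError(f"unknown {section} preset {value!r}")
            out[section] = presets[value]
        else:
            base = {}
            preset_name = value.pop("preset", None)
            if preset_name is not None:
                base = vars(presets[preset_name]).copy()
            base.update(value)
            out[section] = cls(**base)
    return out
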