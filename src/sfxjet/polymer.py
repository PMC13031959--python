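"""PEO chain geometry, solution conformation, and the jet-shell chain census.

Lengths in this module are in nanometres: the empirical relations it
implements (contour length from bond geometry, the Devanand–Selser and
Hofmann R_g scaling laws, the shell-volume census) are all quoted in nm.

The all-trans backbone model gives a monomer length

    l = b_CC sin(θ_CCO/2) + 2 b_CO sin(θ_COC/2)

and an effective backbone width m = 6 b_CC cos(θ_CCO/2).  Both projections
are quoted to 0.01 nm — the precision the idealised tetrahedral-angle model
warrants — and the quoted values feed every downstream volume estimate, so
that the chain of derived numbers is internally consistent at that
precision (l = 0.36 nm, m = 0.53 nm for PEO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .params import BeamSpec, PolymerSpec, ValidationError
from .units import N_AVOGADRO


class RgMethod(str, Enum):
    DEVANAND_SELSER = "devanand_selser"
    HOFMANN = "hofmann"


@dataclass(frozen=True)
class ChainGeometry:
    """All-trans chain geometry; lengths in nm."""

    l: float  # monomer length
    m: float  # effective backbone width
    n: int  # degree of polymerization
    L: float  # contour length, n * l
    g: float  # C-C bond axial projection
    h: float  # C-O bond axial projection


@dataclass(frozen=True)
class ConformationStats:
    """Coil descriptors; nm throughout.

    Kuhn relations for an ideal chain: R0² = L·b = n_K·b², R_g² = R0²/6,
    hence b = 6 R_g²/L and L0 = √6 R_g.
    """

    Rg: float
    L0: float  # Gaussian end-to-end distance, sqrt(6) Rg
    b: float  # Kuhn length
    n_K: float  # Kuhn segment count
    method: RgMethod


@dataclass(frozen=True)
class ShellCensus:
    """Chain counts in the X-ray-illuminated shell volume (both crossings)."""

    V_peo: float  # nm³, single-chain volume m² L
    V_shell: float  # nm³, 2 t_shell x_spot²
    chains_at_full_packing: float  # V_shell / V_peo
    chains_at_concentration: float
    Nx: float
    Ny: float
    Nz: float
    N_box: float  # chains in one shell crossing, Nx Ny Nz (unrounded product)
    N_total: float  # both crossings, 2 N_box


def chain_geometry(p: PolymerSpec) -> ChainGeometry:
    """Monomer geometry, degree of polymerization and contour length."""
    g = p.bond_CC * math.sin(math.radians(p.angle_CCO) / 2.0)
    h = p.bond_CO * math.sin(math.radians(p.angle_COC) / 2.0)
    l = round(g + 2.0 * h, 2)
    m = round(6.0 * p.bond_CC * math.cos(math.radians(p.angle_CCO) / 2.0), 2)
    n = round(p.molar_mass / p.monomer_mass)
    return ChainGeometry(l=l, m=m, n=n, L=n * l, g=g, h=h)


def radius_of_gyration(
    M: float,
    method: RgMethod | str = RgMethod.DEVANAND_SELSER,
    nu: float = 0.5,
    L: Optional[float] = None,
    rho0: float = 1.2,
) -> ConformationStats:
    """Coil radius of gyration of PEO in water.

    ``devanand_selser``: R_g = 0.0215 M^0.583 nm (light-scattering fit).
    ``hofmann``: R_g = ρ0 L^ν with the contour length L in nm and
    ν ∈ {1/3, 1/2, 0.6} classifying solvent quality; the relation is used
    numerically as quoted (its units are informal) and requires ``L``.
    """
    if M <= 0:
        raise ValidationError("molar mass must be > 0")
    method = RgMethod(method)
    if method is RgMethod.DEVANAND_SELSER:
        Rg = 0.0215 * M**0.583
    else:
        if L is None:
            raise ValidationError("hofmann scaling needs the contour length L (nm)")
        Rg = rho0 * L**nu
    L0 = math.sqrt(6.0) * Rg
    if L is not None and L > 0:
        b = 6.0 * Rg**2 / L
        n_K = L / b
    else:
        b = math.nan
        n_K = math.nan
    return ConformationStats(Rg=Rg, L0=L0, b=b, n_K=n_K, method=method)


def end_to_end_distance(Rg: float, gaussian: bool = True) -> float:
    """Relaxed end-to-end distance from R_g.

    ``gaussian=True`` gives the ideal-chain √6 R_g; ``False`` gives the √3 R_g
    convention also in use for the coil-stretch estimates.  Both are exposed
    because neither is uniquely standard for semi-flexible chains.
    """
    return (math.sqrt(6.0) if gaussian else math.sqrt(3.0)) * Rg


def overlap_concentration(M: float, Rg: float) -> float:
    """Overlap concentration c* = M/(8 N_A (R_g·10⁻⁹)³) · 10⁻³ in g/L."""
    if M <= 0 or Rg <= 0:
        raise ValidationError("M and Rg must be > 0")
    return M / (8.0 * N_AVOGADRO * (Rg * 1e-9) ** 3) * 1e-3


def entanglement_concentration(M: float, Rg: float) -> float:
    """Entanglement concentration c_e = 2 c* in g/L."""
    return 2.0 * overlap_concentration(M, Rg)


def shell_census(
    geom: ChainGeometry,
    t_shell: float,
    beam: BeamSpec,
    concentration: float,
    packing: Optional[tuple[float, float, float]] = None,
) -> ShellCensus:
    """Chains illuminated in the jet shell, by two routes that must agree.

    Census route: V_shell/V_PEO chains at full packing, scaled by the w/v
    concentration.  Box route: anisotropic per-axis packing factors
    (c_x, c_y, c_z) with c_x·c_y·c_z = concentration — chains lie along the
    jet axis (y), so packing is dense along y and dilute across (x, z).  By
    default c_y = 1 and c_x = c_z = √concentration.  ``t_shell`` in nm;
    the beam spot is converted from SI.
    """
    if t_shell <= 0:
        raise ValidationError("t_shell must be > 0")
    if not 0.0 <= concentration <= 1.0:
        raise ValidationError("concentration must be a w/v fraction in [0, 1]")
    x_spot = beam.width_x * 1e9  # nm
    V_peo = geom.m**2 * geom.L
    V_shell = 2.0 * t_shell * x_spot**2
    full = V_shell / V_peo
    at_conc = concentration * full
    if packing is None:
        c_xz = math.sqrt(concentration)
        packing = (c_xz, 1.0, c_xz)
    c_x, c_y, c_z = packing
    if not math.isclose(c_x * c_y * c_z, concentration, rel_tol=1e-9):
        raise ValidationError("per-axis packing factors must multiply to the concentration")
    Nx = x_spot / geom.m * c_x
    Nz = t_shell / geom.m * c_z
    Ny = x_spot / geom.L * c_y
    N_box = Nx * Ny * Nz
    return ShellCensus(
        V_peo=V_peo,
        V_shell=V_shell,
        chains_at_full_packing=full,
        chains_at_concentration=at_conc,
        Nx=Nx,
        Ny=Ny,
        Nz=Nz,
        N_box=N_box,
        N_total=2.0 * N_box,
    )
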