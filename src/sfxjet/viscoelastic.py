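"""Stretch and relaxation of polymer chains in the jet shell.

The gas-imposed interfacial shear and the converging meniscus both act on
the sheathing polymer.  Dimensionless Weissenberg numbers Wi = rate × λ_r
decide the regime: Wi ≫ 1 in extension drives the coil-stretch transition,
and Wi ≳ 1 in shear keeps chains from relaxing along the jet.  The steady
extension follows the FENE dumbbell estimate L_steady = L0 √(2 Wi), bounded
by the contour length; relaxation back toward the coil follows the Zimm
exponential.  Lengths in nm, rates in 1/s, times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ValidationError


@dataclass(frozen=True)
class FlowKinematics:
    shear_rate: float  # 1/s
    strain_rate: float  # 1/s
    Wi_shear: float
    Wi_ext: float
    lambda_r: float  # s

    def __post_init__(self) -> None:
        for name in ("shear_rate", "strain_rate", "Wi_shear", "Wi_ext", "lambda_r"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FeneExtension:
    L_steady: float  # nm
    ratio_to_coil: float  # L_steady / L0
    ratio_to_contour: float  # L_steady / L_contour
    clamped_at_coil: bool  # Wi below the coil-stretch threshold
    saturated: bool  # capped at the contour length


@dataclass(frozen=True)
class ChainExtensionState:
    L0: float  # nm
    L_steady: float  # nm
    L_total: float  # nm, contour length
    t_stretch: float  # s
    relaxation_length: float  # m


def shear_rate_in_shell(tau: float, eta: float) -> float:
    """Shear rate γ̇ = τ/η from the interfacial stress and shell viscosity."""
    if eta <= 0:
        raise ValidationError("viscosity must be > 0")
    if tau < 0:
        raise ValidationError("shear stress must be >= 0")
    return tau / eta


def weissenberg(rate: float, lambda_r: float) -> float:
    """Wi = deformation rate × relaxation time."""
    if rate < 0 or lambda_r < 0:
        raise ValidationError("rate and relaxation time must be >= 0")
    return rate * lambda_r


def extensional_strain_rate(Q: float, r: float, dr_dz: float) -> float:
    """Axial strain rate in a converging meniscus, ε̇ = −2Q/(π r³) · dr/dz.

    Positive for a converging profile (dr/dz < 0).
    """
    if r <= 0:
        raise ValidationError("meniscus radius must be > 0")
    return -2.0 * Q / (math.pi * r**3) * dr_dz


def stretch_time(L_total: float, L0: float, strain_rate: float) -> float:
    """Time t = ln(L_total/L0)/ε̇ for affine unravelling from L0 to L_total."""
    if not L_total >= L0 > 0:
        raise ValidationError("need L_total >= L0 > 0")
    if strain_rate <= 0:
        raise ValidationError("strain rate must be > 0")
    return math.log(L_total / L0) / strain_rate


def fene_steady_extension(L0: float, Wi: float, L_contour: float) -> FeneExtension:
    """FENE-dumbbell steady extension L_steady = L0 √(2 Wi), clamped to
    [L0, L_contour].

    Below Wi = 0.5 the formula would shrink the chain below its coil size:
    the result is clamped at L0 and flagged.  Finite extensibility caps the
    result at the contour length, also flagged.
    """
    if L0 <= 0 or L_contour <= 0 or Wi < 0:
        raise ValidationError("L0, L_contour must be > 0 and Wi >= 0")
    raw = L0 * math.sqrt(2.0 * Wi)
    clamped = raw < L0
    saturated = raw > L_contour
    L_steady = min(max(raw, L0), L_contour)
    return FeneExtension(
        L_steady=L_steady,
        ratio_to_coil=L_steady / L0,
        ratio_to_contour=L_steady / L_contour,
        clamped_at_coil=clamped,
        saturated=saturated,
    )


def elastic_energy_ratio(R: float, L_contour: float) -> float:
    """FENE elastic-energy proportionality R²/(L_contour² − R²)."""
    if not 0 <= R < L_contour:
        raise ValidationError("need 0 <= R < L_contour (energy diverges at full extension)")
    return R**2 / (L_contour**2 - R**2)


def zimm_relaxation_profile(L_steady: float, L_total: float, lambda_r: float, t) -> float:
    """Zimm relaxation L(t) = L_steady + (L_total − L_steady) e^{−t/λ_r}.

    Decays from the fully stretched length toward the steady flow-held
    extension; accepts scalar or array ``t`` (seconds, >= 0).
    """
    import numpy as np

    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValidationError("time must be >= 0")
    if lambda_r <= 0:
        raise ValidationError("relaxation time must be > 0")
    out = L_steady + (L_total - L_steady) * np.exp(-t_arr / lambda_r)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def relaxation_length(v_jet: float, t: float) -> float:
    """Distance v × t the jet travels while the chains relax (m)."""
    if v_jet < 0 or t < 0:
        raise ValidationError("velocity and time must be >= 0")
    return v_jet * t
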