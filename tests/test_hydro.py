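import math

import pytest

from sfxjet import (
    HELIUM,
    ValidationError,
    bernoulli_liquid_velocity,
    blasius_layer,
    choked_nozzle_state,
    compound_geometry,
    diameter_from_continuity,
    gas_dynamics_chain,
    interface_shear,
    mean_axial_velocity,
    sutherland_viscosity,
    velocity_from_displacement,
)
from sfxjet.hydro import choked_mass_flow
from sfxjet import units


@pytest.mark.parametrize(
    "disp_um, rate_mhz, v",
    [(79.3, 0.564, 44.7), (41.6, 1.128, 46.9), (0.0, 1.128, 0.0)],
)
def test_explosion_velocimetry(disp_um, rate_mhz, v):
    assert velocity_from_displacement(disp_um * units.UM, rate_mhz * units.MHZ) == pytest.approx(v, abs=0.05)


@pytest.mark.parametrize("q_ul_min, v, d_um", [(30, 44.7, 3.77), (30, 46.9, 3.68)])
def test_continuity_diameter(q_ul_min, v, d_um):
    d = diameter_from_continuity(q_ul_min * units.UL_PER_MIN, v)
    assert d / units.UM == pytest.approx(d_um, abs=0.005)


def test_continuity_scaling_and_round_trip():
    d = diameter_from_continuity(30 * units.UL_PER_MIN, 44.7)
    assert diameter_from_continuity(120 * units.UL_PER_MIN, 44.7) == pytest.approx(2 * d)
    v = mean_axial_velocity(30 * units.UL_PER_MIN, d)
    assert v == pytest.approx(44.7, rel=1e-12)


def test_compound_jet_shell_thickness():
    d_i, t = compound_geometry(3.9 * units.UM, 20 * units.UL_PER_MIN, 10 * units.UL_PER_MIN)
    assert d_i / units.UM == pytest.approx(3.184, abs=0.002)
    assert t / units.NM == pytest.approx(357.8, abs=0.5)


def test_compound_jet_single_liquid_limit():
    d_i, t = compound_geometry(3.9e-6, 5e-10, 0.0)
    assert d_i == pytest.approx(3.9e-6)
    assert t == 0.0


def test_compound_jet_sheath_dominated():
    d_i, t = compound_geometry(4e-6, 10 * units.UL_PER_MIN, 20 * units.UL_PER_MIN)
    assert d_i == pytest.approx(4e-6 / math.sqrt(3), rel=1e-12)
    assert t == pytest.approx((4e-6 - 4e-6 / math.sqrt(3)) / 2, rel=1e-12)


def test_choked_state_helium_operating_point():
    """30 mg/min through a 60 um orifice at C_g = 0.7, 280 K."""
    s = choked_nozzle_state(30 * units.MG_PER_MIN, 60 * units.UM, 0.7, 280.0, HELIUM)
    assert s.P0 == pytest.approx(2.65e5, rel=0.005)
    assert s.a_star == pytest.approx(853, rel=0.005)
    assert s.T_star == pytest.approx(210.0, rel=1e-9)
    assert s.P_star == pytest.approx(1.294e5, rel=0.005)
    assert s.rho_star == pytest.approx(0.297, rel=0.005)
    assert s.P_star < s.P0 and s.T_star < 280.0
    assert s.rho_star == pytest.approx(s.P_star / (HELIUM.R_specific * s.T_star))


def test_choked_flow_is_linear_in_mass_flow():
    s1 = choked_nozzle_state(5e-7, 60e-6, 0.7, 280.0, HELIUM)
    s2 = choked_nozzle_state(1e-6, 60e-6, 0.7, 280.0, HELIUM)
    assert s2.P0 == pytest.approx(2 * s1.P0, rel=1e-12)


def test_choked_state_round_trip_recovers_mass_flow():
    mdot = 30 * units.MG_PER_MIN
    s = choked_nozzle_state(mdot, 60e-6, 0.7, 280.0, HELIUM)
    assert choked_mass_flow(s.P0, 60e-6, 0.7, 280.0, HELIUM) == pytest.approx(mdot, rel=1e-9)


def test_sutherland_viscosity_reference_point_and_choked_value():
    assert sutherland_viscosity(HELIUM.T0_ref, HELIUM) == pytest.approx(HELIUM.mu0, rel=1e-12)
    assert sutherland_viscosity(209.9, HELIUM) == pytest.approx(1.527e-5, rel=0.002)


def test_sutherland_viscosity_monotone_in_temperature():
    mus = [sutherland_viscosity(T, HELIUM) for T in (50, 150, 250, 400, 800)]
    assert all(b > a for a, b in zip(mus, mus[1:]))


def test_blasius_layer_on_choked_helium():
    layer = blasius_layer(0.297, 853.0, 60e-6, 1.527e-5)
    assert layer.Re_x == pytest.approx(994.6, rel=0.01)
    assert layer.delta == pytest.approx(9.36e-6, rel=0.01)


def test_blasius_scalings():
    base = blasius_layer(0.297, 853.0, 60e-6, 1.527e-5)
    x4 = blasius_layer(0.297, 853.0, 240e-6, 1.527e-5)
    assert x4.delta == pytest.approx(2 * base.delta, rel=1e-9)
    mu2 = blasius_layer(0.297, 853.0, 60e-6, 2 * 1.527e-5)
    assert mu2.Re_x == pytest.approx(base.Re_x / 2, rel=1e-12)
    assert mu2.delta == pytest.approx(base.delta * math.sqrt(2), rel=1e-9)


def test_turbulent_reynolds_warns():
    with pytest.warns(UserWarning):
        blasius_layer(1.2, 300.0, 0.5, 1.8e-5)


def test_interface_shear_stress():
    tau = interface_shear(1.527e-5, 800.0, 9.36e-6)
    assert tau == pytest.approx(1.3e3, rel=0.01)
    assert interface_shear(1.527e-5, 0.0, 9.36e-6) == 0.0
    assert interface_shear(1.527e-5, 1600.0, 9.36e-6) == pytest.approx(2 * tau)


def test_bernoulli_discharge_velocity():
    assert bernoulli_liquid_velocity(2.65e5, 1000.0) == pytest.approx(23.0, abs=0.05)
    assert bernoulli_liquid_velocity(0.0, 1000.0) == 0.0
    assert bernoulli_liquid_velocity(4 * 2.65e5, 1000.0) == pytest.approx(2 * 23.02, abs=0.1)


def test_mean_axial_velocity_from_flow_and_diameter():
    assert mean_axial_velocity(30 * units.UL_PER_MIN, 3.77e-6) == pytest.approx(44.8, abs=0.1)


def test_full_gas_chain_reproduces_printed_sequence():
    """P0 -> (P*, T*, rho*) -> mu(T*) -> Re_x -> delta -> tau, each within
    1 % of the published helium chain."""
    chain = gas_dynamics_chain(30 * units.MG_PER_MIN, 60 * units.UM, 0.7, 280.0, HELIUM)
    assert chain.choked.P0 == pytest.approx(2.65e5, rel=0.01)
    assert chain.choked.rho_star == pytest.approx(0.297, rel=0.01)
    assert chain.mu_star == pytest.approx(1.527e-5, rel=0.01)
    assert chain.layer.Re_x == pytest.approx(994.6, rel=0.01)
    assert chain.layer.delta == pytest.approx(9.36e-6, rel=0.01)
    assert chain.tau == pytest.approx(1.3e3, rel=0.01)
    assert chain.v_liquid_bernoulli == pytest.approx(23.0, rel=0.01)


def test_invalid_inputs_rejected():
    with pytest.raises(ValidationError):
        velocity_from_displacement(-1e-6, 1e6)
    with pytest.raises(ValidationError):
        diameter_from_continuity(0.0, 44.7)
    with pytest.raises(ValidationError):
        compound_geometry(3.9e-6, 0.0, 0.0)
    with pytest.raises(ValidationError):
        sutherland_viscosity(-10.0, HELIUM)
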