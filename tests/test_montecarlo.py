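import numpy as np
import pytest

from sfxjet import (
    BeamSpec,
    CrystalSlurry,
    JetSpec,
    PulseTrain,
    ValidationError,
    hard_rod_hit_rate,
    poisson_hit_rate,
)
from sfxjet.montecarlo import (
    Placement,
    PlacementModel,
    check_pulse_independence,
    mc_hit_rate,
    sample_positions,
)
from sfxjet.hitrate import linear_density
from sfxjet import units


def slurry(density_per_ml, d_c_um):
    return CrystalSlurry(number_density=density_per_ml * units.PER_ML, crystal_diameter=d_c_um * units.UM)


def test_identical_seeds_reproduce_bit_for_bit(reference_jet, nano_beam, reference_slurry):
    m = PlacementModel(kind="poisson_points", seed=42)
    a = mc_hit_rate(m, reference_jet, nano_beam, reference_slurry, 20_000)
    b = mc_hit_rate(m, reference_jet, nano_beam, reference_slurry, 20_000)
    assert a == b


def test_zero_density_never_hits(reference_jet, nano_beam):
    est = mc_hit_rate(
        PlacementModel(kind="poisson_points", seed=0), reference_jet, nano_beam, slurry(0.0, 3), 10_000
    )
    assert est.n_hits == 0 and est.p_hat == 0.0


def test_poisson_mean_count_matches_linear_density(reference_jet):
    """6e8/mL in a 1 mm segment of a 3.8 um jet: ~6.8 crystals per draw."""
    sl = slurry(6e8, 3)
    sample = sample_positions(
        PlacementModel(kind="poisson_points", seed=3), reference_jet, sl, n_segments=10_000, segment_length=1e-3
    )
    expected = linear_density(reference_jet, sl) * 1e-3  # = 6.80 per mm
    mean = sample.axial.size / 10_000
    assert mean == pytest.approx(expected, abs=3 * np.sqrt(expected / 10_000))


def test_tonks_sampler_respects_hard_core(reference_jet):
    """Axial gaps between rod centres never drop below the rod length."""
    sl = slurry(6e8, 4)
    sample = sample_positions(
        PlacementModel(kind="tonks_equilibrium", seed=11), reference_jet, sl, n_segments=10_000, segment_length=2e-3
    )
    order = np.lexsort((sample.axial, sample.segment))
    seg, x = sample.segment[order], sample.axial[order]
    same = seg[1:] == seg[:-1]
    assert (np.diff(x)[same] >= sl.crystal_diameter - 1e-12).all()


def test_rsa_sampler_respects_hard_core_and_confinement(reference_jet):
    sl = slurry(6e8, 3)
    sample = sample_positions(
        PlacementModel(kind="hard_sphere_rsa", seed=5), reference_jet, sl, n_segments=3_000, segment_length=1e-3
    )
    r = np.hypot(sample.y, sample.z)
    assert (r <= (reference_jet.d_j - sl.crystal_diameter) / 2 + 1e-15).all()
    order = np.lexsort((sample.axial, sample.segment))
    seg, x = sample.segment[order], sample.axial[order]
    y, z = sample.y[order], sample.z[order]
    # check every same-segment pair within one diameter axially
    for k in range(1, 8):
        cand = (seg[k:] == seg[:-k]) & (x[k:] - x[:-k] < sl.crystal_diameter)
        if not cand.any():
            break
        d2 = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2 + (z[k:] - z[:-k]) ** 2
        assert (d2[cand] >= sl.crystal_diameter**2 - 1e-24).all()


def test_mc_agrees_with_poisson_closed_form(reference_jet, micro_beam, reference_slurry):
    est = mc_hit_rate(
        PlacementModel(kind="poisson_points", seed=1), reference_jet, micro_beam, reference_slurry, 200_000
    )
    p = poisson_hit_rate(reference_jet, micro_beam, reference_slurry).probability
    assert abs(est.p_hat - p) < 3 * est.std_err


def test_tonks_coverage_identity_at_half_packing(reference_jet):
    """theta = 0.5 with a point beam: hit probability is the coverage 0.5."""
    d_c = 2e-6
    density = 0.5 / d_c / reference_jet.cross_section  # n_l * d_c = 0.5
    sl = CrystalSlurry(number_density=density, crystal_diameter=d_c)
    beam = BeamSpec(width_x=1e-15, width_y=1e-15)
    est = mc_hit_rate(
        PlacementModel(kind="tonks_equilibrium", seed=2, segment_length=5e-4),
        reference_jet,
        beam,
        sl,
        100_000,
    )
    assert abs(est.p_hat - 0.5) < 3 * est.std_err


def test_dilute_convergence_to_poisson(reference_jet, nano_beam):
    """Tonks and RSA estimates approach the Poisson closed form as density
    falls over two decades."""
    for kind, analytic in (("tonks_equilibrium", hard_rod_hit_rate), ("hard_sphere_rsa", None)):
        for dens in (6e8, 6e7, 6e6):
            sl = slurry(dens, 3)
            est = mc_hit_rate(PlacementModel(kind=kind, seed=9), reference_jet, nano_beam, sl, 150_000)
            p_poisson = poisson_hit_rate(reference_jet, nano_beam, sl).probability
            # allow the genuine excluded-volume offset (itself -> 0 with density)
            offset = abs(analytic(reference_jet, nano_beam, sl).probability - p_poisson) if analytic else p_poisson * 0.03
            assert abs(est.p_hat - p_poisson) < 4 * est.std_err + offset, (kind, dens)


def test_estimate_metadata_and_standard_error(reference_jet, nano_beam, reference_slurry):
    est = mc_hit_rate(
        PlacementModel(kind="tonks_equilibrium", seed=4), reference_jet, nano_beam, reference_slurry, 10_000
    )
    assert est.model is Placement.TONKS_EQUILIBRIUM
    assert est.p_hat == est.n_hits / est.n_pulses
    assert est.std_err == pytest.approx(np.sqrt(est.p_hat * (1 - est.p_hat) / est.n_pulses))


def test_infeasible_rod_packing_rejected(reference_jet, nano_beam):
    with pytest.raises(ValidationError):
        mc_hit_rate(
            PlacementModel(kind="tonks_equilibrium", seed=0), reference_jet, nano_beam, slurry(4e10, 4), 10_000
        )


def test_segment_length_floor_enforced(reference_jet, nano_beam, reference_slurry):
    with pytest.raises(ValidationError):
        mc_hit_rate(
            PlacementModel(kind="poisson_points", seed=0, segment_length=1e-7),
            reference_jet,
            nano_beam,
            reference_slurry,
            10_000,
        )


def test_pulse_independence_check(reference_jet, nano_beam, reference_slurry, mhz_train):
    spacing, ok = check_pulse_independence(reference_jet, mhz_train, nano_beam, reference_slurry)
    assert spacing == pytest.approx(45.0 / 1.128e6)  # ~40 um between pulses
    assert ok
    crawling = JetSpec(d_j=3.8e-6, v_j=0.5, Q_i=reference_jet.Q_i)
    with pytest.warns(UserWarning):
        _, ok = check_pulse_independence(crawling, mhz_train, nano_beam, reference_slurry)
    assert not ok
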