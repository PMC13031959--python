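import math

import pytest

from sfxjet import (
    BeamSpec,
    CrystalSlurry,
    JetSpec,
    ValidationError,
    hit_rate,
    hit_rate_curve,
    interaction_volume,
    poisson_hit_rate,
    hard_rod_hit_rate,
    hard_sphere_hit_rate,
)
from sfxjet.hitrate import (
    effective_exclusion_length,
    linear_density,
    packing_fraction_1d,
    packing_fraction_3d,
)
from sfxjet import units


def slurry(density_per_ml, d_c_um):
    return CrystalSlurry(number_density=density_per_ml * units.PER_ML, crystal_diameter=d_c_um * units.UM)


def test_interaction_volume_geometry(reference_jet, micro_beam):
    v = interaction_volume(reference_jet, micro_beam, 3 * units.UM)
    assert v == pytest.approx(7.372e-17, rel=1e-3)


def test_interaction_volume_scaling(reference_jet, micro_beam):
    wide = JetSpec(d_j=2 * reference_jet.d_j, v_j=45.0, Q_i=reference_jet.Q_i)
    assert interaction_volume(wide, micro_beam, 3e-6) == pytest.approx(
        4 * interaction_volume(reference_jet, micro_beam, 3e-6)
    )


def test_zero_density_hits_nothing(reference_jet, micro_beam):
    for model in ("poisson", "hard_sphere", "hard_rod"):
        r = hit_rate(model, reference_jet, micro_beam, slurry(0.0, 3))
        assert r.probability == 0.0


def test_poisson_micro_beam_study_conditions(reference_jet, micro_beam):
    # 3.8 um jet, 6e8 crystals/mL, 3 um crystals, 3.5 um beam
    r = poisson_hit_rate(reference_jet, micro_beam, slurry(6e8, 3))
    assert r.expected_crystals_in_volume == pytest.approx(0.04423, rel=1e-3)
    assert r.probability == pytest.approx(0.04327, rel=1e-3)
    assert r.probability == pytest.approx(-math.expm1(-r.expected_crystals_in_volume))


def test_poisson_nano_beam_study_conditions(reference_jet, nano_beam):
    r = poisson_hit_rate(reference_jet, nano_beam, slurry(6e8, 2))
    assert r.probability == pytest.approx(0.01754, rel=1e-3)


def test_hard_rod_zero_width_beam_gives_coverage_theta(reference_jet):
    """With a vanishing beam the hit probability is the linear coverage θ."""
    sl = slurry(6e8, 3)
    theta = packing_fraction_1d(reference_jet, sl)
    thin = BeamSpec(width_x=1e-15, width_y=1e-15)
    assert hard_rod_hit_rate(reference_jet, thin, sl).probability == pytest.approx(theta, rel=1e-6)


def test_hard_rod_infeasible_packing_rejected(reference_jet, nano_beam):
    with pytest.raises(ValidationError):
        hard_rod_hit_rate(reference_jet, nano_beam, slurry(4e10, 4))


def test_dilute_equivalence_of_all_models(reference_jet, nano_beam):
    """At θ, φ <= 0.01 all three closures agree within 1 % relative."""
    sl = slurry(2e8, 2)  # theta ~ 0.0045, phi ~ 0.0008
    assert packing_fraction_1d(reference_jet, sl) <= 0.01
    assert packing_fraction_3d(sl) <= 0.01
    ps = [hit_rate(m, reference_jet, nano_beam, sl).probability for m in ("poisson", "hard_sphere", "hard_rod")]
    assert max(ps) / min(ps) < 1.01


def test_hard_sphere_close_to_poisson_at_low_packing(reference_jet, nano_beam):
    """phi ~ 0.0085 for 3 um crystals at 6e8/mL: < 1 % relative deviation."""
    sl = slurry(6e8, 3)
    assert packing_fraction_3d(sl) == pytest.approx(0.0085, rel=0.05)
    p_hs = hard_sphere_hit_rate(reference_jet, nano_beam, sl).probability
    p_p = poisson_hit_rate(reference_jet, nano_beam, sl).probability
    assert abs(p_hs - p_p) / p_p < 0.012


def test_effective_exclusion_length_limits(reference_jet):
    # total confinement (crystal >= jet): full rod length
    assert effective_exclusion_length(4e-6, 3.8e-6) == pytest.approx(4e-6)
    # mild confinement: shorter than the sphere diameter but positive
    ell = effective_exclusion_length(2e-6, 3.8e-6)
    assert 0 < ell < 2e-6
    # very wide jet: barely any axial exclusion remains
    assert effective_exclusion_length(2e-6, 100e-6) < 0.1e-6


@pytest.mark.parametrize("model", ["poisson", "hard_sphere", "hard_rod"])
def test_probability_monotone_in_density_size_and_beam(model, reference_jet):
    """P is non-decreasing in crystal density, diameter and beam width."""
    last = -1.0
    for dens in (1e8, 3e8, 6e8):
        p = hit_rate(model, reference_jet, BeamSpec(0.6e-6, 0.6e-6), slurry(dens, 3)).probability
        assert p >= last
        last = p
    last = -1.0
    for d_c in (1.0, 2.0, 3.0):
        p = hit_rate(model, reference_jet, BeamSpec(0.6e-6, 0.6e-6), slurry(6e8, d_c)).probability
        assert p >= last
        last = p
    last = -1.0
    for w in (0.3e-6, 0.6e-6, 3.5e-6):
        p = hit_rate(model, reference_jet, BeamSpec(w, w), slurry(6e8, 3)).probability
        assert p >= last
        last = p


def test_curve_flags_crystals_larger_than_jet(reference_jet, nano_beam):
    df = hit_rate_curve(reference_jet, nano_beam, 6e8 * units.PER_ML, [2e-6, 4e-6])
    flagged = df[df.crystal_diameter >= reference_jet.d_j]
    assert flagged["flags"].str.contains("crystal_larger_than_jet").all()
    assert not df[df.crystal_diameter < reference_jet.d_j]["flags"].str.contains("crystal").any()


def test_curve_zero_density_is_identically_zero(reference_jet, nano_beam):
    df = hit_rate_curve(reference_jet, nano_beam, 0.0, [2e-6, 3e-6, 4e-6])
    assert (df.probability == 0).all()


def test_empty_grid_rejected(reference_jet, nano_beam):
    with pytest.raises(ValidationError):
        hit_rate_curve(reference_jet, nano_beam, 6e8 * units.PER_ML, [])
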