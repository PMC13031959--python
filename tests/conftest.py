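import pytest

from sfxjet import BeamSpec, CrystalSlurry, JetSpec, PulseTrain
from sfxjet import units


@pytest.fixture
def reference_jet() -> JetSpec:
    """The 3.8 µm, 45 m/s jet used for the hit-rate study conditions."""
    return JetSpec(d_j=3.8 * units.UM, v_j=45.0, Q_i=30 * units.UL_PER_MIN)


@pytest.fixture
def reference_slurry() -> CrystalSlurry:
    """6e8 crystals/mL of 3 µm crystals."""
    return CrystalSlurry(number_density=6e8 * units.PER_ML, crystal_diameter=3 * units.UM)


@pytest.fixture
def micro_beam() -> BeamSpec:
    return BeamSpec(width_x=3.5 * units.UM, width_y=3.5 * units.UM)


@pytest.fixture
def nano_beam() -> BeamSpec:
    return BeamSpec(width_x=0.6 * units.UM, width_y=0.6 * units.UM)


@pytest.fixture
def mhz_train() -> PulseTrain:
    """1.13 MHz intra-train operation: 352 pulses/train, 10 trains/s."""
    return PulseTrain(trains_per_second=10, pulses_per_train=352, intra_train_rate=1.128e6)
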