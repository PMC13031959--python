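"""Unit conversion constants.

The package computes in SI internally; every non-SI quantity is converted at
the I/O boundary with the constants below.  Each constant converts *from* the
named unit *to* SI (multiply), so ``30 * UL_PER_MIN`` is 30 µL/min in m³/s.
"""

from __future__ import annotations

#: µL/min -> m³/s
UL_PER_MIN = 1e-9 / 60.0
#: mg/min -> kg/s
MG_PER_MIN = 1e-6 / 60.0
#: MHz -> 1/s
MHZ = 1e6
#: µm -> m
UM = 1e-6
#: nm -> m
NM = 1e-9
#: mm -> m
MM = 1e-3
#: crystals per mL -> crystals per m³
PER_ML = 1e6
#: minutes -> seconds
MINUTE = 60.0

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23


def to_si(value: float, factor: float) -> float:
    """Convert ``value`` in the unit whose factor is given to SI."""
    return value * factor


def from_si(value: float, factor: float) -> float:
    """Convert an SI ``value`` back to the unit whose factor is given."""
    return value / factor
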