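"""Hit-rate accounting and data-collection-time budgeting.

The central planning quantity of an SFX beamtime is the time needed to
accumulate a target number of indexed diffraction patterns,

    t = N_target / (pulses_per_second · hit_rate · indexable_fraction),

evaluated with exact rational arithmetic on the count ratios so that printed
times are reproduced from raw counts rather than pre-rounded percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

from .params import CountsRecord, PulseTrain, ValidationError

Number = Union[int, float, Fraction]


@dataclass(frozen=True)
class AcquisitionRates:
    """Hit and indexing rates of one run, as fractions in [0, 1].

    ``indexable_fraction`` is ``None`` when no hits were recorded (0/0 is
    undefined, not zero).  Exact ratios are kept as :class:`Fraction` where
    the inputs were integer counts.
    """

    hit_rate: Fraction
    indexable_fraction: Optional[Fraction]
    total_indexing_rate: Fraction

    def __post_init__(self) -> None:
        for name in ("hit_rate", "total_indexing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {float(v)}")
        if self.indexable_fraction is not None and not 0 <= self.indexable_fraction <= 1:
            raise ValidationError("indexable_fraction must lie in [0, 1]")


def rates_from_counts(counts: CountsRecord) -> AcquisitionRates:
    """Hit rate, indexable fraction and total indexing rate from raw counts."""
    if counts.total_frames <= 0:
        raise ValidationError("total_frames must be positive")
    hit_rate = Fraction(counts.hits, counts.total_frames)
    if counts.hits == 0:
        indexable: Optional[Fraction] = None
        total = Fraction(0)
    else:
        indexable = Fraction(counts.indexed, counts.hits)
        total = Fraction(counts.indexed, counts.total_frames)
    return AcquisitionRates(hit_rate=hit_rate, indexable_fraction=indexable, total_indexing_rate=total)


def collection_time(
    pulses_per_second: Number,
    hit_rate: Number,
    indexable_fraction: Number,
    n_indexed_target: int,
) -> float:
    """Seconds to accumulate ``n_indexed_target`` indexed patterns.

    Returns ``math.inf`` when the hit rate or indexable fraction is zero (no
    amount of beamtime reaches the target).  Rational inputs are combined
    exactly before the single conversion to float.
    """
    if pulses_per_second <= 0 or n_indexed_target <= 0:
        raise ValidationError("pulses_per_second and n_indexed_target must be > 0")
    if not (0 <= hit_rate <= 1 and 0 <= indexable_fraction <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    if hit_rate == 0 or indexable_fraction == 0:
        return math.inf
    exact = all(isinstance(x, (int, Fraction)) for x in (pulses_per_second, hit_rate, indexable_fraction))
    if exact:
        t = Fraction(n_indexed_target) / (
            Fraction(pulses_per_second) * Fraction(hit_rate) * Fraction(indexable_fraction)
        )
        return float(t)
    return n_indexed_target / (float(pulses_per_second) * float(hit_rate) * float(indexable_fraction))


def collection_time_from_counts(
    pulses: PulseTrain | Number, counts: CountsRecord, n_indexed_target: int = 10_000
) -> float:
    """Collection time computed from raw counts (exact ratios throughout)."""
    pps = pulses.pulses_per_second if isinstance(pulses, PulseTrain) else pulses
    r = rates_from_counts(counts)
    if r.indexable_fraction is None:
        return math.inf
    # rational path: pass pps as Fraction when it is integral
    if float(pps) == int(pps):
        pps = int(pps)
    return collection_time(pps, r.hit_rate, r.indexable_fraction, n_indexed_target)


def minutes(seconds: float) -> float:
    return seconds / 60.0


def rounded_minutes(seconds: float) -> int:
    """Whole minutes, round-half-up (16.50 min -> 17; 9.47 min -> 9)."""
    if math.isinf(seconds):
        raise ValidationError("cannot round an infinite collection time")
    return int(math.floor(seconds / 60.0 + 0.5))
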