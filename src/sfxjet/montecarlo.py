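"""Monte-Carlo oracle for the analytic hit-rate models.

Each simulated pulse draws an independent segment of jet, populates it with
crystals under one of three placement statistics, and tests whether any
crystal's axial extent intersects the beam window centred in the segment.
Pulses are independent because consecutive pulses sample jet segments much
farther apart than the interaction window (checked by
:func:`check_pulse_independence`), so the hit count is binomial.

Placement statistics:

* ``poisson_points`` — crystal count Poisson in the segment volume, centres
  uniform in the cylinder;
* ``tonks_equilibrium`` — exact equilibrium hard rods: the canonical
  configuration with N rods in a segment of length Λ is N sorted uniforms on
  the free length Λ − N d_c plus cumulative rod offsets;
* ``hard_sphere_rsa`` — sequential insertion of hard spheres with rejection
  and re-draw, centres confined to radius (d_j − d_c)/2.  When the crystal
  is at least as large as the jet the confinement radius collapses to the
  axis and the model degrades to 1D rods (flagged).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .params import BeamSpec, CrystalSlurry, JetSpec, PulseTrain, ValidationError
from .hitrate import linear_density, packing_fraction_1d, packing_fraction_3d


class Placement(str, Enum):
    POISSON_POINTS = "poisson_points"
    TONKS_EQUILIBRIUM = "tonks_equilibrium"
    HARD_SPHERE_RSA = "hard_sphere_rsa"


#: default segment length as a multiple of the interaction window w + d_c,
#: per placement model; all well above the minimum of 100 windows.  The
#: Tonks sampler draws its rod count per segment from a Poisson law whose
#: overdispersion relative to the true grand-canonical count decays like
#: 1/segment_length, so it runs on much longer segments to keep that
#: finite-segment bias far below Monte-Carlo resolution at 10^7 pulses.
DEFAULT_WINDOW_FACTOR = {
    "poisson_points": 150.0,
    "tonks_equilibrium": 1500.0,
    "hard_sphere_rsa": 150.0,
}

_MAX_RSA_ROUNDS = 500


@dataclass(frozen=True)
class PlacementModel:
    """Which statistics to sample, with the seed that fully determines output."""

    kind: Placement
    seed: int
    segment_length: Optional[float] = None  # m; None -> auto from beam window

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Placement(self.kind))


@dataclass(frozen=True)
class MCEstimate:
    n_pulses: int
    n_hits: int
    p_hat: float
    std_err: float
    model: Placement = Placement.POISSON_POINTS
    seed: int = 0
    segment_length: float = 0.0
    flags: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class PlacementSample:
    """Crystal centre coordinates; axial along the jet, (y, z) transverse."""

    segment: np.ndarray  # int, which segment each crystal belongs to
    axial: np.ndarray  # m
    y: np.ndarray  # m
    z: np.ndarray  # m
    n_segments: int
    segment_length: float


def segment_length_for(model: PlacementModel, beam: BeamSpec, slurry: CrystalSlurry) -> float:
    window = beam.width_x + slurry.crystal_diameter
    if model.segment_length is not None:
        if model.segment_length < 100.0 * window:
            raise ValidationError("segment_length must be at least 100x the interaction window")
        return model.segment_length
    return DEFAULT_WINDOW_FACTOR[model.kind.value] * window


def _poisson_axial(rng, n_segments, lam_seg, L):
    counts = rng.poisson(lam_seg, n_segments)
    total = int(counts.sum())
    seg = np.repeat(np.arange(n_segments), counts)
    x = rng.uniform(0.0, L, total)
    return counts, seg, x


def _tonks_axial(rng, n_segments, n_l, d_c, L):
    """Exact canonical Tonks configurations, vectorised over segments.

    Sorted uniforms on the free length are generated via normalised
    exponential spacings (order statistics without a sort).
    """
    counts = rng.poisson(n_l * L, n_segments)
    # infeasible draws (rods exceed the segment) are redrawn; astronomically
    # rare for admissible densities theta < 1 with our segment lengths
    bad = counts * d_c >= L
    while bad.any():
        counts[bad] = rng.poisson(n_l * L, int(bad.sum()))
        bad = counts * d_c >= L
    total = int(counts.sum())
    if total == 0:
        return counts, np.empty(0, dtype=np.int64), np.empty(0)
    e = rng.standard_exponential(total + n_segments)  # N_i + 1 gaps per segment
    cs = np.cumsum(e)
    starts_e = np.concatenate(([0], np.cumsum(counts + 1)[:-1]))
    ends_e = starts_e + counts  # index of the (N_i+1)-th gap of segment i
    prev = np.where(starts_e > 0, cs[np.maximum(starts_e - 1, 0)], 0.0)
    gap_sum = cs[ends_e] - prev
    offsets_c = np.concatenate(([0], np.cumsum(counts)[:-1]))
    seg = np.repeat(np.arange(n_segments), counts)
    within = np.arange(total) - np.repeat(offsets_c, counts)
    e_idx = np.repeat(starts_e, counts) + within
    partial = cs[e_idx] - np.repeat(prev, counts)
    free = np.repeat(L - counts * d_c, counts)
    y = free * partial / np.repeat(gap_sum, counts)  # sorted uniforms on [0, free]
    centers = y + within * d_c + d_c / 2.0  # left edge + half rod
    return counts, seg, centers


def _draw_cylinder(rng, n, L, r_confine):
    x = rng.uniform(0.0, L, n)
    rr = r_confine * np.sqrt(rng.uniform(0.0, 1.0, n))
    ang = rng.uniform(0.0, 2.0 * math.pi, n)
    return x, rr * np.cos(ang), rr * np.sin(ang)


def _conflict_pairs(seg, x, y, z, d_c):
    """All same-segment sphere pairs closer than d_c, as (index_a, index_b).

    Any such pair is within d_c axially, so it suffices to compare each
    sphere (sorted by axial position within its segment) with its next few
    successors, extending the lookahead until no candidate remains.
    """
    order = np.lexsort((x, seg))
    xs, ss = x[order], seg[order]
    pa: list[np.ndarray] = []
    pb: list[np.ndarray] = []
    k = 1
    while k < xs.size:
        cand = (ss[k:] == ss[:-k]) & (xs[k:] - xs[:-k] < d_c)
        if not cand.any():
            break
        i = order[:-k][cand]
        j = order[k:][cand]
        d2 = (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 + (z[i] - z[j]) ** 2
        hit = d2 < d_c * d_c
        if hit.any():
            pa.append(i[hit])
            pb.append(j[hit])
        k += 1
    if not pa:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(pa), np.concatenate(pb)


def _rsa_positions(rng, n_segments, lam_seg, L, d_c, r_confine):
    """Hard-sphere RSA: sequential insertion with rejection and re-draw.

    All spheres are proposed at once; conflicts are then resolved in rounds.
    Within a round the earlier-inserted (or already settled) sphere of a
    conflicting pair wins and the loser re-draws its position; re-drawn
    spheres effectively re-enter the insertion queue at the back, so the
    final configuration is overlap-free with the exact target count.
    """
    counts = rng.poisson(lam_seg, n_segments)
    total = int(counts.sum())
    seg = np.repeat(np.arange(n_segments), counts)
    x, y, z = _draw_cylinder(rng, total, L, r_confine)
    if total == 0:
        return counts, seg, x, y, z
    # priority: settled spheres outrank unsettled; otherwise insertion order
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    within = np.arange(total) - np.repeat(offsets, counts)
    settled = np.zeros(total, dtype=bool)
    for _ in range(_MAX_RSA_ROUNDS):
        a, b = _conflict_pairs(seg, x, y, z, d_c)
        if a.size == 0:
            settled[:] = True
            break
        # orient each pair so that the higher-priority sphere comes first
        prio_a = settled[a].astype(np.int64) * total * 2 - within[a]
        prio_b = settled[b].astype(np.int64) * total * 2 - within[b]
        swap = prio_b > prio_a
        a[swap], b[swap] = b[swap].copy(), a[swap].copy()
        # fixed point: a sphere loses iff it conflicts with a surviving winner
        alive = np.ones(total, dtype=bool)
        for _ in range(100):
            loses = np.zeros(total, dtype=bool)
            np.logical_or.at(loses, b, alive[a])
            new_alive = ~loses
            new_alive |= settled  # settled spheres never move
            if (new_alive == alive).all():
                break
            alive = new_alive
        conflicted = np.zeros(total, dtype=bool)
        conflicted[a] = True
        conflicted[b] = True
        settled |= alive & ~settled  # winners (and untouched spheres) settle
        settled |= ~conflicted
        losers = np.flatnonzero(~alive & ~settled)
        if losers.size == 0:
            break
        x[losers], y[losers], z[losers] = _draw_cylinder(rng, losers.size, L, r_confine)
    else:
        raise ValidationError("RSA failed to converge; packing too dense for re-draws")
    return counts, seg, x, y, z


def sample_positions(
    model: PlacementModel,
    jet: JetSpec,
    slurry: CrystalSlurry,
    n_segments: int = 1,
    segment_length: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> PlacementSample:
    """Draw crystal centres for ``n_segments`` independent jet segments."""
    L = segment_length if segment_length is not None else model.segment_length
    if L is None:
        raise ValidationError("segment_length required (set it on the model or pass it)")
    if L <= 0:
        raise ValidationError("segment_length must be > 0")
    rng = rng if rng is not None else np.random.default_rng(model.seed)
    d_c = slurry.crystal_diameter
    A = jet.cross_section
    if model.kind is Placement.POISSON_POINTS:
        counts, seg, x = _poisson_axial(rng, n_segments, slurry.number_density * A * L, L)
        rr = (jet.d_j / 2.0) * np.sqrt(rng.uniform(0.0, 1.0, x.size))
        ang = rng.uniform(0.0, 2.0 * math.pi, x.size)
        y, z = rr * np.cos(ang), rr * np.sin(ang)
    elif model.kind is Placement.TONKS_EQUILIBRIUM:
        theta = packing_fraction_1d(jet, slurry)
        if theta >= 1.0:
            raise ValidationError(f"linear packing fraction {theta:.3g} >= 1 is infeasible")
        counts, seg, x = _tonks_axial(rng, n_segments, linear_density(jet, slurry), d_c, L)
        y = np.zeros_like(x)
        z = np.zeros_like(x)
    else:
        phi = packing_fraction_3d(slurry)
        if phi >= 0.2:
            raise ValidationError(f"packing fraction {phi:.3g} >= 0.2: RSA sampler not valid")
        r_confine = max((jet.d_j - d_c) / 2.0, 0.0)
        counts, seg, x, y, z = _rsa_positions(
            rng, n_segments, slurry.number_density * A * L, L, d_c, r_confine
        )
    return PlacementSample(segment=seg, axial=x, y=y, z=z, n_segments=n_segments, segment_length=L)


def mc_hit_rate(
    model: PlacementModel,
    jet: JetSpec,
    beam: BeamSpec,
    slurry: CrystalSlurry,
    n_pulses: int,
    chunk_size: int = 200_000,
) -> MCEstimate:
    """Binomial hit-rate estimate over ``n_pulses`` independent pulses.

    A pulse hits when any crystal interval [x − d_c/2, x + d_c/2] intersects
    the beam interval of width ``width_x`` centred in the segment.
    """
    if n_pulses < 1:
        raise ValidationError("n_pulses must be >= 1")
    L = segment_length_for(model, beam, slurry)
    rng = np.random.default_rng(model.seed)
    d_c = slurry.crystal_diameter
    half_window = (beam.width_x + d_c) / 2.0
    flags = set()
    if slurry.crystal_diameter >= jet.d_j:
        flags.add("crystal_larger_than_jet")
    A = jet.cross_section
    if model.kind is Placement.TONKS_EQUILIBRIUM and packing_fraction_1d(jet, slurry) >= 1.0:
        raise ValidationError("linear packing fraction >= 1 is infeasible")
    n_hits = 0
    done = 0
    while done < n_pulses:
        n = min(chunk_size, n_pulses - done)
        # hit testing needs axial coordinates only; skip the transverse draw
        # for the models whose axial statistics do not depend on it
        if model.kind is Placement.POISSON_POINTS:
            _, seg, axial = _poisson_axial(rng, n, slurry.number_density * A * L, L)
        elif model.kind is Placement.TONKS_EQUILIBRIUM:
            _, seg, axial = _tonks_axial(rng, n, linear_density(jet, slurry), d_c, L)
        else:
            sample = sample_positions(model, jet, slurry, n_segments=n, segment_length=L, rng=rng)
            seg, axial = sample.segment, sample.axial
        close = np.abs(axial - L / 2.0) <= half_window
        if close.any():
            per_seg = np.bincount(seg[close], minlength=n)
            n_hits += int((per_seg > 0).sum())
        done += n
    p_hat = n_hits / n_pulses
    std_err = math.sqrt(p_hat * (1.0 - p_hat) / n_pulses)
    return MCEstimate(
        n_pulses=n_pulses,
        n_hits=n_hits,
        p_hat=p_hat,
        std_err=std_err,
        model=model.kind,
        seed=model.seed,
        segment_length=L,
        flags=frozenset(flags),
    )


def check_pulse_independence(
    jet: JetSpec, pulses: PulseTrain, beam: BeamSpec, slurry: CrystalSlurry
) -> tuple[float, bool]:
    """Spacing v/f between consecutive probed jet segments vs the window.

    Independent-segment sampling is justified when the jet advances farther
    than the interaction window between pulses; otherwise a warning is
    emitted and correlated statistics would be needed.
    """
    spacing = jet.v_j / pulses.intra_train_rate
    window = beam.width_x + slurry.crystal_diameter
    ok = spacing > window
    if not ok:
        warnings.warn(
            f"pulse-to-pulse jet travel {spacing:.3g} m does not exceed the "
            f"interaction window {window:.3g} m; pulses are not independent"
        )
    return spacing, ok
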