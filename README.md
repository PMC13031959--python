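# sfxjet

Sample-delivery physics for serial femtosecond crystallography (SFX).

SFX solves protein structures from single-pulse diffraction snapshots of
microcrystals streamed through an XFEL beam in a micrometre liquid jet.
Whether a beamtime succeeds is largely decided by sample-delivery physics:
how many pulses hit a crystal, how fast and thin the gas-focused jet runs,
and whether the jet survives MHz pulse trains.  `sfxjet` packages that
physics for beamline scientists and instrument designers:

* **Beamtime budgeting** — the time to collect N indexed patterns,
  t = N / (pulses/s · hit rate · indexable fraction), computed with exact
  rational arithmetic from raw frame/hit/index counts.
* **Hit-rate statistics** — single-crystal hit probabilities versus crystal
  size and focus size under three placement models (Poisson points,
  confined hard spheres, 1D hard rods / Tonks gas), with a seeded
  Monte-Carlo simulator as independent oracle.
* **Nozzle gas dynamics** — choked helium discharge (stagnation pressure,
  sonic state), Sutherland viscosity, Blasius boundary layer, interfacial
  shear stress, Bernoulli liquid velocity, jet-explosion velocimetry and
  continuity diameters, compound-jet (core + sheath) geometry.
* **Viscoelastic sheath physics** — PEO chain geometry and coil statistics,
  entanglement concentrations, the chain census in the X-ray-illuminated
  shell, and the stretch–relaxation chain (Weissenberg numbers, FENE
  steady extension L_steady = L₀√(2 Wi), Zimm relaxation) that explains why
  a 360 nm PEO shell makes jets "superstable".

See `docs/methods.md` for the models, assumptions and defaults.

## Worked example

A conservative plan at 2020 pulses/s, 1 % hit rate, 50 % indexable hits:

```
$ sfxjet acqtime --pulses-per-second 2020 --hit-rate 0.01 --indexable-fraction 0.5
seconds,minutes,minutes_rounded
990.0990099009902,16.501650165016503,17
```

collecting 10,000 indexed patterns takes 990 s ≈ 17 minutes.  Characterise
runs from a CSV run sheet (flows in µL/min, helium in mg/min, pulse-to-pulse
gap displacement in µm):

```
$ sfxjet jet --runsheet examples/runsheet.csv
sample,jet_velocity_m_s,jet_diameter_um,dilution,pulses_per_s,shell_thickness_nm,...
HEWL,44.7252,3.7728,1.0,2020.0,0.0,...
HEWL+water,46.9248,3.6833,1.5,1000.0,337.95,...
```

the first row recovers the velocimetry result 79.3 µm × 0.564 MHz
= 44.7 m/s and the continuity diameter 3.77 µm for 30 µL/min.  The polymer
side of the story:

```
$ sfxjet polymer
monomer_length_nm,backbone_width_nm,n_monomers,contour_length_nm,Rg_nm,...
0.36,0.53,2270,817.2,17.678,...
```

a 100 kg/mol PEO chain has 2270 monomers, an 817 nm contour, a 17.7 nm coil
radius, and ≈11,290 chains sit in the illuminated patch of a 360 nm shell
at 1 % w/v.  A Monte-Carlo hit-rate estimate with full metadata:

```
$ sfxjet simulate --model tonks_equilibrium --crystal-um 3 --n-pulses 100000 --seed 1
n_pulses,n_hits,p_hat,std_err,model,seed,segment_length,flags
100000,2422,0.02422,0.000486...,tonks_equilibrium,1,0.0054,
```

`sfxjet reproduce` recomputes the whole published chain (collection times,
gas dynamics, polymer census, stretch physics) and flags each value
pass/fail/info-only; it exits non-zero if any pass-tier value fails.

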