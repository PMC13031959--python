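# Methods

`sfxjet` models the physics of liquid-jet sample delivery for serial
femtosecond crystallography (SFX): how long a beamtime needs to run, how
often an X-ray pulse hits a crystal, how the focusing gas shapes and
accelerates the jet, and why a thin poly(ethylene oxide) (PEO) sheath makes
micrometre jets dramatically more stable.  This note records the models,
their assumptions, the defaults, and the numerical choices.

## Unit discipline

All computation is SI; beamline units (µL/min, mg/min, MHz, µm) are
converted only at I/O boundaries (`sfxjet.units`, `sfxjet.runsheet`).  The
single exception is the polymer module, which works in nanometres because
every empirical relation it implements — contour length from bond geometry,
the radius-of-gyration scaling laws, the shell census — is quoted in nm in
the polymer literature, and one of them (the R_g = ρ₀ L^ν law) is
dimensionally informal and only meaningful evaluated with L in nm.

## Data-collection-time budgeting

The time to accumulate a target number of indexed diffraction patterns is

    t = N_target / (pulses_per_second · hit_rate · indexable_fraction).

Rates are always derived from raw frame/hit/index counts with exact rational
arithmetic (`fractions.Fraction`), never from pre-rounded percentages: the
published per-run collection times are reproducible only from the unrounded
count ratios.  Display rounding of minutes is round-half-up, which is the
only convention consistent with both "16.50 min → 17 min" and
"9.47 min → 9 min" style quoting.  A zero hit rate yields an explicit
infinite-time sentinel (`math.inf`), not an exception, so parameter sweeps
stay total.  One published run prints a collection time (3.57 min)
inconsistent with its own printed counts (which give 2.57 min); it is
carried as `info_only` in the reproduction report and excluded from
validation as a probable typo.

## Hit-rate models

A pulse hits when at least one crystal overlaps the beam.  The beam is
treated as a transverse slab of width w (the horizontal focus) traversing
the full jet chord, so a crystal of diameter d_c is struck when its centre
lies in an axial window of length w + d_c; the beam height is ignored, a
stated approximation valid while the beam is comparable to or taller than
the jet chord (true for both the 3.5 µm and 0.6 µm foci against ≤4 µm
jets).  Crystals are monodisperse spheres; a measured "2–4 µm" size range
is handled by evaluating the curve at the interval endpoints.

* **Poisson** (ideal points): P = 1 − exp(−λ), λ = ρ (w + d_c) · π d_j²/4.
* **Hard rod (Tonks gas)**: exact equilibrium 1D statistics at linear
  density n_l = ρ π d_j²/4 and packing θ = n_l d_c; the void probability of
  an interval of length w is P_void = (1 − θ) exp(−n_l w/(1 − θ)).  This is
  the appropriate model once crystals approach the jet diameter.
* **Hard sphere**: spheres whose centres are confined to radius
  (d_j − d_c)/2 behave axially like rods with the *mean* exclusion length
  ℓ̄ = E[√(d_c² − s²)], s the transverse separation of two independent
  uniform centres in the confinement disk (evaluated by quadrature of the
  disk line-picking density).  The probability is the Tonks form with rod
  length ℓ̄ and void interval w + d_c − ℓ̄, which keeps the detection
  window at its true value.  ℓ̄ → d_c recovers the rod model; ℓ̄ → 0 or
  dilution recovers Poisson.

A first-principles point: excluded volume **raises** the single-crystal hit
probability relative to Poisson.  Hard-core anticorrelation spreads
crystals apart, so fewer windows waste more than one crystal; a correction
of the form λ(1 − φ) has the wrong sign, as the Monte-Carlo oracle shows
immediately.  The Monte-Carlo simulator, not any closure, is the authority
for validating these analytic forms.

## Monte-Carlo oracle

Each simulated pulse draws an independent segment of jet, populates it
under one of three placement statistics, and tests the axial window; hits
are i.i.d. Bernoulli, giving binomial standard errors.  Independence of
pulses is justified because the jet travels v/f ≈ 40 µm between MHz pulses,
several times the ≤7 µm interaction window; `check_pulse_independence`
asserts this and warns otherwise.  A correlated advected-ribbon mode is
deliberately out of scope.

* *Poisson points*: count ~ Poisson(ρV), centres uniform in the cylinder.
* *Tonks equilibrium*: the exact canonical construction — N sorted uniforms
  on the free length Λ − N d_c plus cumulative rod offsets — with N drawn
  Poisson per segment.  Sorted uniforms are generated via normalised
  exponential spacings, so the sampler is fully vectorised.
* *Hard-sphere RSA*: sequential insertion with rejection and re-draw,
  centres confined to radius (d_j − d_c)/2.  Proposals are laid down in
  bulk and the rare collisions resolved in vectorised rounds (the earlier
  or already-settled sphere wins; losers re-draw, re-entering the queue at
  the back), which preserves the exact target count.  When d_c ≥ d_j the
  confinement radius collapses to the axis and the sampler degrades
  automatically to 1D rods (flagged).

Default segment lengths are 150 interaction windows (500 µm–1 mm scale),
except 1500 windows for the Tonks model: its per-segment rod count is drawn
from a Poisson law, which is overdispersed relative to the true
grand-canonical count, and the resulting bias in the void probability
decays like 1/Λ.  At 1500 windows the residual bias is unresolvable at 10⁷
pulses (measured |z| < 0.5), far below the 3σ criterion used at 10⁶.  A
floor of 100 windows is enforced for user-supplied segment lengths.  One
seeded `numpy` generator drives each run; identical seeds reproduce
estimates bit for bit, and seeds are echoed in all outputs.

## Nozzle gas dynamics

The helium line of a gas-dynamic virtual nozzle is choked at the orifice.
From the measured mass flow ṁ, orifice diameter D and discharge
coefficient C_g (default 0.7), the stagnation pressure follows from the
(linear) choked mass-flow relation, and the sonic state from isentropic
relations: T* = 2T₀/(γ+1), P* = P₀(2/(γ+1))^{γ/(γ−1)}, ρ* = P*/(RT*),
a* = √(γRT*).  Helium ships as a named preset (γ = 5/3,
R = 2077 J kg⁻¹ K⁻¹, Sutherland μ₀ = 1.98×10⁻⁵ Pa s at 298 K, S = 80 K),
overridable in configuration.  The gas viscosity entering the boundary
layer and shear stress is the Sutherland value at the *choked* temperature
(≈1.53×10⁻⁵ Pa s at 210 K), not the room-temperature value — the gas that
shears the jet is the cold expanded gas.  The boundary layer is the Blasius
laminar solution δ = 4.92 x/√Re_x, developed over x = D by default (one
orifice diameter of travel), with a warning beyond Re_x = 5×10⁵.  The
interfacial shear is τ = μ_g Δv/δ with Δv defaulting to 800 m/s — sonic
helium (≈850 m/s) against a ≈40 m/s jet, quoted at the precision this
order-of-magnitude chain warrants; the value used is echoed in results.
The liquid discharge velocity uses Bernoulli with ΔP = P₀, treating the
~10⁻³ mbar chamber as vacuum.

Jet kinematics are measurement-side: explosion velocimetry v = (gap
displacement) × (intra-train rate), continuity d = √(4Q/(πv)), and the
compound-jet geometry d_i = d_j √(Q_i/(Q_i+Q_o)),
t_shell = (d_j − d_i)/2.  One published value — "≈40 m/s" from
Q = 45 µL/min and an image-read d ≈ 4.5 µm — is order-of-magnitude only
(the exact arithmetic gives 47 m/s) and is carried as `info_only`.

## Polymer shell physics

The all-trans PEO backbone gives a monomer length
l = b_CC sin(θ_CCO/2) + 2 b_CO sin(θ_COC/2) and effective width
m = 6 b_CC cos(θ_CCO/2) from tabulated bond lengths (0.154/0.143 nm) and
tetrahedral-ish angles (109.5°/112°).  Both projections are quoted to
0.01 nm — the precision the idealised-geometry model warrants — and the
quoted values (l = 0.36 nm, m = 0.53 nm) feed every downstream volume, so
the derived chain (L = n·l with n = round(M/44.05), V_PEO = m²L, the shell
census) is internally consistent at that precision.  Coil sizes come from
two exposed scaling laws: the Devanand–Selser light-scattering fit
R_g = 0.0215 M^0.583 nm, and the Hofmann form R_g = ρ₀ L^ν (ρ₀ ≈ 1.2,
ν ∈ {1/3, 1/2, 0.6} by solvent quality; dimensionally informal, used as
quoted).  Ideal-chain (Kuhn) relations R₀² = Lb = n_K b², R_g² = R₀²/6 hold
identically by construction.  The overlap and entanglement concentrations
are c* = M/(8 N_A R_g³) and c_e = 2c*: ≈0.75 % w/v for PEO100k, which is
why the 1 % working solution is entangled and carries the long 26.2 µs
relaxation time.

The shell census counts chains the beam illuminates two ways that agree
identically when unrounded: (i) concentration × V_shell/V_PEO with
V_shell = 2 t_shell x_spot² (both shell crossings), and (ii) an anisotropic
box product N_x N_y N_z with per-axis packing factors (c_x, c_y, c_z)
multiplying to the concentration — chains lie along the jet, so the default
is c_y = 1, c_x = c_z = √c.  Both end-to-end conventions in circulation
(√6 R_g for a Gaussian coil, √3 R_g in the stretching estimate) are exposed
explicitly; neither is silently preferred.

## Stretch and relaxation

The shear rate in the thin shell is γ̇ = τ/η with η ≈ 1 mPa s
(shear-thinning adjusted).  Weissenberg numbers Wi = rate × λ_r use an
explicit λ_r always: 7 ns (dilute Zimm) gives Wi ≈ 0.009 ≪ 1, while the
1 % w/v value 26.2 µs gives Wi ≈ 34 — the same flow that would let a dilute
chain relax freezes an entangled one.  The meniscus strain rate is
ε̇ = −2Q/(πr³)·dr/dz, ≈1.5×10⁷ s⁻¹ at the tip, giving extensional Wi in
the hundreds: a firm coil–stretch transition.  The affine stretch time is
ln(L/L₀)/ε̇; the FENE-dumbbell steady extension is L_steady = L₀√(2 Wi),
clamped to [L₀, L_contour] with explicit flags rather than errors (below
Wi = 0.5 the formula would shrink the coil; finite extensibility caps it),
so sweeps stay total.  Stored elastic energy is proportional to
R²/(L² − R²), and relaxation follows the Zimm exponential
L(t) = L_steady + (L_total − L_steady)e^{−t/λ_r}.  The Zimm profile is
implemented exactly as stated even though its asymptote is L_steady, not
the near-coil length; the published "≈10 µs to near-coil" is therefore not
derivable from it and is treated as an input to the relaxation-length
estimate (v_jet × t ≈ 0.4 mm), never as a validated output.  Published
variants of the stretch numbers (200 vs 226 ns; Wi 390 vs 340) are both
recorded; the package reports unrounded values.

## Reproduction report and tolerances

`sfxjet reproduce` (and `sfxjet.report.reproduce()`) recomputes every
reference value live and compares at a tolerance of
max(0.5 %, half the printing quantum): closed-form chains against
3-significant-figure values get 0.5 %, coarser-printed values (360 nm,
1.3 kPa, 1.5×10⁷ s⁻¹) get half their last printed digit.  Known
inconsistencies are `info_only` and never fail the run.  Monte-Carlo
comparisons use 3 binomial standard errors at 10⁶ pulses.

## Problem sizes

The test suite runs the Monte-Carlo oracle at 10⁶ pulses per grid point on
a 12-point (crystal size × beam width × model) grid, with 10⁴–2×10⁵ pulses
in unit-level checks; the full suite completes in about a minute on one
CPU.  Development-time bias measurements used 10⁷ pulses.

## Known limitations

No multi-crystal-per-shot statistics (the ≥80 % nanocrystal regime), no
crystal polydispersity, no diffraction-signal or detection-threshold
modelling, no whipping instability or jet-breakup dynamics, and no
crystallographic data processing.  The hard-sphere closure is first-order
in packing (validated to φ < 0.03 against RSA; flagged beyond φ = 0.3),
and the RSA ensemble is non-equilibrium — at the dilutions of interest the
difference from equilibrium is below Monte-Carlo resolution.  The
synthetic-data generator emulates crystal *placement* statistics only;
real jets add flow-rate drift, crystal settling, filter losses and beam
pointing jitter, so agreement here demonstrates the statistical model
chain, not detector-level hit rates.
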