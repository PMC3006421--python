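# Methods

## Model overview

The package simulates one temperature-controlled RF activation of a
bronchial-thermoplasty catheter: a 3 s closed-loop delivery in which a
PID controller ramps the electrode thermocouple to 65 °C over 0.5 s and
holds it there. Two fields are coupled on a shared tetrahedral mesh of
a symmetry-reduced sector:

- a quasi-static conduction (Laplace) problem for the electric
  potential with temperature-dependent tissue conductivity
  σ(T) = σ₀·exp[α(T − T₀)], α = 0.015 /°C — at 480 kHz soft tissue is
  essentially resistive, so displacement currents and capacitive
  coupling are neglected;
- the transient Pennes bioheat equation with Joule source, blood
  perfusion sinks, and evaporative sinks.

Conductivity is refreshed (and the electrical problem re-solved) before
every thermal step, the stronger reading of "coupled".

## Geometry and mesh

Cylindrical coordinates, airway axis = z. The 30° sector (1/12 of the
circumference for six equally spaced electrodes) spans z ∈ [0, 10 mm]
with mirror symmetry at the electrode's axial midpoint. Defaults: 4 mm
lumen, wall thickness 10 % of the lumen diameter (2.0 → 2.4 mm radii),
10 mm electrode length, parenchyma out to r = 10 mm.

The electrode cross-section is not published; it is modeled as an
annular-sector box (width 0.5 mm, height 0.25 mm, embedded 0.1 mm into
the wall, all configurable) rather than a D-profile — the profile
detail is below the resolved scale, and the box conforms exactly to the
structured grid.

Meshing is a graded tensor grid in (r, θ, z) whose breakpoints coincide
with every material interface; each hexahedral cell is split into six
tetrahedra (Freudenthal subdivision, conforming across cells, no
inverted elements by construction). Resolution is finest at the
electrode–tissue interface and coarsens monotonically outward. The
parenchyma and far-axial margins grade from a *fixed first-cell size*,
so near-field resolution does not change when the domain margins are
rescaled (important for the domain-size sensitivity check). The lumen
is truncated at a small core radius (0.4 mm) instead of being meshed to
the axis; the truncation face is adiabatic and insulated, and lumen air
(σ = 10⁻¹⁶ S/m, k = 0.030 W/m/K) is near-inert there. Refinement
levels: tiny (≈3k elements, tests), coarse (≈12k, default), medium,
fine (≈82k), paper-fidelity.

Verification is by mesh convergence against closed forms (slab and
annulus resistance, logarithmic steady conduction profile), not by
matching any particular element count.

## Materials

| material | σ₀ S/m | k W/m·K | c J/kg·K | ρ kg/m³ |
|---|---|---|---|---|
| lumen air | 1e-16 | 0.030 | 1009 | 0.995 |
| blood | 0.748 | 0.52 | 4176 | 1060 |
| airway wall (trachea) | 0.359 | 0.5 | 3000 | 1500 |
| parenchyma | 0.15 | 0.451 | 1643 | 199 |
| electrode (SS 304) | 1.39e6 | 16.2 | 500 | 8030 |

σ(T) applies to tissue only; metal and air are temperature-independent,
and σ(T) is clamped above 100 °C purely as a numerical guard for
off-nominal sweeps. Parenchyma is treated as an 80/20 air/blood volume
mixture: the mixture rule reproduces σ₀ = 0.2×0.748 ≈ 0.15 S/m and
c ≈ 1642 J/kg·K, but the tabulated k and ρ are measured lung values and
are used verbatim (the 80/20 volume-average density would be ≈213, not
199; the mixture rule is exposed for sensitivity studies only). k, c,
ρ, and h_fg are held temperature-independent.

## Loss terms

**Perfusion.** Pennes sink ρ_b c_b ω (T − T_body) with ω = 0.02 s⁻¹ in
parenchyma (5.25 L/min cardiac output distributed over a 4.3 L lung)
and 0.6×10⁻³ s⁻¹ in the wall (resting skeletal-muscle estimate).
Perfusion is constant — local heating is assumed not to change it.

**Evaporation.** Each alveolus (diameter 0.3 mm) is a moist sphere
losing water by steady diffusion: per-alveolus power
h_fg·2πd·M·D(T)·(1−H_r)·C_s(T), with D(T) = (0.171·T + 20.84)×10⁻⁶
m²/s, C_s(T) = 0.2821·e^(0.0588T) mol/m³ (the molar unit is inferred
from the presence of the molar mass M; the fit reproduces published
saturation tables), H_r = 0.95, h_fg = 2.4×10⁶ J/kg. The volumetric
sink is the per-alveolus power times the alveolar number density
(3×10⁸ alveoli / 4.3 L). The luminal surface carries the same physics
reduced to a planar diffusion film of thickness δ = 1 mm (configurable;
the published form of the luminal term is not available).

Both terms are referenced to their 37 °C values by default
(`mode.baseline_subtraction`), so they represent the *increase* in
evaporative loss during acute heating. This is a deliberate design
choice: applied at full value, the printed coefficients imply a resting
volumetric sink of ~1.9×10⁷ W/m³ throughout the parenchyma — a resting
loss that is in reality balanced by physiology and is not part of the
treatment energy balance; carrying it unbalanced refrigerates the whole
domain and breaks energy-budget closure. Even in subtracted form the
evaporative sink is strong (its linearization, ~1.1×10⁶ W/m³/°C at
37 °C, exceeds the perfusion sink by an order of magnitude), making
evaporation the dominant loss channel, consistent with its described
importance. Convective cooling inside the lumen is neglected (stagnant
air around the catheter).

## Boundary and initial conditions

Electrical: drive voltage on the electrode cross-section at z = 0;
ground (0 V) on the 30° midplane; all other exterior surfaces
insulated. Thermal: symmetry planes and the lumen-truncation face
adiabatic; outer radius and far axial face fixed at 37 °C; evaporative
flux on the luminal surface.

Initial conditions (three modes): `nominal` — tissue 37 °C, electrode
and lumen air 35 °C (nodes shared with tissue stay at 37 °C: the
contact surface equilibrates on contact, and a cold luminal surface
node set would leak a spurious ~0.24 W through the fixed far boundary);
`pretreat_offset` (default) — additionally imprints the residual warmth
of the generator's 0.1 A, 300 ms test pulse as a Gaussian bump
(length scale 0.5 mm) so the control point reads 41 °C, matching the
published starting point; `pretreat_pulse` — actually simulates the
constant-current test pulse (it warms the control point by ~1.7 °C from
35 °C and its energy is logged separately, not added to the activation
energy).

## Time integration and control

Backward-implicit stepping with lumped (row-sum) mass: conduction and
perfusion implicit; Joule source and evaporation sinks evaluated at the
previous iterate, with an optional Picard loop (tol 10⁻⁶, ≤5 passes).
Lumping makes the discrete energy identity exact per step: stored heat
= Joule − perfusion − evaporation − boundary outflow (the outflow is
the consistent reaction at the fixed-temperature nodes), so the energy
budget closes to round-off by construction and is asserted to ≤1 %.

Step size starts at 10⁻⁶ s, doubles on smooth steps up to 0.03 s,
halves on rejection, and is truncated to land exactly on 50 ms
telemetry boundaries. A step is also rejected when the largest nodal
temperature change exceeds 1 °C — a transient-accuracy control that
keeps the ramp resolved (the bound matches the ~1 °C tracking tolerance
of interest).

The PID law V = k_p e + k_i ∫e + k_d de/dt (k_p = 20, k_i = 60,
k_d = 0; error = target − measured, the sign that produces positive
drive) is evaluated **continuously**, at every solver step, with
trapezoidal integral accumulation. This is a deliberate design choice:
with this plant, a strict 50 ms zero-order hold at k_p = 20 is
unstable (the sampled-data loop gain exceeds unity and the voltage
limit-cycles between the clamp and zero), whereas microsecond startup
steps and degree-level tracking are natural when the control expression
lives inside the transient solve. The strict 50 ms zero-order-hold mode
is retained (`controller.cadence: interval`), and 50 ms remains the
telemetry cadence in both modes. The output clamp defaults to
[0, 50] V on the sector drive (the physical generator's limit is not
published) with conditional-integration anti-windup; in the default
per-step mode the clamp is inactive after the first milliseconds. The
derivative term, if enabled, acts on the measurement to avoid set-point
kick. The commanded hold level, ramp time, and activation length are
configurable; the target ramp starts from the measured initial
control-point temperature unless overridden.

## Device-level telemetry and the symmetry convention

Adjacent electrodes are driven antisymmetrically (±V), so the midplane
between them is 0 V by symmetry and the sector drive voltage is half
the generator terminal voltage. The sector carries 1/4 of one
electrode's current (two circumferential sides × two axial halves), and
the generator sources three of the six electrodes. Telemetry therefore
reports V = 2·V_drive, I = 12·I_sector, Z = V/I, P = V·I = 24 × sector
power. These factors are frozen by two brute-force audits (a
double-width model with a whole electrode between grounded midplanes,
and a 60° model with a ±V electrode pair whose midplane must float at
≈0 V) that together compose to the full 1/24 reduction.

## Sensitivity sweeps

`sensitivity_sweep` reruns the activation per multiplier and tabulates
relative changes of total energy, ramp energy, and treatment-zone
thermal metrics. The treatment zone is the wall under the electrode
(z ≤ electrode half-length): a fixed region that stays comparable when
the domain is rescaled (averaging over the whole wall would dilute the
average with 37 °C tissue and measure the averaging domain, not the
physics). The domain-size multiplier scales the parenchyma margins
beyond the wall and electrode — halving the literal half-length would
collide with the 5 mm electrode half-length and describe a different
device, not a smaller domain.

## What the model does and does not show

The defaults reproduce the study conditions: coarse-mesh activation
holds 65.00 ± 0.02 °C with a ramp-end tracking error of ~0.2 °C, and
the hold-phase delivered power (~4.2 W) matches the published energy
slope. Two quantities sit outside the published bands and are reported
as they come out: the ramp energy E(0.5 s) converges to ~10.3–10.7 J
against a published 7.7 J (hold physics matches, so the excess is
ramp-phase stored heat near the electrode, governed by the unpublished
electrode cross-section and embed depth), and the ±20 % alveolar-ratio
sweep moves total energy by up to ~3.8 % against a published ±2.8 %
(±0.7 J vs ±0.5 J absolute; our evaporative share of the budget is
larger). Hold-phase impedance is essentially flat (≈93 Ω, <1 % drift)
rather than slowly decreasing: the near-electrode hot spot formed
during the ramp relaxes after the power drops fivefold at ramp end,
slightly outweighing far-field warming. Impedance does fall strongly
while the tissue heats (113 → 87 Ω over the ramp) and ends below its
starting value.

Known limitations: no tissue-damage (Arrhenius) model; no boiling or
phase change above 100 °C; humidity is a constant parameter, not a
transported field; no dispersive dielectric model; no airway branching
or electrode-contact mechanics; the experimental canine telemetry
curves are not reproduced (raw data unpublished). The synthetic
geometry is an idealized circular airway — real airways are
non-circular, wall thickness varies with inflation, and electrode
contact is irregular, so agreement here bounds numerical and model
consistency, not anatomical realism.
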