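# Methods

This note documents the models, numerical choices and limitations of
`theatresmoke`. The package quantifies how the tip temperature of an
electro-surgical knife shapes the dispersion of surgical smoke — waste gas
(CO, CO2, CH4, NH3), condensed tar droplets and non-viable particles — in
a laminar-flow operating theatre, and the resulting exposure of surgeon
and patient.

## Empirical source models

In vitro tissue-cutting measurements across knife powers P = 20–80 W are
summarized by four least-squares polynomials (ascending coefficients):

| quantity | polynomial | units |
|---|---|---|
| tip temperature `T_tip` | `270 − 4.59 P + 0.095 P²` | °C |
| net waste-gas flow `G` | `9.30e−6 − 4.49e−8 P + 7.16e−9 P²` | m³/s (STP) |
| particle formation `F_p` | `−4.14e−3 + 6.33e−4 P − 2.06e−6 P² + 2.80e−7 P³` | g/s |
| tar formation `F_t` | `2.82e−3 + 4.69e−4 P − 9.69e−6 P² + 1.98e−7 P³` | g/s |

Notes and choices:

* The particle cubic is negative below ~6.6 W; the evaluator clamps it to
  zero by default because a formation rate cannot be negative, while
  refitting (which must see the raw polynomial) can disable the clamp.
* The published power↔temperature correspondence (20/60/70/80 W ↔
  200/300/400/500 °C) comes from rounding the quadratic to the nearest
  100 °C. The quadratic's minimum is ~214.6 °C at 24.2 W, so 200 °C is not
  exactly attainable; `power_for_temperature` honours the published table
  in lookup mode (the default when assembling the four canonical cases)
  and otherwise returns the exact larger root, flagging temperatures below
  the vertex.
* Refitting uses unweighted ordinary least squares (degree 2 for the
  quadratics, 3 for the cubics), with a rank check on the number of
  distinct powers.

The synthetic sweep generator emulates the bench experiment: responses are
the truth polynomials times `(1 + ε)`, `ε ~ N(0, cv²)`, clamped at zero,
with one child seed stream per response so adding a response never
perturbs the others. Multiplicative noise is the natural model when the
responses span four orders of magnitude; the original study reports no
replicate counts or uncertainties, so the default `cv = 0.02` is a
declared assumption. What passing recovery tests show is that the fitting
machinery is unbiased and consistent under this noise model — not that
the bench data had this error structure.

## Theatre scene and mesh

The theatre is an 8 × 6 × 3 m room: a 2.4 × 2.6 m ceiling inlet supplies
a uniform 0.096 m/s downward air curtain; two 4 × 0.3 m outlet slots sit
0.1 m above the floor on the two opposite 8 m walls (the source setup
states only "two opposite walls"; this is the pair the 4 m slot fits
centred on); a
1.8 × 0.8 × 0.8 m operating table stands centred on the floor; the
incision — the smoke source — is 0.1 m above the table centre (z = 0.9 m).
The inlet is centred on the ceiling (placement unstated in the source
description; centring is the symmetric choice).

The mesh is rectilinear Cartesian. Cells whose centre falls inside the
table box (half-open comparisons throughout, so every point belongs to
exactly one cell) are solid; every boundary or fluid–solid face carries
one patch label, assigned by which patch rectangle the face centre falls
in. By default the axes are **graded** toward the incision with a smooth
Gaussian-bump width profile: on the standard 40 × 30 × 15 grid the finest
cells are 6.5–8 cm — the scale of the wound region the smoke actually
emerges from — against ~20 cm mean spacing. This matters physically: the
source releases only a few W of sensible heat, and on a uniform 20 cm
grid that heat dilutes below the ~1 K excess needed to reverse the
ceiling downdraft, so no plume can exist in cell-averaged fields at all.
Grading restores a resolvable buoyant column while keeping the cell count
at desk scale. A uniform mesh remains available (`graded_mesh: false`)
and is used by the geometry unit tests. Stretching the finest cells to
~5 cm (min_fraction 0.15) destabilizes the collocated scheme and is
rejected.

## Flow model

Steady incompressible RANS with the standard k–ε closure:

* eddy viscosity `μ_t = ρ C_μ k²/ε` with the study's constants C1 = 1.43,
  C2 = 1.93, C_μ = 0.09, σ_k = 1.0, σ_ε = 1.43 (slightly off the
  canonical 1.44/1.92/1.3 set, which stays selectable);
* energy equation for temperature with effective diffusivity
  `μ/σ_T + μ_t/σ_tT` (σ_T = 1.0, σ_tT = 0.9);
* buoyancy through the gravity term only, with the full ideal-gas density
  ratio `ρ(T) = ρ_ref T_ref/T`: the source sits ~470 K above ambient,
  far beyond the Boussinesq linearization, while Mach numbers are ~1e−4,
  so density variation elsewhere is negligible;
* standard wall functions (log law above y* = 11.63, linear below) for
  wall shear and near-wall ε; the four vertical walls carry a Robin heat
  condition with exterior coefficient 1.5 W/m²K in series with the
  interior film conductance and exterior temperature 30 °C (these warm
  walls drive the weak natural-convection updraft observed along the
  outlet-free walls); ceiling, floor and table are adiabatic;
* inlet turbulence from `k = 1.5 (V T_i)²`, `ε = C_μ^0.75 k^1.5 / l` with
  intensity 3.7% and `l = 0.07 ×` the 2.4 m inlet width (the 2.4 vs 2.6 m
  ambiguity is a config knob);
* waste-gas species as passive scalars (no effect on mixture density
  except through temperature).

The smoke source is a volumetric mass/momentum/enthalpy/species source in
the cell containing the incision point: the physical source is sub-grid
at any room-scale resolution. The measured net waste-gas flow is
STP-referenced, so the injected mass rate is `ρ_STP · G`; the gas enters
at the tip temperature and its injection velocity follows from ideal-gas
expansion over the source-cell footprint. Air properties
(μ = 1.85e−5 Pa·s, cp = 1006 J/kg/K, M = 28.96 g/mol at ~300 K) and the
dispersed-phase densities (tar 1000, particles 1200 kg/m³) are config
defaults standing in for an unavailable measured property table; the
waste-gas composition is likewise a configurable placeholder (mole
fractions CO 0.25, CO2 0.45, CH4 0.06, NH3 0.04) respecting the reported
dominance of CO + CO2, and **every absolute CO concentration downstream is
composition-dependent**.

## Discretization and solution

Finite volumes on the collocated rectilinear grid: first-order upwind
convection (bounded) with central diffusion; Rhie–Chow face-flux
interpolation against pressure checkerboarding; SIMPLEC pressure–velocity
coupling with per-face flux corrections (continuity closes to the inner
CG tolerance each outer iteration, and a few tight projections polish the
fluxes before the passive scalars are transported). A deferred-correction
blend toward central-difference convection exists for momentum and energy
(`central_blend`); it is off by default because on the benchmark plume
cases it either limit-cycles (full central) or converges to slightly
lower ascent heights (half blend) without improving the physics.

Outer iterations are damped two ways: implicit under-relaxation
(0.7 momentum, 0.3 pressure, 0.5 scalars — standard SIMPLEC practice) and
a pseudo-transient inertial term `ρV/Δτ` with Δτ = 2 s that conditions
the nearly stagnant regions and cancels identically at steady state
(converged fields agree to a few mm in plume height for Δτ between 1 and
4 s). Strongly anisotropic grids (cell aspect ratios ≳ 4) need a gentler
continuation, Δτ ≈ 0.5 s. Linear systems: red–black Gauss–Seidel sweeps (numba-compiled when
available, vectorized Jacobi otherwise) for momentum and scalars, and a
Jacobi-preconditioned conjugate-gradient solve of the SPD
pressure-correction system.

Residuals are scaled FLUENT-style by the magnitude of each equation's own
transport terms, `Σ|a_P φ_P|`, floored by an inlet-throughput reference so
trivially satisfied equations read as converged; the continuity residual
is scaled by the inlet mass flow. (Normalizing by the first-iteration
residual was tried first and abandoned: cold-start spikes inflate the
norm and declare stiff graded-mesh cases converged prematurely.) The
default tolerance is 1e−4; the coarse-grid exposure cases use 1e−3, by
which point the plume height changes by < 1% per further decade of
residual. Temperatures are carried in kelvin internally; k and ε are
floored at tiny positive values; T is clamped to the physically
attainable band between the coldest boundary and the source temperature.

Degenerate inputs are rejected early: patches unresolved by the grid
raise a mesh error naming the patch, a source position inside the table
raises a config error, and non-finite fields or velocities beyond
50 m/s raise a solver fault carrying the residual history.

## Dispersed phase

At d_p = 2 μm the Schiller–Naumann relaxation time is
`τ = ρ_p d_p²/(18 μ) ≈ 1.2e−5 s` against flow time scales of seconds
(Stokes number ≪ 1), so:

* the **Eulerian route** (quantitative: profiles, g/m³ values, threshold
  flags) treats each phase as a passive scalar with the measured
  injection rate at the incision — the small-Stokes limit of the mixture
  formulation;
* the **Lagrangian route** (qualitative: trajectories, fate statistics)
  integrates the drag law with an exact exponential update of the linear
  relaxation, unconditionally stable for any step, so the step size is
  set by the cell-crossing time alone (a τ/5 step bound would demand ~1e7
  steps per parcel and is redundant given the exact integrator). The
  drag law carries no body force; gravity is an opt-in flag (terminal
  velocity ~0.12 mm/s, negligible in 0.1 m/s room currents, but the flag
  lets the Stokes settling limit be verified exactly).

The two routes are kept distinct deliberately — the source description
invokes both a discrete-phase and a mixture treatment without
reconciling them — and a test checks they agree on where the smoke
accumulates (rank ordering of the most-loaded cells).

## Exposure metrics

* **H_smoke**: on the vertical cell-centre line through the incision, the
  lowest positive-to-negative sign change of vertical velocity above the
  incision, linearly interpolated; "plume reaches ceiling" and "no
  upwelling" are explicit flagged outcomes, not numbers. The first
  crossing (not the highest) is used because a single plume turned back
  by the ceiling downflow has exactly one physical turnover height.
* The published H_smoke(T_tip) quadratic is evaluated with
  exponent-restored coefficients `(1.14, −6.37e−4, 2.45e−6)`: as printed
  (−6.37 T + 2.45 T²) the curve would give ~1e5 m at 200 °C, while the
  restored form reproduces the reported 1.1 m and 1.45 m endpoints —
  read as typeset decimal exponents lost in production.
* **Flow zones**: cells are labelled by sign/position rules on the
  velocity (upwelling above the incision, laminar downflow over the
  table, horizontal flow toward the outlet walls, slow peripheral
  downflow, horizontal flow toward the outlet-free walls, wall
  natural-convection updraft, other). The rule thresholds (0.005 m/s,
  0.5 m upwelling radius, 1.5-cell wall layer) are config-exposed; the
  labels partition the fluid volume exactly. The source material
  enumerates seven zones but never defines zone (3); "other" absorbs the
  gap.
* **Zones for thresholds**: the surgeon operating zone is the box within
  0.5 m horizontally of the incision between 1.1 and 1.45 m height (the
  counter-flow region a bowed-over surgeon breathes in); the wound zone
  is the incision cell plus its face neighbours. Threshold flags are
  strict comparisons of zone means: CO 9 ppm (EPA 8-hour limit), 50 ppm
  and 200 ppm (both reported for the surgeon zone in mutually
  inconsistent places — the report carries both flags and takes no
  side), tar 20 g/m³ and particles 12 g/m³ for the wound.
* **ppm conversion**: `ppm = Y_CO (M_mix/M_CO) · 1e6` with M_mix fixed at
  dry air (dilute-smoke approximation).
* Nose-height profiles are trilinear samples along the table centre line
  at z = 1.1 m (lying patient) and around the table border at z = 1.5 m
  (standing surgeon).

## Problem sizes

The standard analysis grid is 40 × 30 × 15 (18 000 cells, graded); the
grid-sensitivity companion is 64 × 48 × 24. One coarse-grid case
converges to 1e−3 in roughly 2 000–3 000 outer iterations (about two
minutes with numba). The test suite runs the four canonical cases once on
the standard grid and shares them across tests; unit-level solver checks
use 20 × 15 × 9 and smaller grids.

## Known limitations

* Scaled-down fidelity: the coarse-grid ascent heights land within ~5%
  (200 °C) and ~13% (500 °C) of the published values; the hotter plume is
  still under-resolved at desk scale, and near-source concentrations
  remain discretization-dependent (a point source has no grid-converged
  cell value).
* The k–ε model with wall functions is dubious at these near-laminar
  indoor velocities; it is used because it is the study's stated closure.
* No radiation, humidity, transient dynamics, two-way particle coupling,
  coalescence/evaporation of tar, or turbulent-dispersion random walk for
  parcels; no patient/surgeon bodies or lamps in the scene.
* Absolute CO ppm values inherit the assumed source composition wholesale
  and are flagged accordingly; only their monotonicity in tip temperature
  is meaningful under the defaults.
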