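# Methods

## Model overview

`hapsim` is a deterministic hybrid model: discrete cells (static polygonal
contours discretized into boundary points) embedded in continuum fields
(oxygen, inactive pro-drug, active drug, metabolic sensitizer) on a
Cartesian grid, coupled through (i) a regularized-Stokeslet interstitial
flow in which cell boundaries are no-slip obstacles, (ii)
receptor-localized uptake terms, and (iii) an irreversible per-cell death
switch that feeds back into the uptake terms.  Cells neither move, divide
nor lyse — the simulated horizon is three hours.

All internal quantities use a single μm–minute unit system (velocities in
μm/min, diffusivities in μm²/min, viscosity in mg/(μm·min)); concentrations
are mmHg for oxygen and ag/μm³ for the drugs and sensitizer.

## Tissue geometry and the synthetic generator

The domain is Ω = [0, 200] × [0, 100] μm with the vessel along the left
edge and h = 2 μm grid spacing.  Grid nodes covered by a cell contour
(boundary-inclusive point-in-polygon, via shapely) are masked: they carry
no field values and are omitted from all stencils.  Each boundary point is
a pseudo-receptor whose neighborhood is the set of interstitial nodes
within strict distance ε = 2 μm (the indicator χ_ε); a node inside several
receptor disks is counted once per covering receptor, so uptake scales with
the local receptor density.  Receptors at tight cell–cell contacts may
cover no interstitial node at all; they then absorb nothing (logged).

The synthetic generator emulates a segmented histology patch by a **shrunk
Voronoi tessellation**: Voronoi regions of a jittered hexagonal point set
(mirror-padded for boundedness) are each shrunk inward by half the
inter-cell clearance (2.8 μm by default), producing irregular polygonal
cells arranged in cords with narrow interstitial channels, a cell-free
strip of 2ε along the vessel edge, and contours resampled to ε spacing.
`n_cells` sets the packing density (default 300 on the full domain, the
scale of the digitized tissue this emulates); `mean_radius` (default 4 μm)
caps the equivalent-circle radius at 1.4× and floors it at 0.35×.  The
clearance default keeps every channel wide enough to carry grid nodes; the
emergent cell-area fraction is ≈ 0.37 and the emergent steady-state
normoxia/hypoxia border falls at ≈ 105–130 μm across seeds, matching the
oxygenation structure of the digitized tissue the model was built around.
Real histology features the generator does **not** emulate: cell-size
zonation with vessel distance, anisotropic cords, multiple or non-straight
vessels, and stromal regions.  Tests passing on this geometry therefore
validate the solver contracts and the model's qualitative behavior, not
patient- or slide-specific quantitative outcomes.

## Interstitial flow

Stokes flow (Re ≪ 1) is solved by the method of regularized Stokeslets:
point forces smoothed by φ_ε(r) = 2ε⁴/π(r²+ε²)³ placed at spacing ε on the
vessel face (imposed velocity u_in along +x), on the top/bottom walls
(zero velocity; walls own the corner points) and on every cell boundary
point (zero velocity).  The right edge is an open outflow and carries no
constraint.  The 2M×2M mobility system is solved directly (LAPACK LU) for
2M ≤ 12000 and by restarted GMRES above that; either way the promise is
the residual — re-evaluated boundary velocities must match the imposed
ones to 1e-8 relative, or the solve raises.  The velocity is then evaluated
once at every interstitial node and cached; in-cell nodes report exactly
zero.  The vasodilator multiplies the cached field by λ (Stokes linearity
makes this exact).  Pressure is never materialized.

**Transport regime.**  The default influx speed is u_in = 1 μm/min.  At
this speed the domain Péclet number uL/D_γ ≈ 0.2 and compound transport is
diffusion-dominated, which is the regime consistent with the tissue-scale
behavior this model represents: pro-drug penetration over tens of minutes
to hours, slow interstitial clearance, and a stable oxygen gradient with a
hypoxic far side.  At a literal 1 μm/s (60 μm/min) the channel would flush
every compound in ~3 minutes and no hypoxic steady state could form at
these uptake rates.  The speed is a config field (`fluid.u_in`) for users
who want the advective regime.

## Transport discretization

Each species advances by Lie splitting at Δt = 1.5×10⁻³ min: (1) boundary
values, (2) diffusion, (3) advection, (4) reactions; the splitting error is
O(Δt).

* **Masked diffusion** — explicit 4-neighbor Laplacian in which any
  neighbor inside a cell is omitted from the stencil (cell interiors are
  impermeable; interstitial mass changes only through domain edges).  The
  unsplit 2D update is stable and positivity-preserving only for
  ν = Δt·D/h² ≤ 0.25, while oxygen and sensitizer run at ν = 0.375;
  `masked_diffusion_step` therefore substeps internally so each substep
  carries ν ≤ 0.25 (two substeps at the defaults).  The call contract
  rejects ν > 0.5.
* **Advection** — first-order upwind along the cached flow; an in-cell or
  off-grid upwind neighbor contributes zero gradient, so nothing is
  transported across cell boundaries.  CFL at the defaults is ≈ 7×10⁻⁴.
* **Boundary conditions** — right edge: zero Dirichlet (open tissue);
  top/bottom: no-flux.  Left (vessel) edge: oxygen always exchanges with
  plasma (Dirichlet γ^in = 60 mmHg, λ-scaled during the vasodilator
  window).  A drug or the sensitizer is pinned to its λ-scaled vascular
  value (η_i: 50, ξ: 101 ag/μm³; η_a: 0) **only while it is in
  circulation**; after plasma clearance the vessel wall becomes no-flux
  for that compound.  This makes interstitial clearance intrinsically slow
  (diffusion out of the open right edge only) — the behavior that lets
  late enhancer injections still find drug in the tissue.  An absorbing
  post-bolus vessel would instead drain the near-vessel tissue within
  minutes.  The optional interstitial decay ω_i (default 0) provides a
  fast-clearance variant.
* **Reactions** — oxygen uptake ψ(ξ, γ)·cover at receptor-covered nodes;
  hypoxia-gated activation moving a fraction of η_i to η_a per step;
  active-drug uptake α·η_a·cover and decay ω_a = ln2/10 per min.  Negative
  values from roundoff are clamped to zero and counted; default runs
  produce zero clamp events, and the counter is surfaced in every result.

**Oxygen uptake function.**  Above the severe-hypoxia level
(γ ≥ 0.5·γ_hyp = 5 mmHg) uptake is the sensitizer-tiered constant γ₀·ψ_k
(left-inclusive tier edges at ξ = 9, 22, 88 ag/μm³).  Below it the rate
ramps linearly to zero with the remaining oxygen, γ₀·γ/(0.5·γ_hyp),
joining the constant branch continuously at 5 mmHg.  The continuity is
load-bearing: a rate that jumps at the branch point gives weakly-supplied
tissue two stable oxygen states, and a transient (e.g. a vasodilator
bolus) would leave the field permanently below its initial gradient
instead of recovering — contradicting both the uniqueness of the steady
state and the transient-hypoxia behavior the model exists to capture.

**Activation.**  The conversion gate is inclusive (γ ≤ γ_hyp) and the
default reading is *per-step*: 90% of the local inactive drug converts each
Δt while hypoxic — effectively instantaneous conversion, keeping active
and inactive pools an order of magnitude apart.  A continuous-rate reading
(0.9/min) is available via `activation_mode="per_min"`.

## Steady-state oxygen

Every simulation starts from the stationary oxygen gradient: the drug-free
oxygen update iterated until ‖γⁿ − γⁿ⁻¹‖₂/(N_i·N_j) < 10⁻¹⁰ (all cells
alive, no sensitizer).  With the defaults this converges in a few tens of
thousands of iterations; against closed-form 1D solutions the converged
field is exact to rounding without flow, and within the upwind scheme's
numerical-diffusion envelope (D + u·h/2) with flow.

## Pharmacodynamics

Cell l accumulates Γ_l += Δt·α·Σ η_a over its receptor neighborhoods, on
exactly the same η_a values from which the transport step removes
Δt·α·η_a·cover — node removal and cell gain are two views of one flux and
agree to 1e-10 relative over any interval (asserted in tests).  The death
test converts the node-sum to a mean concentration (Γ_l·h²/A_l, making the
threshold's units ag/μm³) and fires at ≥ 1, once per step after the
reaction stage; ties break toward death.  Dead cells are removed from the
oxygen- and drug-uptake coverage from the next step and keep their
(frozen) accumulation; their contours remain obstacles.

## Schedules, metrics and sweeps

A schedule is at most one bolus per compound over a 180-min horizon
(plasma windows: HAP 10 min, sensitizer 25 min, vasodilator 25 min).  The
reported metrics are the dead-cell count/fraction, the tissue-mean
interstitial oxygen, and the normoxia/hypoxia border — the smallest
vessel distance whose per-column interstitial mean falls below γ_hyp
(domain length when no column qualifies; all-interior columns are treated
as missing).  Offset sweeps shift the enhancer boluses relative to the HAP
start (negative = before HAP); when an offset would start before t = 0 the
whole schedule shifts right so the earliest compound starts at zero.  Each
lattice point is an independent run sharing the cached flow and steady
state, checkpointable to a .npz for resume; local maxima are detected
4-neighborhood plateau-aware (connected equal-count components greater
than all outside neighbors, reported as ranges).  The default sweep grid
(5-min steps over [−40, +90] min) spans all regimes of interest; at ~30 s
per 180-min run a 1D sweep is ~15 minutes of compute and a full 2D sweep
several hours on one CPU, so the test suite exercises sweep mechanics on
single-point and toy lattices only.

## Transient-hypoxia timing

With the default conditions (synthetic tissue, 25-min enhancer windows
starting at 5 min) the tissue-mean oxygen minimum falls essentially at the
**end of the bolus window** for both enhancers: ~30 min for the
vasodilator (supply snaps back when the window closes) and ~30.5 min for
the sensitizer (its total uptake enhancement peaks when influx stops,
since post-window spreading at fixed sensitizer mass moves material down
the concave tier ladder).  Recovery to 98% of initial oxygenation takes
~45–50 min (vasodilator) and ~1.5–2.5 h (sensitizer, whose tissue
reservoir persists because the vessel stops exchanging it).  The minimum
time is window-dominated: it is insensitive to seed, packing style and
density across everything we tested, so a reported minimum ~10 min after a
window closes implies a correspondingly later window, not a different
tissue.

## Problem sizes and numerical health

The default study tissue is ~300 cells / ~3000 boundary points; one
force solve is a dense 2M ≈ 6600 system (~10 s), the steady state ~15 s,
and one 180-min simulation 20–30 s on one CPU (numba kernels).  The test
suite exercises the full pipeline on this size once and otherwise uses
60×40 to 100×40 μm tissues with 10–40 cells.  Clamp events, solver
residuals and the uptake/accumulation flux identity are recorded in every
result's counters.

## Known limitations

* Single straight vessel on one edge; no vessel network, no 3D.
* Cells are static: no proliferation, migration, lysis or clearance of
  dead remnants; no explicit cell metabolism (sensitizer action is
  immediate).
* First-order splitting, upwinding and masked stencils: resolution-level
  accuracy near 2-μm channels is qualitative; channels narrower than the
  grid spacing carry no nodes and behave as sealed.
* Plasma pharmacokinetics are square windows; no absorption/elimination
  curves, no multi-dose schedules.
* The death model is a sharp accumulated-dose threshold shared by all
  cells; no heterogeneity in sensitivity.
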