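"""Reaction–advection–diffusion transport of oxygen, drugs and sensitizer.

Four diffusible species live on the masked grid: oxygen γ (mmHg), the
inactive pro-drug η_i, its active form η_a, and the metabolic sensitizer ξ
(all three in ag/μm³).  Each evolves by

    ∂c/∂t = D Δc − u·∇c − (reactions),

discretized with an explicit masked 4-neighbor Laplacian (stencil points
inside cells are omitted — cell interiors are impermeable), first-order
upwind advection along the precomputed Stokeslet flow, and pointwise
reaction terms, applied in that order (Lie splitting; the splitting error is
O(Δt) and Δt = 1.5×10⁻³ min).

Boundary conditions: Dirichlet on the left (vessel) edge — the vascular
value of whichever compounds are in circulation, λ-scaled while the
vasodilator is active — zero Dirichlet on the right (open tissue), no-flux
top/bottom.

Reactions: oxygen is absorbed at cell pseudo-receptors at the tiered rate
ψ(ξ, γ); the pro-drug converts to its active form only where γ ≤ γ_hyp; the
active drug is absorbed by live cells and decays with half-life 10 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import TissueDomain
from .stokes import FlowField

__all__ = [
    "ScalarField",
    "TransportParams",
    "Bolus",
    "VesselBC",
    "StabilityError",
    "masked_diffusion_step",
    "upwind_advection_step",
    "oxygen_uptake_rate",
    "activation_rate",
    "steady_state_oxygen",
    "sensitizer_step",
    "drug_step",
    "apply_vessel_boundary",
    "boundary_values",
]

#: largest stability number dt·D/h² a single unsplit 2D substep may carry
MAX_SUBSTEP_NU = 0.25


class StabilityError(ValueError):
    """Explicit step would violate its stability bound."""


@dataclass
class TransportParams:
    """Physical and numerical transport parameters (μm–min unit system).

    Defaults are the model's study conditions: oxygen diffusivity
    10³ μm²/min with the drugs slowed by their molecular size (D_γ/50
    inactive, D_γ/25 active) and the small sensitizer diffusing like oxygen;
    hypoxia threshold 10 mmHg; baseline uptake 0.85 mmHg/min with the
    sensitizer-tiered enhancement factors (1, 5/3, 7.5/3, 12.5/3) switching
    at ξ = 9, 22, 88 ag/μm³; 90% per-step pro-drug conversion in hypoxia;
    active-drug uptake 0.5/min and decay log(2)/10 per min (10-min
    half-life); Δt = 1.5×10⁻³ min.
    """

    d_gamma: float = 1.0e3            # μm²/min
    d_eta_i: float = 1.0e3 / 50.0
    d_eta_a: float = 1.0e3 / 25.0
    d_xi: float = 1.0e3
    gamma_hyp: float = 10.0           # mmHg
    gamma_0: float = 0.85             # mmHg/min
    psi: tuple = (1.0, 5.0 / 3.0, 7.5 / 3.0, 12.5 / 3.0)
    xi_tiers: tuple = (9.0, 22.0, 88.0)   # ag/μm³
    phi_conv: float = 0.9             # conversion fraction (see activation_mode)
    activation_mode: str = "per_step"  # "per_step" (0.9 of η_i each step) or
    #                                    "per_min" (continuous rate 0.9/min)
    alpha: float = 0.5                # 1/min, active-drug uptake
    omega_a: float = math.log(2.0) / 10.0  # 1/min, active-drug decay
    omega_i: float = 0.0              # optional inactive-drug interstitial decay
    dt: float = 1.5e-3                # min
    death_threshold: float = 1.0      # ag/μm³ mean accumulated concentration

    def __post_init__(self) -> None:
        for name in ("d_gamma", "d_eta_i", "d_eta_a", "d_xi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.phi_conv <= 1.0 and self.activation_mode == "per_step":
            raise ValueError("per-step conversion fraction must be in [0, 1]")
        if self.activation_mode not in ("per_step", "per_min"):
            raise ValueError(f"unknown activation_mode {self.activation_mode!r}")
        if len(self.psi) != 4 or len(self.xi_tiers) != 3:
            raise ValueError("need 4 enhancement factors and 3 tier thresholds")

    @property
    def conv_fraction(self) -> float:
        """Fraction of local η_i converted per time step while hypoxic."""
        if self.activation_mode == "per_step":
            return self.phi_conv
        return min(self.phi_conv * self.dt, 1.0)


@dataclass(frozen=True)
class Bolus:
    """One bolus window of a compound in circulation."""

    compound: str  # 'HAP' | 'Sens' | 'Vaso'
    start: float   # min
    duration: float

    def __post_init__(self) -> None:
        if self.compound not in ("HAP", "Sens", "Vaso"):
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.start < 0:
            raise ValueError("bolus start must be >= 0")
        if self.duration <= 0:
            raise ValueError("bolus duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration

    def active(self, t: float) -> bool:
        return self.start <= t <= self.end


#: plasma clearance times (min): HAP 10, sensitizer 25, vasodilator 25
DEFAULT_DURATIONS = {"HAP": 10.0, "Sens": 25.0, "Vaso": 25.0}


@dataclass
class VesselBC:
    """Vessel-edge boundary values and the active treatment windows.

    Baselines: γ^in = 60 mmHg, η_i^in = 50 ag/μm³, ξ^in = 101 ag/μm³; the
    active drug never enters from the vessel.  While the vasodilator window
    is open, every influx value and the flow magnitude are multiplied by λ
    (default 0.5, the vascular-steal flow reduction).
    """

    gamma_in: float = 60.0
    eta_i_in: float = 50.0
    xi_in: float = 101.0
    lam: float = 0.5
    boluses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"λ must be in [0, 1], got {self.lam}")
        by_compound: dict[str, list[Bolus]] = {}
        for b in self.boluses:
            by_compound.setdefault(b.compound, []).append(b)
        for compound, blist in by_compound.items():
            blist.sort(key=lambda b: b.start)
            for a, b in zip(blist, blist[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping {compound} boluses at t={a.start} and t={b.start}")

    def window(self, compound: str, t: float) -> bool:
        return any(b.compound == compound and b.active(t) for b in self.boluses)


def boundary_values(bc: VesselBC, t: float) -> tuple[float, float, float, float]:
    """Vessel-edge Dirichlet values (γ, η_i, ξ) and the flow scale at time t.

    Returns ``(gamma, eta_i, xi, flow_scale)``; the active drug's vessel
    value is always zero.
    """
    lam = bc.lam if bc.window("Vaso", t) else 1.0
    g = lam * bc.gamma_in
    ei = lam * bc.eta_i_in if bc.window("HAP", t) else 0.0
    xi = lam * bc.xi_in if bc.window("Sens", t) else 0.0
    return g, ei, xi, lam


def apply_vessel_boundary(fields: dict, bc: VesselBC, t: float,
                          domain: TissueDomain) -> dict:
    """Apply the vessel-edge condition for time t to every field.

    Oxygen always exchanges with plasma: its left column is Dirichlet at
    γ^in, λ-scaled during the vasodilator window.  A drug or the sensitizer
    is pinned (Dirichlet at its λ-scaled vascular value; zero for the active
    drug) only while its compound is in circulation; once it has cleared
    from plasma the vessel wall stops exchanging it (no-flux), so the tissue
    is not drained back through the vessel.  Outside all windows the
    boundary *values* are (γ^in, 0, 0, 0).  The right-edge zero-Dirichlet
    column is pinned for every field.
    """
    g, ei, xi, _ = boundary_values(bc, t)
    hap_on = bc.window("HAP", t)
    spec = {"oxygen": (g, True), "inactive_drug": (ei, hap_on),
            "active_drug": (0.0, hap_on), "sensitizer": (xi, bc.window("Sens", t))}
    interior = domain.interior_mask
    for name, f in fields.items():
        value, pin_left = spec[name]
        _kernels._pin_edges(f.values, interior, value, pin_left)
    return fields


@dataclass
class ScalarField:
    """One diffusible species on the masked grid."""

    name: str  # 'oxygen' | 'inactive_drug' | 'active_drug' | 'sensitizer'
    values: np.ndarray          # (n_i, n_j); zero inside cells
    diffusion: float            # μm²/min
    decay: float = 0.0          # 1/min

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def copy(self) -> "ScalarField":
        return replace(self, values=self.values.copy())

    def total_mass(self, h: float) -> float:
        return float(self.values.sum()) * h * h


def make_fields(domain: TissueDomain, params: TransportParams) -> dict:
    """Fresh zero-initialized fields for all four species."""
    z = lambda: np.zeros(domain.grid.shape)
    return {
        "oxygen": ScalarField("oxygen", z(), params.d_gamma),
        "inactive_drug": ScalarField("inactive_drug", z(), params.d_eta_i,
                                     params.omega_i),
        "active_drug": ScalarField("active_drug", z(), params.d_eta_a,
                                   params.omega_a),
        "sensitizer": ScalarField("sensitizer", z(), params.d_xi),
    }


def masked_diffusion_step(fieldc: ScalarField, domain: TissueDomain,
                          dt: float) -> ScalarField:
    """Explicit masked diffusion over one step of length ``dt``.

    In-cell stencil neighbors are omitted, so interstitial mass changes only
    through the outer domain edges (which reflect here; Dirichlet columns are
    the boundary operator's job).  The stability contract is
    ``dt·D/h² ≤ 0.5``; internally the update is substepped so each unsplit
    2D substep carries at most ν = 0.25.
    """
    h = domain.grid.h
    nu = dt * fieldc.diffusion / (h * h)
    if nu > 0.5 + 1e-12:
        raise StabilityError(
            f"diffusion stability number dt·D/h² = {nu:.3f} exceeds 0.5")
    nsub = max(1, math.ceil(nu / MAX_SUBSTEP_NU - 1e-12))
    out = fieldc.values
    for _ in range(nsub):
        out = _kernels.diffusion_substep(out, domain.interior_mask, nu / nsub)
    return replace(fieldc, values=out)


def upwind_advection_step(fieldc: ScalarField, flow: FlowField,
                          domain: TissueDomain, dt: float) -> ScalarField:
    """First-order upwind transport along the (λ-scaled) flow field."""
    h = domain.grid.h
    ux, uy = flow.scaled()
    cfl = float(max(np.abs(ux).max(), np.abs(uy).max(), 0.0)) * dt / h
    if cfl > 1.0 + 1e-12:
        raise StabilityError(f"advection CFL number {cfl:.3f} exceeds 1")
    out = _kernels.upwind_step(fieldc.values, ux, uy, domain.interior_mask, dt, h)
    return replace(fieldc, values=out)


def oxygen_uptake_rate(gamma, xi, params: TransportParams):
    """Cellular oxygen uptake ψ(ξ, γ) in mmHg/min (per covering receptor).

    Under severe hypoxia (γ < 0.5·γ_hyp) the rate ramps linearly to zero
    with the remaining oxygen, joining the baseline γ_0 continuously at the
    branch point; otherwise it is the tiered constant γ_0·ψ_k with the tier
    picked by the local sensitizer concentration (ψ_0 = 1 covers ξ = 0).
    A continuous ramp keeps the oxygen steady state unique — a rate that
    jumps at the branch point makes deep tissue bistable and the
    post-transient field would never return to its initial gradient.
    """
    gamma = np.asarray(gamma, dtype=float)
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(params.psi)
    tier = np.digitize(xi, params.xi_tiers)
    enhanced = params.gamma_0 * psi[tier]
    ramp = params.gamma_0 * gamma / (0.5 * params.gamma_hyp)
    return np.where(gamma < 0.5 * params.gamma_hyp, ramp, enhanced)[()]


def activation_rate(gamma, params: TransportParams):
    """Per-step conversion fraction: φ^conv where γ ≤ γ_hyp (inclusive), else 0."""
    gamma = np.asarray(gamma, dtype=float)
    return np.where(gamma <= params.gamma_hyp, params.conv_fraction, 0.0)[()]


def steady_state_oxygen(
    domain: TissueDomain,
    flow: FlowField,
    params: TransportParams,
    bc: VesselBC,
    tol: float = 1e-10,
    max_iter: int = 2_000_000,
    alive: np.ndarray | None = None,
) -> ScalarField:
    """Stationary oxygen gradient used as the initial condition of every run.

    Iterates the drug-free oxygen update (no sensitizer) until
    ``||γⁿ − γⁿ⁻¹||₂ / (N_i·N_j) < tol``.  ``alive`` restricts the uptake to
    the flagged cells (default: all cells alive).
    """
    g0 = np.full(domain.grid.shape, bc.gamma_in, dtype=float)
    g0[domain.interior_mask] = 0.0
    ux, uy = flow.scaled()
    cover = domain.cover_count(alive=alive)
    zeros = np.zeros_like(g0)
    g, n_iter, res = _kernels.steady_oxygen(
        g0, zeros, domain.interior_mask, ux, uy, cover,
        params.d_gamma, params.dt, domain.grid.h, bc.gamma_in,
        params.gamma_hyp, params.gamma_0, np.asarray(params.psi, dtype=float),
        np.asarray(params.xi_tiers, dtype=float), tol, max_iter)
    if res >= tol:
        raise RuntimeError(
            f"steady-state oxygen did not converge in {max_iter} iterations "
            f"(residual {res:.3e})")
    return ScalarField("oxygen", g, params.d_gamma)


def sensitizer_step(xi: ScalarField, flow: FlowField, domain: TissueDomain,
                    dt: float, influx: float | None = None) -> ScalarField:
    """Sensitizer transport: diffusion + advection only (no uptake, no decay).

    ``influx`` is the vessel Dirichlet value during the bolus window
    (λ-scaled if the vasodilator is active); ``None`` means the sensitizer
    has cleared from plasma and the vessel edge is no-flux.
    """
    h = domain.grid.h
    ux, uy = flow.scaled()
    out = _kernels.passive_step(xi.values, domain.interior_mask, ux, uy,
                                xi.diffusion, dt, h,
                                0.0 if influx is None else float(influx),
                                influx is not None)
    return replace(xi, values=out)


def drug_step(
    eta_i: ScalarField,
    eta_a: ScalarField,
    oxygen: ScalarField,
    flow: FlowField,
    domain: TissueDomain,
    cells,
    params: TransportParams,
    dt: float,
    influx: float | None = None,
) -> tuple[ScalarField, ScalarField, dict]:
    """Advance the drug pair one step: transport, activation, uptake, decay.

    Activation transfers mass exactly (η_i's loss is η_a's gain, node by
    node, before uptake/decay).  Uptake acts only through live cells'
    receptors; ``cells`` is the pharmacodynamics CellStateArray (or None for
    a cell-free step).  ``influx`` is the inactive drug's vessel Dirichlet
    value during the HAP window, ``None`` once it has cleared from plasma
    (no vessel exchange).  Returns the new fields and a bookkeeping dict
    with ``uptake_removed``, ``accum_gained`` and ``clamped`` counts.
    """
    h = domain.grid.h
    ux, uy = flow.scaled()
    interior = domain.interior_mask
    pin = influx is not None
    ei = _kernels.passive_step(eta_i.values, interior, ux, uy,
                               eta_i.diffusion, dt, h,
                               0.0 if influx is None else float(influx), pin)
    ea = _kernels.passive_step(eta_a.values, interior, ux, uy,
                               eta_a.diffusion, dt, h, 0.0, pin)
    _kernels.activation_stage(ei, ea, oxygen.values, interior,
                              params.conv_fraction, params.gamma_hyp)
    gained = 0.0
    if cells is not None:
        ptr, nodes, mult = domain.cover_arrays()
        before = cells.accumulated.sum()
        _kernels.accumulate_cells(ea, ptr, nodes, mult, cells.alive,
                                  cells.accumulated, params.alpha, dt)
        gained = cells.accumulated.sum() - before
        cover = cells.live_cover(domain)
    else:
        cover = np.zeros_like(ei)
    clamped, removed = _kernels.uptake_decay_stage(
        ei, ea, interior, cover, params.alpha, params.omega_a, params.omega_i, dt)
    book = {"uptake_removed": removed * h * h, "accum_gained": gained * h * h,
            "clamped": clamped}
    return replace(eta_i, values=ei), replace(eta_a, values=ea), book
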