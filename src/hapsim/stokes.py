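"""Interstitial flow by the method of regularized Stokeslets.

The interstitial fluid obeys the Stokes equations (Re ≪ 1 at cell scale).
Point forces smoothed over a disk of radius ε (the cutoff φ_ε) are placed on
the vessel face (imposed influx velocity u_in), on the top/bottom walls and
on every cell boundary point (no-slip).  Inverting the resulting mobility
system for the forces and re-summing the kernel gives the velocity anywhere
in the domain.  The field is time-invariant (cells are non-motile); the
vasodilator only rescales its magnitude by λ.

Internal units are μm and minutes throughout (μ in mg/(μm·min), velocities
in μm/min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import lu_factor, lu_solve, lstsq
from scipy.sparse.linalg import LinearOperator, gmres

from . import _kernels
from .geometry import TissueDomain

__all__ = [
    "StokesletSystem",
    "FlowField",
    "SolverError",
    "cutoff_phi",
    "stokeslet_velocity",
    "build_stokeslet_system",
    "solve_boundary_forces",
    "compute_velocity_field",
    "scale_flow",
]

log = logging.getLogger(__name__)

#: Fluid viscosity, mg/(μm·min) — water at body temperature.
DEFAULT_MU = 0.04
#: Vessel influx speed, μm/min.  The default keeps the compound transport in
#: the diffusion-dominated regime (domain Péclet ≈ 0.2) that matches the slow
#: multi-hour interstitial penetration and clearance this model represents;
#: see docs/methods.md for the regime analysis and the faster alternative.
DEFAULT_U_IN = 1.0

# point labels
VESSEL, WALL, CELL = 0, 1, 2


class SolverError(RuntimeError):
    """Force solve failed the boundary-velocity residual contract."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        super().__init__(
            f"boundary force solve residual {residual:.3e} exceeds tol {tol:.3e}")


@dataclass
class StokesletSystem:
    """Force points, imposed velocities and (after solving) the forces."""

    points: np.ndarray          # (M, 2) μm
    imposed_u: np.ndarray       # (M, 2) μm/min
    mu: float = DEFAULT_MU
    epsilon: float = 2.0
    labels: np.ndarray = None   # (M,) int: VESSEL / WALL / CELL
    forces: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.imposed_u = np.asarray(self.imposed_u, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (M, 2)")
        if self.points.shape != self.imposed_u.shape:
            raise ValueError("points and imposed_u shapes differ")
        if len(self.points) < 1:
            raise ValueError("need at least one force point")
        if self.mu <= 0 or self.epsilon <= 0:
            raise ValueError("mu and epsilon must be positive")
        if self.labels is None:
            self.labels = np.full(len(self.points), CELL, dtype=int)

    @property
    def n_points(self) -> int:
        return len(self.points)


def cutoff_phi(r, epsilon: float):
    """Regularization cutoff φ_ε(r) = 2ε⁴ / (π (r² + ε²)³), 1/μm².

    Strictly decreasing in r and normalized to unit integral over the plane.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = np.asarray(r, dtype=float)
    return 2.0 * epsilon ** 4 / (np.pi * (r ** 2 + epsilon ** 2) ** 3)


def stokeslet_velocity(x, system: StokesletSystem) -> np.ndarray:
    """Velocity at point(s) ``x`` from the system's regularized forces.

    u(x) = (1/4πμ) Σ_k [ (2ε²/(r²+ε²) − ln(r²+ε²)) f_k
                         + (f_k·(x−x_k)) (x−x_k) / (r²+ε²) ]

    The kernel is regular at r = 0 (value (2 − ln ε²)/(4πμ) · f).
    """
    if system.forces is None:
        raise ValueError("forces not solved yet")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = _kernels.stokeslet_sum(x, system.points, system.forces,
                                 system.mu, system.epsilon)
    return out[0] if out.shape[0] == 1 else out


def build_stokeslet_system(
    domain: TissueDomain,
    u_in: float = DEFAULT_U_IN,
    mu: float = DEFAULT_MU,
) -> StokesletSystem:
    """Place force points on the vessel face, the walls and all cell contours.

    Vessel points run along the left edge at spacing ε with imposed velocity
    (u_in, 0); wall points along the top/bottom edges at spacing ε with zero
    velocity; corner points are deduplicated and assigned to the walls.  Cell
    boundary points carry zero velocity.  The right edge is an open outflow
    and carries no constraint.
    """
    g, eps = domain.grid, domain.epsilon
    pts, vels, labs = [], [], []
    # walls (own the corners)
    xw = np.arange(g.x_min, g.x_max + 0.5 * eps, eps)
    for x in xw:
        pts.append((x, g.y_min)); vels.append((0.0, 0.0)); labs.append(WALL)
        pts.append((x, g.y_max)); vels.append((0.0, 0.0)); labs.append(WALL)
    # vessel face, corners excluded
    yv = np.arange(g.y_min + eps, g.y_max - 0.5 * eps, eps)
    for y in yv:
        pts.append((g.x_min, y)); vels.append((u_in, 0.0)); labs.append(VESSEL)
    # cell pseudo-receptors
    for cell in domain.cells:
        for (x, y) in cell.boundary_points:
            pts.append((x, y)); vels.append((0.0, 0.0)); labs.append(CELL)
    return StokesletSystem(points=np.array(pts), imposed_u=np.array(vels),
                           mu=mu, epsilon=eps, labels=np.array(labs))


def solve_boundary_forces(
    system: StokesletSystem,
    tol: float = 1e-8,
    method: str = "auto",
    max_gmres_iter: int = 2000,
) -> StokesletSystem:
    """Invert the mobility system for the boundary forces.

    The promise is the residual: after solving, re-evaluating the velocity at
    every constraint point reproduces its imposed value with relative residual
    ≤ ``tol`` (relative to the largest imposed speed, or absolute if all
    imposed velocities vanish).  ``method``: 'direct' (dense LU, default for
    2M ≤ 12000), 'gmres', or 'auto'.
    """
    m2 = 2 * system.n_points
    a = _kernels.stokeslet_matrix(system.points, system.mu, system.epsilon)
    b = system.imposed_u.ravel()
    if method == "auto":
        method = "direct" if m2 <= 12000 else "gmres"
    if not b.any():
        f = np.zeros(m2)
    elif method == "direct":
        try:
            f = lu_solve(lu_factor(a), b)
        except np.linalg.LinAlgError:
            f = lstsq(a, b)[0]
    elif method == "gmres":
        op = LinearOperator((m2, m2), matvec=lambda v: a @ v)
        f, info = gmres(op, b, rtol=min(tol * 1e-2, 1e-10), atol=0.0,
                        restart=300, maxiter=max_gmres_iter)
        if info != 0:
            # fall back to the dense factorization rather than give up
            log.warning("GMRES did not converge (info=%s); dense fallback", info)
            f = lu_solve(lu_factor(a), b)
    else:
        raise ValueError(f"unknown method {method!r}")

    resid_vec = (a @ f - b).reshape(-1, 2)
    scale = float(np.linalg.norm(system.imposed_u, axis=1).max())
    resid = float(np.linalg.norm(resid_vec, axis=1).max())
    if scale > 0:
        resid /= scale
    if resid > tol:
        raise SolverError(resid, tol)
    system.forces = f.reshape(-1, 2)
    log.info("force solve: M=%d, residual %.2e", system.n_points, resid)
    return system


@dataclass
class FlowField:
    """Interstitial velocity at every grid node (zero reported inside cells).

    ``scale`` is the vasodilator factor λ: by Stokes linearity the modulated
    field is exactly λ times the baseline.
    """

    ux: np.ndarray  # (n_i, n_j) μm/min at scale=1
    uy: np.ndarray
    scale: float = 1.0

    def scaled(self) -> tuple[np.ndarray, np.ndarray]:
        return self.ux * self.scale, self.uy * self.scale

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy) * self.scale


def compute_velocity_field(domain: TissueDomain, system: StokesletSystem) -> FlowField:
    """Evaluate the Stokeslet sum once at every interstitial grid node.

    In-cell nodes carry exactly zero velocity in the returned field (they are
    masked out of transport).  The field is cached by the caller — geometry is
    static, so it never needs recomputation.
    """
    if system.forces is None:
        raise ValueError("solve_boundary_forces first")
    g = domain.grid
    xs, ys = g.node_x(), g.node_y()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    open_nodes = ~domain.interior_mask
    targets = np.column_stack([gx[open_nodes], gy[open_nodes]])
    ux = np.zeros(g.shape)
    uy = np.zeros(g.shape)
    if len(targets):
        u = _kernels.stokeslet_sum(targets, system.points, system.forces,
                                   system.mu, system.epsilon)
        ux[open_nodes] = u[:, 0]
        uy[open_nodes] = u[:, 1]
    return FlowField(ux=ux, uy=uy)


def scale_flow(fieldv: FlowField, lam: float) -> FlowField:
    """Vasodilator modulation u → λ·u; λ must lie in [0, 1] (λ=1 baseline)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"flow scale λ must be in [0, 1], got {lam}")
    return replace(fieldv, scale=lam)
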