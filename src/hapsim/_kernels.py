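"""Numba kernels for the hot loops: Stokeslet sums and masked transport steps.

Everything here operates on plain float64/int64/bool arrays; the friendly
dataclass surfaces live in the sibling modules.  Kernels are deterministic
and single-threaded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Regularized Stokeslets
# ---------------------------------------------------------------------------


@njit(cache=True)
def stokeslet_matrix(points: np.ndarray, mu: float, eps: float) -> np.ndarray:
    """Dense 2M×2M mobility matrix A with u = A f (interleaved x/y components)."""
    m = points.shape[0]
    a = np.empty((2 * m, 2 * m))
    e2 = eps * eps
    c = 1.0 / (4.0 * np.pi * mu)
    for p in range(m):
        xp = points[p, 0]
        yp = points[p, 1]
        for q in range(m):
            dx = xp - points[q, 0]
            dy = yp - points[q, 1]
            r2e = dx * dx + dy * dy + e2
            diag = c * (2.0 * e2 / r2e - np.log(r2e))
            w = c / r2e
            a[2 * p, 2 * q] = diag + w * dx * dx
            a[2 * p, 2 * q + 1] = w * dx * dy
            a[2 * p + 1, 2 * q] = w * dy * dx
            a[2 * p + 1, 2 * q + 1] = diag + w * dy * dy
    return a


@njit(cache=True)
def stokeslet_sum(targets: np.ndarray, points: np.ndarray, forces: np.ndarray,
                  mu: float, eps: float) -> np.ndarray:
    """Velocity at each target from all regularized point forces."""
    n = targets.shape[0]
    m = points.shape[0]
    out = np.zeros((n, 2))
    e2 = eps * eps
    c = 1.0 / (4.0 * np.pi * mu)
    for t in range(n):
        xt = targets[t, 0]
        yt = targets[t, 1]
        ux = 0.0
        uy = 0.0
        for k in range(m):
            dx = xt - points[k, 0]
            dy = yt - points[k, 1]
            r2e = dx * dx + dy * dy + e2
            diag = 2.0 * e2 / r2e - np.log(r2e)
            fd = (forces[k, 0] * dx + forces[k, 1] * dy) / r2e
            ux += diag * forces[k, 0] + fd * dx
            uy += diag * forces[k, 1] + fd * dy
        out[t, 0] = c * ux
        out[t, 1] = c * uy
    return out


# ---------------------------------------------------------------------------
# Masked transport steps
# ---------------------------------------------------------------------------


@njit(cache=True)
def diffusion_substep(c: np.ndarray, interior: np.ndarray, nu: float) -> np.ndarray:
    """One explicit masked 4-neighbor diffusion substep (no-flux outer edges).

    Neighbors inside cells are omitted from the stencil entirely, so the cell
    interiors are impermeable and interstitial mass is conserved exactly when
    all outer edges reflect.
    """
    nx, ny = c.shape
    out = np.zeros_like(c)
    for i in range(nx):
        for j in range(ny):
            if interior[i, j]:
                continue
            v = c[i, j]
            acc = 0.0
            if i > 0 and not interior[i - 1, j]:
                acc += c[i - 1, j] - v
            if i < nx - 1 and not interior[i + 1, j]:
                acc += c[i + 1, j] - v
            if j > 0 and not interior[i, j - 1]:
                acc += c[i, j - 1] - v
            if j < ny - 1 and not interior[i, j + 1]:
                acc += c[i, j + 1] - v
            out[i, j] = v + nu * acc
    return out


@njit(cache=True)
def upwind_step(c: np.ndarray, ux: np.ndarray, uy: np.ndarray,
                interior: np.ndarray, dt: float, h: float) -> np.ndarray:
    """First-order upwind advection step; in-cell or off-grid upwind neighbors
    contribute zero gradient (no transport across cell boundaries)."""
    nx, ny = c.shape
    out = np.zeros_like(c)
    for i in range(nx):
        for j in range(ny):
            if interior[i, j]:
                continue
            v = c[i, j]
            u = ux[i, j]
            w = uy[i, j]
            dcdx = 0.0
            if u > 0.0:
                if i > 0 and not interior[i - 1, j]:
                    dcdx = (v - c[i - 1, j]) / h
            elif u < 0.0:
                if i < nx - 1 and not interior[i + 1, j]:
                    dcdx = (c[i + 1, j] - v) / h
            dcdy = 0.0
            if w > 0.0:
                if j > 0 and not interior[i, j - 1]:
                    dcdy = (v - c[i, j - 1]) / h
            elif w < 0.0:
                if j < ny - 1 and not interior[i, j + 1]:
                    dcdy = (c[i, j + 1] - v) / h
            out[i, j] = v - dt * (u * dcdx + w * dcdy)
    return out


@njit(cache=True)
def _pin_edges(c: np.ndarray, interior: np.ndarray, left_value: float,
               pin_left: bool) -> None:
    """Right edge: zero Dirichlet (open tissue).  Left (vessel) edge: Dirichlet
    at ``left_value`` only while the compound exchanges with plasma
    (``pin_left``); otherwise the vessel wall is a no-flux boundary — a
    compound that has cleared from circulation is not drained back out."""
    nx, ny = c.shape
    for j in range(ny):
        if pin_left and not interior[0, j]:
            c[0, j] = left_value
        if not interior[nx - 1, j]:
            c[nx - 1, j] = 0.0


@njit(cache=True)
def _diffuse(c: np.ndarray, interior: np.ndarray, d: float, dt: float, h: float,
             left_value: float, pin_left: bool) -> np.ndarray:
    """Masked diffusion over one transport step, substepped so that each
    substep satisfies nu <= 0.25 (the unsplit 2D positivity/stability bound).
    Dirichlet edges re-pinned after every substep."""
    nu = dt * d / (h * h)
    nsub = int(np.ceil(nu / 0.25 - 1e-12))
    if nsub < 1:
        nsub = 1
    out = c
    for _ in range(nsub):
        out = diffusion_substep(out, interior, nu / nsub)
        _pin_edges(out, interior, left_value, pin_left)
    return out


@njit(cache=True)
def uptake_psi(gamma: float, xi: float, gamma_hyp: float, gamma_0: float,
               psi: np.ndarray, xi_tiers: np.ndarray) -> float:
    """Oxygen uptake rate (mmHg/min): below the severe-hypoxia level
    (0.5·γ_hyp) the rate ramps linearly to zero with the remaining oxygen,
    matching the baseline γ_0 continuously at the branch point; above it the
    rate is the sensitizer-tiered constant γ_0·ψ_k."""
    if gamma < 0.5 * gamma_hyp:
        return gamma_0 * gamma / (0.5 * gamma_hyp)
    if xi < xi_tiers[0]:
        return gamma_0 * psi[0]
    if xi < xi_tiers[1]:
        return gamma_0 * psi[1]
    if xi < xi_tiers[2]:
        return gamma_0 * psi[2]
    return gamma_0 * psi[3]


@njit(cache=True)
def oxygen_step(gamma: np.ndarray, xi: np.ndarray, interior: np.ndarray,
                ux: np.ndarray, uy: np.ndarray, cover: np.ndarray,
                d_gamma: float, dt: float, h: float, bc_gamma: float,
                gamma_hyp: float, gamma_0: float,
                psi: np.ndarray, xi_tiers: np.ndarray) -> tuple:
    """One full oxygen update: diffusion -> advection -> receptor uptake.

    Returns (field, n_clamped).  Uptake acts at nodes covered by live-cell
    receptors, once per covering receptor point.
    """
    nx, ny = gamma.shape
    g = _diffuse(gamma, interior, d_gamma, dt, h, bc_gamma, True)
    g = upwind_step(g, ux, uy, interior, dt, h)
    _pin_edges(g, interior, bc_gamma, True)
    clamped = 0
    for i in range(1, nx - 1):
        for j in range(ny):
            if interior[i, j]:
                continue
            cov = cover[i, j]
            if cov > 0.0:
                rate = uptake_psi(g[i, j], xi[i, j], gamma_hyp, gamma_0, psi, xi_tiers)
                g[i, j] -= dt * rate * cov
                if g[i, j] < 0.0:
                    g[i, j] = 0.0
                    clamped += 1
    return g, clamped


@njit(cache=True)
def passive_step(c: np.ndarray, interior: np.ndarray, ux: np.ndarray,
                 uy: np.ndarray, d: float, dt: float, h: float,
                 bc_left: float, pin_left: bool) -> np.ndarray:
    """Diffusion + advection only (the sensitizer has no uptake or decay).
    ``pin_left`` is True while the compound is in circulation (vessel
    Dirichlet); False once it has cleared (no vessel exchange)."""
    out = _diffuse(c, interior, d, dt, h, bc_left, pin_left)
    out = upwind_step(out, ux, uy, interior, dt, h)
    _pin_edges(out, interior, bc_left, pin_left)
    return out


@njit(cache=True)
def steady_oxygen(gamma: np.ndarray, xi: np.ndarray, interior: np.ndarray,
                  ux: np.ndarray, uy: np.ndarray, cover: np.ndarray,
                  d_gamma: float, dt: float, h: float, bc_gamma: float,
                  gamma_hyp: float, gamma_0: float, psi: np.ndarray,
                  xi_tiers: np.ndarray, tol: float, max_iter: int) -> tuple:
    """Iterate the oxygen update to the stationary gradient.

    Convergence criterion: ||γ^n − γ^{n−1}||_2 / (N_i·N_j) < tol between
    consecutive iterations.  Returns (field, n_iter, residual).
    """
    n_nodes = gamma.shape[0] * gamma.shape[1]
    res = np.inf
    it = 0
    g = gamma.copy()
    _pin_edges(g, interior, bc_gamma, True)
    while it < max_iter:
        g_new, _ = oxygen_step(g, xi, interior, ux, uy, cover, d_gamma, dt, h,
                               bc_gamma, gamma_hyp, gamma_0, psi, xi_tiers)
        s = 0.0
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                d2 = g_new[i, j] - g[i, j]
                s += d2 * d2
        res = np.sqrt(s) / n_nodes
        g = g_new
        it += 1
        if res < tol:
            break
    return g, it, res


@njit(cache=True)
def activation_stage(eta_i: np.ndarray, eta_a: np.ndarray, gamma: np.ndarray,
                     interior: np.ndarray, conv_frac: float,
                     gamma_hyp: float) -> float:
    """Hypoxia-gated activation: move ``conv_frac``·η_i from the inactive to
    the active pool at every interstitial node with γ <= γ_hyp.  The transfer
    is mass-exact by construction.  Returns the total converted amount."""
    nx, ny = eta_i.shape
    converted = 0.0
    for i in range(1, nx - 1):
        for j in range(ny):
            if interior[i, j]:
                continue
            if gamma[i, j] <= gamma_hyp:
                moved = conv_frac * eta_i[i, j]
                eta_i[i, j] -= moved
                eta_a[i, j] += moved
                converted += moved
    return converted


@njit(cache=True)
def uptake_decay_stage(eta_i: np.ndarray, eta_a: np.ndarray,
                       interior: np.ndarray, cover: np.ndarray, alpha: float,
                       omega_a: float, omega_i: float, dt: float) -> tuple:
    """Receptor-localized uptake of the active drug plus decay terms.

    Must run on the same η_a the per-cell accumulators saw, so node removal
    (dt·α·η_a·cover) and cell gain are two views of one flux.  Returns
    (n_clamped, uptake_removed_total).
    """
    nx, ny = eta_i.shape
    clamped = 0
    removed = 0.0
    for i in range(1, nx - 1):
        for j in range(ny):
            if interior[i, j]:
                continue
            if omega_i > 0.0:
                eta_i[i, j] -= dt * omega_i * eta_i[i, j]
            cov = cover[i, j]
            if cov > 0.0:
                take = dt * alpha * eta_a[i, j] * cov
                eta_a[i, j] -= take
                removed += take
            eta_a[i, j] -= dt * omega_a * eta_a[i, j]
            if eta_i[i, j] < 0.0:
                eta_i[i, j] = 0.0
                clamped += 1
            if eta_a[i, j] < 0.0:
                eta_a[i, j] = 0.0
                clamped += 1
    return clamped, removed


@njit(cache=True)
def accumulate_cells(eta_a: np.ndarray, ptr: np.ndarray, nodes: np.ndarray,
                     mult: np.ndarray, alive: np.ndarray, accum: np.ndarray,
                     alpha: float, dt: float) -> None:
    """Per-cell active-drug accumulation: Γ_l += dt·α·Σ_receptor-nodes η_a·mult.

    Must be called on the pre-uptake η_a so the node-level removal and the
    cell-level gain are two views of the same flux.
    """
    flat = eta_a.ravel()
    for l in range(alive.shape[0]):
        if not alive[l]:
            continue
        s = 0.0
        for k in range(ptr[l], ptr[l + 1]):
            s += flat[nodes[k]] * mult[k]
        accum[l] += dt * alpha * s


@njit(cache=True)
def apply_deaths(accum: np.ndarray, norm: np.ndarray, alive: np.ndarray,
                 death_time: np.ndarray, ptr: np.ndarray, nodes: np.ndarray,
                 mult: np.ndarray, cover_flat: np.ndarray, threshold: float,
                 t: float) -> int:
    """Kill cells whose area-normalized accumulation reached the lethal
    threshold (inclusive >=); remove their receptors from the live coverage."""
    n_new = 0
    for l in range(alive.shape[0]):
        if alive[l] and accum[l] * norm[l] >= threshold:
            alive[l] = False
            death_time[l] = t
            for k in range(ptr[l], ptr[l + 1]):
                cover_flat[nodes[k]] -= mult[k]
            n_new += 1
    return n_new


@njit(cache=True)
def masked_mean(c: np.ndarray, interior: np.ndarray) -> float:
    s = 0.0
    n = 0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            if not interior[i, j]:
                s += c[i, j]
                n += 1
    if n == 0:
        return np.nan
    return s / n


@njit(cache=True)
def column_means(c: np.ndarray, interior: np.ndarray) -> np.ndarray:
    """Per-column mean over interstitial nodes; NaN for all-interior columns."""
    nx, ny = c.shape
    out = np.empty(nx)
    for i in range(nx):
        s = 0.0
        n = 0
        for j in range(ny):
            if not interior[i, j]:
                s += c[i, j]
                n += 1
        out[i] = s / n if n > 0 else np.nan
    return out


@njit(cache=True)
def run_segment(gamma, eta_i, eta_a, xi, interior, ux, uy, cover,
                ptr, nodes, mult, alive, accum, death_time, norm,
                d_gamma, d_eta_i, d_eta_a, d_xi,
                dt, h, bc_gamma, bc_eta_i, bc_xi,
                gamma_hyp, gamma_0, psi, xi_tiers,
                conv_frac, alpha, omega_a, omega_i, threshold,
                drugs_on, sens_on, pin_ei, pin_xi, n_steps, step0, t0,
                rec_stride, rec_t, rec_mean_gamma, rec_ndead, rec_cols,
                counters):
    """Advance all active fields ``n_steps`` steps under constant boundary
    values (one schedule segment).  Mutates the fields and cell-state arrays
    in place and fills the record arrays at every ``rec_stride``-th global
    step.  ``counters``: [clamp_events, node_step_count, uptake_removed,
    accum_gained] (running totals across segments)."""
    n_dead = 0
    for l in range(alive.shape[0]):
        if not alive[l]:
            n_dead += 1
    cover_flat = cover.ravel()
    for s in range(n_steps):
        t = t0 + (s + 1) * dt
        g, cl = oxygen_step(gamma, xi, interior, ux, uy, cover, d_gamma, dt, h,
                            bc_gamma, gamma_hyp, gamma_0, psi, xi_tiers)
        gamma[:, :] = g
        counters[0] += cl
        counters[1] += gamma.shape[0] * gamma.shape[1]
        if sens_on:
            xi[:, :] = passive_step(xi, interior, ux, uy, d_xi, dt, h, bc_xi,
                                    pin_xi)
            counters[1] += xi.shape[0] * xi.shape[1]
        if drugs_on:
            eta_i[:, :] = passive_step(eta_i, interior, ux, uy, d_eta_i, dt, h,
                                       bc_eta_i, pin_ei)
            eta_a[:, :] = passive_step(eta_a, interior, ux, uy, d_eta_a, dt, h,
                                       0.0, pin_ei)
            activation_stage(eta_i, eta_a, gamma, interior, conv_frac,
                             gamma_hyp)
            # accumulation must see the post-activation, pre-uptake η_a
            a0 = accum.sum()
            accumulate_cells(eta_a, ptr, nodes, mult, alive, accum, alpha, dt)
            counters[3] += accum.sum() - a0
            cl, removed = uptake_decay_stage(eta_i, eta_a, interior, cover,
                                             alpha, omega_a, omega_i, dt)
            counters[0] += cl
            counters[1] += 2 * eta_i.shape[0] * eta_i.shape[1]
            counters[2] += removed
            n_dead += apply_deaths(accum, norm, alive, death_time, ptr, nodes,
                                   mult, cover_flat, threshold, t)
        gstep = step0 + s + 1
        if rec_stride > 0 and gstep % rec_stride == 0:
            k = gstep // rec_stride
            if k < rec_t.shape[0]:
                rec_t[k] = t
                rec_mean_gamma[k] = masked_mean(gamma, interior)
                rec_ndead[k] = n_dead
                rec_cols[k, :] = column_means(gamma, interior)
    return n_dead
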