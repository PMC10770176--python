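"""Treatment schedules, full simulations, outcome metrics and offset sweeps.

A treatment schedule is at most one bolus per compound (HAP, sensitizer,
vasodilator) over a 3-hour horizon.  ``run_simulation`` advances the coupled
system — vessel boundary → transport → reactions → cell death — at the
model time step from the precomputed steady oxygen gradient, recording the
dead-cell count, the tissue-mean oxygenation and the normoxia/hypoxia
border over time.  ``sweep_offsets`` reruns the simulation over a lattice of
enhancer injection offsets relative to the HAP injection and locates the
local maxima of the dead-cell landscape.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import TissueDomain
from .pharmacodynamics import CellStateArray, make_cell_states
from .stokes import FlowField
from .transport import (Bolus, DEFAULT_DURATIONS, ScalarField, TransportParams,
                        VesselBC, boundary_values, steady_state_oxygen)

__all__ = [
    "Bolus",
    "TreatmentSchedule",
    "SimulationResult",
    "SweepResult",
    "run_simulation",
    "hypoxia_border",
    "strip_average_profile",
    "sweep_offsets",
    "find_local_maxima",
]

log = logging.getLogger(__name__)


@dataclass
class TreatmentSchedule:
    """Bolus windows (at most one per compound) and the simulation horizon."""

    boluses: list = field(default_factory=list)
    t_end: float = 180.0

    def __post_init__(self) -> None:
        compounds = [b.compound for b in self.boluses]
        if len(compounds) != len(set(compounds)):
            raise ValueError("at most one bolus per compound")
        for b in self.boluses:
            if b.end > self.t_end:
                raise ValueError(
                    f"{b.compound} window [{b.start}, {b.end}] exceeds horizon "
                    f"{self.t_end}")

    @classmethod
    def single(cls, compound: str, start: float, duration: float | None = None,
               t_end: float = 180.0) -> "TreatmentSchedule":
        duration = DEFAULT_DURATIONS[compound] if duration is None else duration
        return cls([Bolus(compound, start, duration)], t_end)

    def bolus(self, compound: str) -> Bolus | None:
        for b in self.boluses:
            if b.compound == compound:
                return b
        return None

    def event_times(self) -> list[float]:
        times = {0.0, self.t_end}
        for b in self.boluses:
            times.add(b.start)
            times.add(b.end)
        return sorted(t for t in times if 0.0 <= t <= self.t_end)


@dataclass
class SimulationResult:
    """Time series and end-state of one treatment simulation."""

    times: np.ndarray            # record times (min)
    n_dead: np.ndarray           # dead-cell count trace
    mean_oxygen: np.ndarray      # tissue-mean oxygen (mmHg), interstitial nodes
    border: np.ndarray           # normoxia/hypoxia border distance (μm)
    oxygen_columns: np.ndarray   # (n_rec, n_i) strip-averaged oxygen
    cells: CellStateArray
    fields: dict                 # final ScalarFields
    snapshots: dict = field(default_factory=dict)  # t -> {name: array}
    counters: dict = field(default_factory=dict)   # numerical-health counters
    schedule: TreatmentSchedule | None = None

    @property
    def dead_count(self) -> int:
        return int(self.n_dead[-1])

    @property
    def dead_fraction(self) -> float:
        n = self.cells.n_cells
        return self.dead_count / n if n else 0.0


def hypoxia_border(oxygen: ScalarField | np.ndarray, domain: TissueDomain,
                   gamma_hyp: float = 10.0) -> float:
    """Distance from the vessel at which strip-averaged oxygen first drops
    below γ_hyp; the domain length if no column qualifies."""
    values = oxygen.values if isinstance(oxygen, ScalarField) else np.asarray(oxygen)
    g = domain.grid
    if values.ndim == 2:
        cols = _kernels.column_means(values, domain.interior_mask)
    else:
        cols = values
    return _border_from_columns(cols, g.h, g.x_max - g.x_min, gamma_hyp)


def _border_from_columns(cols: np.ndarray, h: float, length: float,
                         gamma_hyp: float = 10.0) -> float:
    """First column (vessel-relative x) whose strip average is hypoxic;
    NaN columns (no interstitial node) are skipped."""
    hits = np.where(~np.isnan(cols) & (cols < gamma_hyp))[0]
    return float(hits[0] * h) if len(hits) else float(length)


def strip_average_profile(fieldc: ScalarField | np.ndarray,
                          domain: TissueDomain) -> np.ndarray:
    """Per-column mean over interstitial nodes only (NaN where a column has
    no interstitial node — missing, not zero)."""
    values = fieldc.values if isinstance(fieldc, ScalarField) else np.asarray(fieldc)
    return _kernels.column_means(values, domain.interior_mask)


def run_simulation(
    domain: TissueDomain,
    schedule: TreatmentSchedule,
    params: TransportParams | None = None,
    bc: VesselBC | None = None,
    flow: FlowField | None = None,
    oxygen0: ScalarField | None = None,
    record_dt: float = 0.5,
    snapshot_times: tuple = (),
) -> SimulationResult:
    """Run one full treatment simulation.

    ``flow`` and ``oxygen0`` (the solved interstitial flow and the stationary
    oxygen gradient) may be precomputed once per geometry and shared between
    runs — both are schedule-independent.  The dynamics are fully
    deterministic given the inputs.
    """
    params = params or TransportParams()
    bc = bc or VesselBC()
    bc = VesselBC(gamma_in=bc.gamma_in, eta_i_in=bc.eta_i_in, xi_in=bc.xi_in,
                  lam=bc.lam, boluses=list(schedule.boluses))
    if flow is None:
        from .stokes import build_stokeslet_system, solve_boundary_forces, \
            compute_velocity_field
        system = solve_boundary_forces(build_stokeslet_system(domain))
        flow = compute_velocity_field(domain, system)
    if oxygen0 is None:
        oxygen0 = steady_state_oxygen(domain, flow, params, bc)

    g = domain.grid
    dt = params.dt
    n_steps_total = int(round(schedule.t_end / dt))
    rec_stride = max(1, int(round(record_dt / dt)))
    n_rec = n_steps_total // rec_stride + 1

    gamma = oxygen0.values.copy()
    eta_i = np.zeros(g.shape)
    eta_a = np.zeros(g.shape)
    xi = np.zeros(g.shape)
    cells = make_cell_states(domain)
    ptr, nodes, mult = domain.cover_arrays()
    cover = domain.cover_count()
    norm = cells.norm if cells.n_cells else np.zeros(0)

    rec_t = np.full(n_rec, np.nan)
    rec_mean = np.full(n_rec, np.nan)
    rec_ndead = np.zeros(n_rec, dtype=np.int64)
    rec_cols = np.full((n_rec, g.n_i), np.nan)
    rec_t[0] = 0.0
    rec_mean[0] = _kernels.masked_mean(gamma, domain.interior_mask)
    rec_cols[0] = _kernels.column_means(gamma, domain.interior_mask)
    counters = np.zeros(4)

    psi = np.asarray(params.psi, dtype=float)
    tiers = np.asarray(params.xi_tiers, dtype=float)

    # schedule segments with constant boundary values, split at snapshots
    events = sorted(set(schedule.event_times())
                    | {t for t in snapshot_times if 0.0 < t <= schedule.t_end})
    snapshots: dict = {}
    hap = schedule.bolus("HAP")
    sens = schedule.bolus("Sens")
    step0 = 0
    for t_a, t_b in zip(events, events[1:]):
        n_seg = int(round(t_b / dt)) - int(round(t_a / dt))
        if n_seg <= 0:
            continue
        t_mid = 0.5 * (t_a + t_b)
        bc_g, bc_ei, bc_xi, lam = boundary_values(bc, t_mid)
        ux = flow.ux * lam
        uy = flow.uy * lam
        drugs_on = hap is not None and t_b > hap.start
        sens_on = sens is not None and t_b > sens.start
        pin_ei = hap is not None and hap.start <= t_mid <= hap.end
        pin_xi = sens is not None and sens.start <= t_mid <= sens.end
        _kernels.run_segment(
            gamma, eta_i, eta_a, xi, domain.interior_mask, ux, uy, cover,
            ptr, nodes, mult, cells.alive, cells.accumulated, cells.death_time,
            norm, params.d_gamma, params.d_eta_i, params.d_eta_a, params.d_xi,
            dt, g.h, bc_g, bc_ei, bc_xi,
            params.gamma_hyp, params.gamma_0, psi, tiers,
            params.conv_fraction, params.alpha, params.omega_a, params.omega_i,
            params.death_threshold, drugs_on, sens_on, pin_ei, pin_xi,
            n_seg, step0, t_a,
            rec_stride, rec_t, rec_mean, rec_ndead, rec_cols, counters)
        step0 += n_seg
        if any(abs(t_b - ts) < 0.5 * dt for ts in snapshot_times):
            snapshots[t_b] = {"oxygen": gamma.copy(), "inactive_drug": eta_i.copy(),
                              "active_drug": eta_a.copy(), "sensitizer": xi.copy()}

    # fill any record rows the segment loop did not reach (t=0 already set)
    valid = ~np.isnan(rec_t)
    length = g.x_max - g.x_min
    border = np.array([_border_from_columns(rec_cols[k], g.h, length)
                       if valid[k] else np.nan for k in range(n_rec)])
    fields = {
        "oxygen": ScalarField("oxygen", gamma, params.d_gamma),
        "inactive_drug": ScalarField("inactive_drug", eta_i, params.d_eta_i),
        "active_drug": ScalarField("active_drug", eta_a, params.d_eta_a,
                                   params.omega_a),
        "sensitizer": ScalarField("sensitizer", xi, params.d_xi),
    }
    counter_dict = {
        "clamp_events": int(counters[0]),
        "node_steps": int(counters[1]),
        "clamp_fraction": counters[0] / counters[1] if counters[1] else 0.0,
        "uptake_removed": counters[2] * g.h * g.h,
        "accum_gained": counters[3] * g.h * g.h,
    }
    rec_ndead[~valid] = rec_ndead[valid][-1] if valid.any() else 0
    return SimulationResult(
        times=rec_t[valid], n_dead=rec_ndead[valid], mean_oxygen=rec_mean[valid],
        border=border[valid], oxygen_columns=rec_cols[valid], cells=cells,
        fields=fields, snapshots=snapshots, counters=counter_dict,
        schedule=schedule)


# ---------------------------------------------------------------------------
# Offset sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Dead-cell landscape over a lattice of enhancer injection offsets."""

    axes: dict                  # compound -> offset array (min)
    dead_count: np.ndarray      # shape = tuple(len(a) for a in axes.values())
    maxima: list                # [(offsets dict or ranges, count), ...]
    infeasible: np.ndarray      # bool mask of flagged lattice points
    schedules: np.ndarray       # object array of the schedule used per point


def _offset_schedule(base: TreatmentSchedule, offsets: dict) -> TreatmentSchedule:
    """Shift enhancer boluses relative to the HAP start; clamp the whole
    schedule so no window starts before t = 0 (negative offset = enhancer
    before HAP)."""
    hap = base.bolus("HAP")
    if hap is None:
        raise ValueError("offset sweeps need a HAP bolus in the base schedule")
    starts = {"HAP": hap.start}
    durations = {"HAP": hap.duration}
    for compound, off in offsets.items():
        b = base.bolus(compound)
        durations[compound] = b.duration if b else DEFAULT_DURATIONS[compound]
        starts[compound] = hap.start + off
    shift = -min(starts.values())
    if shift > 0:
        starts = {c: s + shift for c, s in starts.items()}
    boluses = [Bolus(c, starts[c], durations[c]) for c in starts]
    return TreatmentSchedule(boluses, base.t_end)


def sweep_offsets(
    domain: TissueDomain,
    base: TreatmentSchedule,
    axes: dict,
    params: TransportParams | None = None,
    bc: VesselBC | None = None,
    flow: FlowField | None = None,
    oxygen0: ScalarField | None = None,
    progress=None,
    checkpoint=None,
) -> SweepResult:
    """One independent simulation per lattice point of enhancer offsets.

    ``axes`` maps compound name ('Sens'/'Vaso') to an array of offsets in
    minutes relative to the HAP injection.  All runs share the precomputed
    flow and steady-state oxygen.  Points whose windows cannot fit in the
    horizon are flagged infeasible, not silently skipped.  ``checkpoint`` may
    name a .npz path used to store/resume partial results.
    """
    params = params or TransportParams()
    bc = bc or VesselBC()
    if flow is None or oxygen0 is None:
        from .stokes import build_stokeslet_system, solve_boundary_forces, \
            compute_velocity_field
        if flow is None:
            flow = compute_velocity_field(
                domain, solve_boundary_forces(build_stokeslet_system(domain)))
        if oxygen0 is None:
            oxygen0 = steady_state_oxygen(domain, flow, params, bc)

    names = list(axes)
    grids = [np.asarray(axes[c], dtype=float) for c in names]
    shape = tuple(len(a) for a in grids)
    dead = np.full(shape, -1, dtype=np.int64)
    infeasible = np.zeros(shape, dtype=bool)
    schedules = np.empty(shape, dtype=object)

    if checkpoint is not None:
        try:
            saved = np.load(checkpoint, allow_pickle=True)
            if saved["dead"].shape == dead.shape:
                dead = saved["dead"]
                infeasible = saved["infeasible"]
        except (FileNotFoundError, KeyError):
            pass

    for idx in itertools.product(*(range(n) for n in shape)):
        offsets = {c: grids[k][idx[k]] for k, c in enumerate(names)}
        try:
            sched = _offset_schedule(base, offsets)
        except ValueError:
            infeasible[idx] = True
            dead[idx] = 0
            continue
        schedules[idx] = sched
        if dead[idx] >= 0 and not infeasible[idx]:
            continue  # restored from checkpoint
        res = run_simulation(domain, sched, params, bc, flow=flow,
                             oxygen0=oxygen0)
        dead[idx] = res.dead_count
        if progress is not None:
            progress(idx, offsets, res.dead_count)
        if checkpoint is not None:
            np.savez(checkpoint, dead=dead, infeasible=infeasible)
    maxima = find_local_maxima(dead, grids, names, infeasible)
    return SweepResult(axes={c: g for c, g in zip(names, grids)},
                       dead_count=dead, maxima=maxima, infeasible=infeasible,
                       schedules=schedules)


def find_local_maxima(counts: np.ndarray, grids: list, names: list,
                      infeasible: np.ndarray | None = None) -> list:
    """Plateau-aware local maxima on the offset lattice.

    A connected component of equal counts is a maximum if every feasible
    4-neighbor outside it is strictly smaller; plateaus are reported as
    offset ranges.  Returns ``[(offsets, count), ...]`` where each offset is
    a scalar (single point) or a (lo, hi) range per axis.
    """
    counts = np.asarray(counts)
    if infeasible is None:
        infeasible = np.zeros(counts.shape, dtype=bool)
    visited = np.zeros(counts.shape, dtype=bool)
    out = []
    for start in itertools.product(*(range(n) for n in counts.shape)):
        if visited[start] or infeasible[start]:
            continue
        value = counts[start]
        component = [start]
        visited[start] = True
        stack = [start]
        is_max = True
        while stack:
            p = stack.pop()
            for d in range(counts.ndim):
                for step in (-1, 1):
                    q = list(p)
                    q[d] += step
                    q = tuple(q)
                    if not all(0 <= q[k] < counts.shape[k] for k in range(counts.ndim)):
                        continue
                    if infeasible[q]:
                        continue
                    if counts[q] == value and not visited[q]:
                        visited[q] = True
                        component.append(q)
                        stack.append(q)
                    elif counts[q] > value:
                        is_max = False
        if not is_max:
            continue
        offsets = {}
        for k, name in enumerate(names):
            vals = sorted({grids[k][p[k]] for p in component})
            offsets[name] = vals[0] if len(vals) == 1 else (vals[0], vals[-1])
        out.append((offsets, int(value)))
    out.sort(key=lambda item: -item[1])
    return out
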