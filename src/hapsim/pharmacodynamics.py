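"""Per-cell pharmacodynamics: active-drug accumulation and irreversible death.

Each cell integrates the active drug absorbed through its pseudo-receptors,

    dΓ_l/dt = α Σ_receptors Σ_{nodes in ε-disk} η_a(node),

the exact mirror of the uptake sink in the active-drug transport equation
(two views of one flux).  A cell dies — irreversibly — once its accumulated
node-sum, converted to a mean concentration over the cell (Γ_l·h²/A_l),
reaches the lethal threshold (1 ag/μm³).  Dead cells stop absorbing both
oxygen and drug but their remnants remain as transport obstacles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import TissueDomain
from .transport import ScalarField

__all__ = ["CellStateArray", "make_cell_states", "accumulate_drug", "update_death"]


@dataclass
class CellStateArray:
    """Vectorized state of all cells in the tissue."""

    cell_ids: np.ndarray       # (N,) int
    accumulated: np.ndarray    # (N,) node-summed concentration units (ag/μm³·nodes)
    alive: np.ndarray          # (N,) bool
    death_time: np.ndarray     # (N,) min; NaN while alive
    areas: np.ndarray          # (N,) μm²
    norm: np.ndarray = field(default=None)  # h²/A_l — node sum → mean concentration

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_dead(self) -> int:
        return int((~self.alive).sum())

    def normalized_accumulation(self) -> np.ndarray:
        """Mean accumulated active-drug concentration per cell (ag/μm³)."""
        return self.accumulated * self.norm

    def live_cover(self, domain: TissueDomain) -> np.ndarray:
        """Receptor coverage count per grid node over live cells only."""
        return domain.cover_count(alive=self.alive)

    def event_table(self) -> np.ndarray:
        """(cell_id, death_time, final normalized accumulation) rows."""
        return np.column_stack([self.cell_ids, self.death_time,
                                self.normalized_accumulation()])


def make_cell_states(domain: TissueDomain) -> CellStateArray:
    n = domain.n_cells
    areas = domain.cell_areas()
    h = domain.grid.h
    return CellStateArray(
        cell_ids=np.array([c.cell_id for c in domain.cells], dtype=int),
        accumulated=np.zeros(n),
        alive=np.ones(n, dtype=bool),
        death_time=np.full(n, np.nan),
        areas=areas,
        norm=(h * h) / areas if n else np.zeros(0),
    )


def accumulate_drug(cells: CellStateArray, eta_a: ScalarField,
                    domain: TissueDomain, alpha: float, dt: float) -> CellStateArray:
    """Add dt·α·Σ η_a over each live cell's receptor neighborhoods.

    Dead cells accumulate nothing (all absorption stops at death); their
    stored accumulation is frozen.
    """
    ptr, nodes, mult = domain.cover_arrays()
    _kernels.accumulate_cells(eta_a.values, ptr, nodes, mult, cells.alive,
                              cells.accumulated, alpha, dt)
    return cells


def update_death(cells: CellStateArray, threshold: float, t: float) -> CellStateArray:
    """Kill cells whose area-normalized accumulation reached ``threshold``.

    The comparison is inclusive (≥) and death is irreversible: once dead a
    cell stays dead regardless of later field values, and it leaves every
    uptake sum from the next step on.
    """
    trigger = cells.alive & (cells.normalized_accumulation() >= threshold)
    cells.alive[trigger] = False
    cells.death_time[trigger] = t
    return cells
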