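"""Shared fixtures: small tissues and their solved flow / steady oxygen.

Everything here is generated programmatically; the heavier session-scoped
fixtures are shared across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import hapsim as hs


@pytest.fixture(scope="session")
def small_grid() -> hs.GridSpec:
    return hs.GridSpec(0.0, 60.0, 0.0, 40.0, 2.0)


@pytest.fixture(scope="session")
def empty_domain(small_grid) -> hs.TissueDomain:
    return hs.generate_synthetic_tissue(small_grid, n_cells=0, seed=1)


@pytest.fixture(scope="session")
def small_domain(small_grid) -> hs.TissueDomain:
    return hs.generate_synthetic_tissue(small_grid, n_cells=10, mean_radius=4.0,
                                        seed=3)


@pytest.fixture(scope="session")
def small_flow(small_domain) -> hs.FlowField:
    system = hs.solve_boundary_forces(hs.build_stokeslet_system(small_domain))
    return hs.compute_velocity_field(small_domain, system)


@pytest.fixture(scope="session")
def params() -> hs.TransportParams:
    return hs.TransportParams()


@pytest.fixture(scope="session")
def vessel_bc() -> hs.VesselBC:
    return hs.VesselBC()


@pytest.fixture(scope="session")
def small_steady(small_domain, small_flow, params, vessel_bc) -> hs.ScalarField:
    return hs.steady_state_oxygen(small_domain, small_flow, params, vessel_bc)


@pytest.fixture(scope="session")
def mid_domain() -> hs.TissueDomain:
    grid = hs.GridSpec(0.0, 100.0, 0.0, 40.0, 2.0)
    return hs.generate_synthetic_tissue(grid, n_cells=40, mean_radius=4.0,
                                        seed=2)


@pytest.fixture(scope="session")
def mid_flow(mid_domain) -> hs.FlowField:
    system = hs.solve_boundary_forces(hs.build_stokeslet_system(mid_domain))
    return hs.compute_velocity_field(mid_domain, system)


@pytest.fixture(scope="session")
def mid_steady(mid_domain, mid_flow, params, vessel_bc) -> hs.ScalarField:
    return hs.steady_state_oxygen(mid_domain, mid_flow, params, vessel_bc)


@pytest.fixture()
def zero_flow(small_grid) -> hs.FlowField:
    shape = small_grid.shape
    return hs.FlowField(ux=np.zeros(shape), uy=np.zeros(shape))


def uniform_flow(grid: hs.GridSpec, ux: float, uy: float = 0.0) -> hs.FlowField:
    return hs.FlowField(ux=np.full(grid.shape, float(ux)),
                        uy=np.full(grid.shape, float(uy)))


def masked_domain(grid: hs.GridSpec, mask: np.ndarray) -> hs.TissueDomain:
    """Cell-free domain with a hand-chosen interior mask (stencil tests)."""
    return hs.TissueDomain(grid=grid, cells=[], epsilon=2.0,
                           interior_mask=np.asarray(mask, dtype=bool))
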