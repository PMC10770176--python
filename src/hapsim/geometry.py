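"""Tissue geometry: computational domain, cell contours, grid masks, receptor maps.

The simulation domain is a rectangular patch of tumor tissue with a blood
vessel along its left edge.  Tumor cells are closed polygonal contours whose
boundary points ("pseudo-receptors") act both as no-slip obstacles for the
interstitial flow and as the sites of oxygen / active-drug absorption.
Scalar fields live on a regular Cartesian grid; nodes falling inside a cell
contour are masked out of the transport stencils (cell interiors are
impermeable unless a compound is absorbed through the boundary).

Geometry files are plain delimited text, one row per boundary point with
columns ``cell_id,x,y`` (μm), points ordered along each contour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "GridSpec",
    "CellGeometry",
    "TissueDomain",
    "GeometryError",
    "PackingError",
    "load_tissue",
    "write_geometry",
    "generate_synthetic_tissue",
    "build_receptor_map",
    "resample_contour",
]

log = logging.getLogger(__name__)

#: Default regularization radius ε (μm); also the boundary-point spacing.
DEFAULT_EPSILON = 2.0


class GeometryError(ValueError):
    """Invalid tissue geometry (open contour, overlap, out-of-domain, ...)."""


class PackingError(RuntimeError):
    """Synthetic generator could not place the requested number of cells."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not pack {requested} cells; placed {achieved} before the "
            f"candidate sites were exhausted"
        )


@dataclass(frozen=True)
class GridSpec:
    """Regular Cartesian grid over the rectangular domain [x_min,x_max]×[y_min,y_max].

    Nodes sit at ``x_min + i*h`` / ``y_min + j*h`` (0-based), so the node
    counts are ``(x_max-x_min)/h + 1`` per axis; the spacing must divide both
    side lengths exactly.  Default: a 200×100 μm patch at h = 2 μm.
    """

    x_min: float = 0.0
    x_max: float = 200.0
    y_min: float = 0.0
    y_max: float = 100.0
    h: float = 2.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"grid spacing must be positive, got h={self.h}")
        for lo, hi, name in ((self.x_min, self.x_max, "x"), (self.y_min, self.y_max, "y")):
            if hi <= lo:
                raise ValueError(f"degenerate {name}-extent [{lo}, {hi}]")
            n = (hi - lo) / self.h
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"grid spacing h={self.h} does not divide the {name}-extent {hi - lo}"
                )

    @property
    def n_i(self) -> int:
        """Number of nodes along x."""
        return round((self.x_max - self.x_min) / self.h) + 1

    @property
    def n_j(self) -> int:
        """Number of nodes along y."""
        return round((self.y_max - self.y_min) / self.h) + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_i, self.n_j)

    def node_x(self) -> np.ndarray:
        return self.x_min + self.h * np.arange(self.n_i)

    def node_y(self) -> np.ndarray:
        return self.y_min + self.h * np.arange(self.n_j)


@dataclass
class CellGeometry:
    """A single tumor cell: closed contour of boundary points (pseudo-receptors)."""

    cell_id: int
    boundary_points: np.ndarray  # (N_l, 2) μm, ordered, first point not repeated
    area: float = 0.0  # μm², set from the polygon on construction

    def __post_init__(self) -> None:
        self.boundary_points = np.asarray(self.boundary_points, dtype=float)
        if self.boundary_points.ndim != 2 or self.boundary_points.shape[1] != 2:
            raise GeometryError(f"cell {self.cell_id}: boundary points must be (N,2)")
        if len(self.boundary_points) < 3:
            raise GeometryError(f"cell {self.cell_id}: needs >= 3 boundary points")
        if self.area == 0.0:
            self.area = self.polygon().area
        if self.area <= 0:
            raise GeometryError(f"cell {self.cell_id}: non-positive area {self.area}")

    @property
    def n_points(self) -> int:
        return len(self.boundary_points)

    def polygon(self) -> Polygon:
        poly = Polygon(self.boundary_points)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError(f"cell {self.cell_id}: contour is self-intersecting")
        return poly


def resample_contour(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed contour to (approximately) uniform arc-length spacing.

    The Stokeslet regularization error bound assumes boundary-point spacing
    ≈ ε, so contours are resampled on load/generation.  The number of points
    is ``max(4, round(perimeter / spacing))``.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = float(seg.sum())
    if perimeter <= 0:
        raise GeometryError("degenerate contour with zero perimeter")
    n_new = max(4, int(round(perimeter / spacing)))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, perimeter, n_new, endpoint=False)
    out = np.empty((n_new, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


@dataclass
class TissueDomain:
    """Digitized tissue: grid, cells, masks and receptor neighborhoods.

    Attributes
    ----------
    grid : GridSpec
    cells : list of CellGeometry
    epsilon : float
        Regularization radius ε (μm); strict receptor radius of Eq-style
        indicator ``χ_ε(x, X) = 1 iff ||x − X|| < ε``.
    interior_mask : (n_i, n_j) bool
        True at nodes inside (or on the boundary of) some cell.
    receptor_map : list (per cell) of list (per boundary point) of node-index
        tuples ``(i, j)`` — the interstitial nodes within ε of that receptor.
    """

    grid: GridSpec
    cells: list[CellGeometry]
    epsilon: float = DEFAULT_EPSILON
    interior_mask: np.ndarray = field(default=None, repr=False)
    receptor_map: list = field(default=None, repr=False)
    # Per-cell flattened coverage (node index -> multiplicity), CSR-style arrays
    # used by the transport/pharmacodynamics kernels.
    _cover_ptr: np.ndarray = field(default=None, repr=False)
    _cover_nodes: np.ndarray = field(default=None, repr=False)
    _cover_mult: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GeometryError(f"duplicate cell_id(s): {dup}")
        if self.interior_mask is None:
            self.interior_mask = compute_interior_mask(self.grid, self.cells)
        if self.receptor_map is None:
            build_receptor_map(self)

    # -- derived quantities -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_boundary_points(self) -> int:
        return sum(c.n_points for c in self.cells)

    def cell_areas(self) -> np.ndarray:
        return np.array([c.area for c in self.cells])

    def interstitial_fraction(self) -> float:
        return 1.0 - self.interior_mask.mean()

    def cover_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR-style per-cell receptor coverage.

        Returns ``(ptr, nodes, mult)`` where for cell ``l`` the flat grid node
        indices ``nodes[ptr[l]:ptr[l+1]]`` are covered with multiplicities
        ``mult[...]`` (a node counted once per receptor point whose ε-disk
        contains it, per the literal double sum in the uptake terms).
        """
        return self._cover_ptr, self._cover_nodes, self._cover_mult

    def cover_count(self, alive: np.ndarray | None = None) -> np.ndarray:
        """Total receptor coverage per node, restricted to live cells."""
        count = np.zeros(self.grid.shape, dtype=float).ravel()
        ptr, nodes, mult = self.cover_arrays()
        for l in range(self.n_cells):
            if alive is not None and not alive[l]:
                continue
            np.add.at(count, nodes[ptr[l]:ptr[l + 1]], mult[ptr[l]:ptr[l + 1]])
        return count.reshape(self.grid.shape)


def compute_interior_mask(grid: GridSpec, cells: Sequence[CellGeometry]) -> np.ndarray:
    """Node-inside-cell mask; nodes on a contour count as interior (obstacles)."""
    mask = np.zeros(grid.shape, dtype=bool)
    if not cells:
        return mask
    xs, ys = grid.node_x(), grid.node_y()
    for cell in cells:
        poly = cell.polygon()
        x0, y0, x1, y1 = poly.bounds
        i0 = max(0, math.ceil((x0 - grid.x_min) / grid.h - 1e-12))
        i1 = min(grid.n_i - 1, math.floor((x1 - grid.x_min) / grid.h + 1e-12))
        j0 = max(0, math.ceil((y0 - grid.y_min) / grid.h - 1e-12))
        j1 = min(grid.n_j - 1, math.floor((y1 - grid.y_min) / grid.h + 1e-12))
        if i1 < i0 or j1 < j0:
            continue
        gx, gy = np.meshgrid(xs[i0:i1 + 1], ys[j0:j1 + 1], indexing="ij")
        inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel())
        mask[i0:i1 + 1, j0:j1 + 1] |= inside.reshape(gx.shape)
    return mask


def build_receptor_map(domain: TissueDomain) -> list:
    """Map each cell boundary point to the interstitial grid nodes within ε.

    Strict inequality ``||x − X|| < ε`` (a node exactly ε away is excluded);
    nodes inside cells are excluded.  Receptors whose whole ε-disk is interior
    (e.g. at tight cell–cell contacts) map to an empty list (logged).
    """
    grid, eps = domain.grid, domain.epsilon
    mask = domain.interior_mask
    n_j = grid.n_j
    receptor_map: list[list[list[tuple[int, int]]]] = []
    ptr = [0]
    nodes_flat: list[int] = []
    n_empty = 0
    for cell in domain.cells:
        per_cell: list[list[tuple[int, int]]] = []
        for (px, py) in cell.boundary_points:
            i_lo = max(0, math.ceil((px - eps - grid.x_min) / grid.h))
            i_hi = min(grid.n_i - 1, math.floor((px + eps - grid.x_min) / grid.h))
            j_lo = max(0, math.ceil((py - eps - grid.y_min) / grid.h))
            j_hi = min(grid.n_j - 1, math.floor((py + eps - grid.y_min) / grid.h))
            hits: list[tuple[int, int]] = []
            for i in range(i_lo, i_hi + 1):
                dx = grid.x_min + i * grid.h - px
                for j in range(j_lo, j_hi + 1):
                    if mask[i, j]:
                        continue
                    dy = grid.y_min + j * grid.h - py
                    if dx * dx + dy * dy < eps * eps:
                        hits.append((i, j))
            if not hits:
                n_empty += 1
            per_cell.append(hits)
            nodes_flat.extend(i * n_j + j for (i, j) in hits)
        receptor_map.append(per_cell)
        ptr.append(len(nodes_flat))
    if n_empty:
        log.warning("%d boundary point(s) have no interstitial node within ε", n_empty)

    # Collapse per-cell node lists into (node, multiplicity) CSR arrays.
    c_ptr = [0]
    c_nodes: list[int] = []
    c_mult: list[float] = []
    for l in range(len(domain.cells)):
        seg = nodes_flat[ptr[l]:ptr[l + 1]]
        if seg:
            uniq, counts = np.unique(np.array(seg, dtype=np.int64), return_counts=True)
            c_nodes.extend(uniq.tolist())
            c_mult.extend(counts.astype(float).tolist())
        c_ptr.append(len(c_nodes))
    domain.receptor_map = receptor_map
    domain._cover_ptr = np.array(c_ptr, dtype=np.int64)
    domain._cover_nodes = np.array(c_nodes, dtype=np.int64)
    domain._cover_mult = np.array(c_mult, dtype=float)
    return receptor_map


# ---------------------------------------------------------------------------
# File I/O (delimited text: cell_id,x,y)
# ---------------------------------------------------------------------------

def load_tissue(
    path: str | Path,
    grid: GridSpec | None = None,
    epsilon: float = DEFAULT_EPSILON,
    resample: bool = True,
) -> TissueDomain:
    """Load a tissue geometry file and build masks + receptor map.

    The file holds one boundary point per row, ``cell_id,x,y`` in μm, points
    ordered along each contour; the contour is implicitly closed (a repeated
    first point is tolerated).  Contours whose endpoints differ by more than
    the grid spacing are rejected as open; out-of-domain coordinates and
    duplicate cell ids are rejected naming the offending cell.
    """
    grid = grid or GridSpec()
    path = Path(path)
    try:
        raw = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:  # tolerate the writer's "cell_id,x,y" header row
        raw = np.loadtxt(path, delimiter=",", ndmin=2, skiprows=1)
    if raw.shape[1] != 3:
        raise GeometryError(f"{path}: expected 3 columns (cell_id,x,y)")
    ids = raw[:, 0].astype(int)
    seen: set[int] = set()
    cells: list[CellGeometry] = []
    order = []
    last = None
    for cid in ids:
        if cid != last:
            order.append(cid)
            last = cid
    if len(order) != len(set(order)):
        dup = sorted({c for c in order if order.count(c) > 1})
        raise GeometryError(f"duplicate cell_id {dup[0]}: contour rows are not contiguous")
    for cid in order:
        pts = raw[ids == cid, 1:]
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise GeometryError(f"cell {cid}: fewer than 3 boundary points")
        gap = float(np.linalg.norm(pts[0] - pts[-1]))
        # consecutive points are ~ε apart; a terminal gap far beyond the grid
        # spacing means the contour was never closed
        if gap > max(grid.h, 2.0 * epsilon):
            raise GeometryError(f"cell {cid}: open contour (endpoint gap {gap:.2f} μm)")
        if (pts[:, 0] < grid.x_min).any() or (pts[:, 0] > grid.x_max).any() \
                or (pts[:, 1] < grid.y_min).any() or (pts[:, 1] > grid.y_max).any():
            raise GeometryError(f"cell {cid}: boundary point outside the domain")
        if resample:
            pts = resample_contour(pts, epsilon)
        cells.append(CellGeometry(cell_id=int(cid), boundary_points=pts))
        seen.add(cid)
    _check_overlaps(cells)
    domain = TissueDomain(grid=grid, cells=cells, epsilon=epsilon)
    log.info(
        "loaded %s: %d cells, %d boundary points, interstitial fraction %.2f",
        path, domain.n_cells, domain.n_boundary_points, domain.interstitial_fraction(),
    )
    return domain


def write_geometry(domain_or_cells, path: str | Path) -> None:
    """Write cells to the delimited geometry format (cell_id,x,y)."""
    cells = domain_or_cells.cells if isinstance(domain_or_cells, TissueDomain) else domain_or_cells
    rows = []
    for c in cells:
        for (x, y) in c.boundary_points:
            rows.append((c.cell_id, x, y))
    np.savetxt(path, np.array(rows), delimiter=",", fmt=["%d", "%.6f", "%.6f"],
               header="cell_id,x,y", comments="")


def _check_overlaps(cells: Sequence[CellGeometry]) -> None:
    polys = [c.polygon() for c in cells]
    tree = shapely.STRtree(polys)
    for a, b in zip(*tree.query(polys, predicate="intersects")):
        if a < b and polys[a].intersection(polys[b]).area > 1e-9:
            raise GeometryError(
                f"cells {cells[a].cell_id} and {cells[b].cell_id} overlap")


# ---------------------------------------------------------------------------
# Synthetic tissue generator
# ---------------------------------------------------------------------------

def generate_synthetic_tissue(
    grid: GridSpec | None = None,
    n_cells: int = 300,
    mean_radius: float = 4.0,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    clearance: float = 2.8,
) -> TissueDomain:
    """Generate a dense, non-overlapping synthetic tumor tissue.

    Emulates a digitized histology patch: irregular polygonal cells tiling
    the domain the way segmented tumor cords do, separated by narrow
    interstitial channels, with a cell-free strip of width ≥ 2ε along the
    left (vessel) edge.  Cells are Voronoi regions of a jittered hexagonal
    point set, each shrunk inward by ``clearance/2`` so neighboring contours
    stay ≥ ``clearance`` apart (wide enough for the transport grid to carry
    interstitial nodes through the channels).  ``n_cells`` sets the packing
    density; ``mean_radius`` bounds the cell sizes (an equivalent radius cap
    of 1.4·mean_radius and a floor of 0.35·mean_radius).  Boundary points
    are resampled at spacing ≈ ε.  Deterministic for a fixed
    ``(parameters, seed)``.
    """
    grid = grid or GridSpec()
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells > 0 and mean_radius < 2 * grid.h:
        raise ValueError(f"mean_radius must be >= 2h = {2 * grid.h}")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return TissueDomain(grid=grid, cells=[], epsilon=epsilon)

    strip = 2.0 * epsilon  # cell-free margin at the vessel edge
    x_lo, x_hi = grid.x_min + strip, grid.x_max
    y_lo, y_hi = grid.y_min, grid.y_max
    area = (x_hi - x_lo) * (y_hi - y_lo)

    # site-overage ladder: a few % of Voronoi cells are lost to the shrink
    cells: list[CellGeometry] = []
    for overage in (1.04, 1.12, 1.25):
        cells = _tessellate_cells(rng, n_cells, mean_radius, epsilon,
                                  clearance, overage, x_lo, x_hi, y_lo, y_hi,
                                  area)
        if len(cells) == n_cells:
            break
    if len(cells) < n_cells:
        raise PackingError(n_cells, len(cells))
    return TissueDomain(grid=grid, cells=cells, epsilon=epsilon)


def _tessellate_cells(rng, n_cells, mean_radius, epsilon, clearance, overage,
                      x_lo, x_hi, y_lo, y_hi, area):
    """One tessellation attempt: shrunk Voronoi cells of a jittered hex set."""
    from scipy.spatial import Voronoi
    from shapely.geometry import box

    n_sites = int(math.ceil(overage * n_cells))
    s = math.sqrt(2.0 * area / (math.sqrt(3.0) * n_sites))
    sites = []
    row = 0
    y = y_lo + 0.4 * s
    while y < y_hi:
        x = x_lo + (0.25 if row % 2 == 0 else 0.75) * s
        while x < x_hi:
            sites.append((x, y))
            x += s
        row += 1
        y += s * math.sqrt(3.0) / 2.0
    sites = np.asarray(sites)
    sites = sites + rng.uniform(-0.24 * s, 0.24 * s, size=sites.shape)
    sites[:, 0] = np.clip(sites[:, 0], x_lo + 1.0, x_hi - 1.0)
    sites[:, 1] = np.clip(sites[:, 1], y_lo + 1.0, y_hi - 1.0)
    rng.shuffle(sites)

    # mirror the sites across every edge so all interior regions are bounded
    padded = [sites]
    for axis, value in ((0, x_lo), (0, x_hi), (1, y_lo), (1, y_hi)):
        m = sites.copy()
        m[:, axis] = 2.0 * value - m[:, axis]
        padded.append(m)
    vor = Voronoi(np.vstack(padded))
    clip = box(x_lo, y_lo, x_hi, y_hi)

    cells: list[CellGeometry] = []
    r_cap = 1.4 * mean_radius
    a_min = math.pi * (0.35 * mean_radius) ** 2
    for k in range(len(sites)):
        if len(cells) == n_cells:
            break
        region = vor.regions[vor.point_region[k]]
        if not region or -1 in region:
            continue
        poly = Polygon(vor.vertices[region]).intersection(clip)
        poly = poly.buffer(-0.5 * clearance, join_style=1)
        if poly.is_empty:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
        r_eq = math.sqrt(poly.area / math.pi)
        if r_eq > r_cap:
            poly = poly.buffer(-(r_eq - r_cap), join_style=1)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda p: p.area)
        if poly.is_empty or poly.area < a_min:
            continue
        pts = resample_contour(np.asarray(poly.exterior.coords[:-1]), epsilon)
        cells.append(CellGeometry(cell_id=len(cells) + 1, boundary_points=pts))
    return cells
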