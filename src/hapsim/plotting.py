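"""Four-panel tissue snapshots: oxygen (with the normoxia/hypoxia border),
sensitizer, inactive pro-drug and active drug (with dead cells filled),
each with its strip-averaged profile curve above the tissue panel."""

from __future__ import annotations

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Polygon as MplPolygon

from .geometry import TissueDomain
from .scheduling import _border_from_columns
from . import _kernels

__all__ = ["render_snapshot"]

_PANELS = [
    ("oxygen", "O$_2$ (mmHg)", "viridis"),
    ("sensitizer", "Sens (ag/μm³)", "cividis"),
    ("inactive_drug", "HAP (ag/μm³)", "inferno"),
    ("active_drug", "active drug (ag/μm³)", "magma"),
]


def render_snapshot(domain: TissueDomain, fields: dict, cells=None,
                    t: float | None = None, gamma_hyp: float = 10.0):
    """Render the four-compound snapshot figure; returns the Figure.

    ``fields`` maps the species name to either a ScalarField or a raw
    (n_i, n_j) array.  Dead cells (``cells.alive == False``) are filled black
    in the active-drug panel; the oxygen panel carries a vertical line at the
    hypoxia border computed from the same strip-average shown above it.
    """
    g = domain.grid
    extent = (g.x_min, g.x_max, g.y_min, g.y_max)
    fig, axes = plt.subplots(
        2, 4, figsize=(16, 4.2), sharex=True,
        gridspec_kw={"height_ratios": [1, 2.6], "hspace": 0.12})
    xs = g.node_x()
    border = None
    for k, (name, label, cmap) in enumerate(_PANELS):
        f = fields.get(name)
        values = getattr(f, "values", f)
        if values is None:
            values = np.zeros(g.shape)
        cols = _kernels.column_means(np.asarray(values, dtype=float),
                                     domain.interior_mask)
        ax_prof, ax_map = axes[0, k], axes[1, k]
        ax_prof.plot(xs, cols, lw=1.2)
        ax_prof.set_ylabel(label, fontsize=7)
        im = ax_map.imshow(np.asarray(values, dtype=float).T, origin="lower",
                           extent=extent, aspect="equal", cmap=cmap)
        fig.colorbar(im, ax=ax_map, shrink=0.85)
        for cell in domain.cells:
            pts = cell.boundary_points
            ax_map.add_patch(MplPolygon(pts, closed=True, fill=False,
                                        ec="0.6", lw=0.3))
        if name == "oxygen":
            border = _border_from_columns(cols, g.h, g.x_max - g.x_min,
                                          gamma_hyp)
            for ax in (ax_prof, ax_map):
                ax.axvline(g.x_min + border, color="r", ls="--", lw=1)
            ax_prof.axhline(gamma_hyp, color="c", ls=":", lw=0.8)
        if name == "active_drug" and cells is not None:
            for idx, cell in enumerate(domain.cells):
                if not cells.alive[idx]:
                    ax_map.add_patch(MplPolygon(cell.boundary_points,
                                                closed=True, fc="k", ec="k"))
        ax_map.set_xlabel("x (μm)")
    title = "tissue snapshot" if t is None else f"tissue snapshot at t = {t:g} min"
    if border is not None:
        title += f"  (normoxia/hypoxia border {border:.0f} μm)"
    fig.suptitle(title)
    fig.hypoxia_border = border  # convenience for tests / callers
    return fig
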