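"""Result serialization: delimited time-series tables, field arrays, manifest.

A results directory is self-describing: it carries the time-series table,
the per-cell event log, final/snapshot fields as a compressed array
container, the full config (plus its hash) and a manifest with per-file
checksums, so any archived directory can be re-run to identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scheduling import SimulationResult

__all__ = ["write_results", "validate_manifest", "ManifestError"]


class ManifestError(RuntimeError):
    """A manifest re-validation failed (missing or altered file)."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_results(result: SimulationResult, out_dir: str | Path,
                  config=None) -> dict:
    """Write a simulation result to ``out_dir`` and return the manifest.

    Files: ``timeseries.csv`` (t, n_dead, border, mean_oxygen),
    ``cells.csv`` (cell_id, death_time, final normalized accumulation),
    ``fields.npz`` (final fields + strip profiles + any snapshots),
    ``config.yaml`` (if a config is given), ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ts = pd.DataFrame({
        "t_min": result.times,
        "n_dead": result.n_dead,
        "border_um": result.border,
        "mean_oxygen_mmHg": result.mean_oxygen,
    })
    ts.to_csv(out / "timeseries.csv", index=False)

    cells = pd.DataFrame(result.cells.event_table(),
                         columns=["cell_id", "death_time_min", "final_accum"])
    cells["cell_id"] = cells["cell_id"].astype(int)
    cells.to_csv(out / "cells.csv", index=False)

    arrays = {f"final_{name}": f.values for name, f in result.fields.items()}
    arrays["oxygen_columns"] = result.oxygen_columns
    for t, snap in result.snapshots.items():
        for name, arr in snap.items():
            arrays[f"snapshot_{t:g}_{name}"] = arr
    np.savez_compressed(out / "fields.npz", **arrays)

    files = ["timeseries.csv", "cells.csv", "fields.npz"]
    if config is not None:
        from .config import save_config
        save_config(config, out / "config.yaml")
        files.append("config.yaml")

    manifest = {
        "tool": "hapsim",
        "version": __version__,
        "config_hash": config.hash() if config is not None else None,
        "counters": result.counters,
        "dead_count": result.dead_count,
        "dead_fraction": result.dead_fraction,
        "files": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_manifest(out_dir: str | Path) -> dict:
    """Re-hash every listed file; raise ManifestError on a missing or
    modified file.  Returns the manifest on success."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        path = out / name
        if not path.exists():
            raise ManifestError(f"missing file: {name}")
        if _sha256(path) != digest:
            raise ManifestError(f"checksum mismatch: {name}")
    return manifest
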