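"""Run configuration: a validated, round-trippable YAML surface over the model.

Every physical parameter default is the model's study condition; an empty
config (plus a geometry section) therefore reproduces the default setup.
Unknown keys are rejected, non-physical values raise named validation
errors, and a config hash travels with every results directory for
provenance.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import GridSpec, TissueDomain, generate_synthetic_tissue, load_tissue
from .scheduling import TreatmentSchedule
from .transport import Bolus, DEFAULT_DURATIONS, TransportParams, VesselBC

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class GeometryConfig:
    source: str = "synthetic"       # 'synthetic' | 'file'
    path: str | None = None
    n_cells: int = 300
    mean_radius: float = 4.0        # μm
    seed: int = 7


@dataclass
class FluidConfig:
    mu: float = 0.04                # mg/(μm·min)
    u_in: float = 1.0               # μm/min (see docs/methods.md on the regime)
    solver_tol: float = 1e-8


@dataclass
class ScheduleConfig:
    t_end: float = 180.0
    hap_start: float | None = 5.0
    hap_duration: float = DEFAULT_DURATIONS["HAP"]
    sens_start: float | None = None
    sens_duration: float = DEFAULT_DURATIONS["Sens"]
    vaso_start: float | None = None
    vaso_duration: float = DEFAULT_DURATIONS["Vaso"]


@dataclass
class VesselConfig:
    gamma_in: float = 60.0
    eta_i_in: float = 50.0
    xi_in: float = 101.0
    lam: float = 0.5


@dataclass
class OutputConfig:
    dir: str = "results"
    record_dt: float = 0.5
    snapshot_times: list = field(default_factory=list)


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    epsilon: float = 2.0
    fluid: FluidConfig = field(default_factory=FluidConfig)
    transport: TransportParams = field(default_factory=TransportParams)
    vessel: VesselConfig = field(default_factory=VesselConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    steady_tol: float = 1e-10

    def validate(self) -> None:
        g = self.geometry
        if g.source not in ("synthetic", "file"):
            raise ConfigError(f"geometry.source must be 'synthetic' or 'file', got {g.source!r}")
        if g.source == "file" and not g.path:
            raise ConfigError("geometry.source='file' requires geometry.path")
        if g.source == "synthetic" and g.n_cells < 0:
            raise ConfigError("geometry.n_cells must be >= 0")
        if not 0.0 <= self.vessel.lam <= 1.0:
            raise ConfigError(f"vessel.lam must be in [0, 1], got {self.vessel.lam}")
        for name in ("gamma_in", "eta_i_in", "xi_in"):
            if getattr(self.vessel, name) < 0:
                raise ConfigError(f"vessel.{name} must be non-negative")
        if self.fluid.mu <= 0:
            raise ConfigError("fluid.mu must be positive")
        if self.fluid.u_in < 0:
            raise ConfigError("fluid.u_in must be non-negative")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        s = self.schedule
        if s.t_end <= 0:
            raise ConfigError("schedule.t_end must be positive")
        for c in ("hap", "sens", "vaso"):
            start = getattr(s, f"{c}_start")
            if start is not None and start < 0:
                raise ConfigError(f"schedule.{c}_start must be >= 0")
            if getattr(s, f"{c}_duration") <= 0:
                raise ConfigError(f"schedule.{c}_duration must be positive")
        # TransportParams validates itself on construction; re-check anyway
        nu = self.transport.dt * self.transport.d_gamma / self.grid.h ** 2
        if nu > 0.5:
            raise ConfigError(
                f"explicit stability number dt·D_γ/h² = {nu:.3f} exceeds 0.5")

    # -- model-object builders ---------------------------------------------
    def build_domain(self) -> TissueDomain:
        g = self.geometry
        if g.source == "file":
            return load_tissue(g.path, grid=self.grid, epsilon=self.epsilon)
        return generate_synthetic_tissue(grid=self.grid, n_cells=g.n_cells,
                                         mean_radius=g.mean_radius, seed=g.seed,
                                         epsilon=self.epsilon)

    def build_schedule(self) -> TreatmentSchedule:
        s = self.schedule
        boluses = []
        for compound, key in (("HAP", "hap"), ("Sens", "sens"), ("Vaso", "vaso")):
            start = getattr(s, f"{key}_start")
            if start is not None:
                boluses.append(Bolus(compound, start, getattr(s, f"{key}_duration")))
        return TreatmentSchedule(boluses, s.t_end)

    def build_vessel_bc(self) -> VesselBC:
        v = self.vessel
        return VesselBC(gamma_in=v.gamma_in, eta_i_in=v.eta_i_in, xi_in=v.xi_in,
                        lam=v.lam, boluses=self.build_schedule().boluses)

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["transport"]["psi"] = list(self.transport.psi)
        d["transport"]["xi_tiers"] = list(self.transport.xi_tiers)
        return d

    def hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_SECTIONS = {
    "geometry": GeometryConfig,
    "fluid": FluidConfig,
    "vessel": VesselConfig,
    "schedule": ScheduleConfig,
    "output": OutputConfig,
    "transport": TransportParams,
    "grid": GridSpec,
}
_SCALARS = {"epsilon", "steady_tol"}


def _build_section(cls, data: dict, section: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {section} section: {exc}") from exc


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing sections take their defaults.

    ``overrides`` (same nested structure) are applied on top — the CLI uses
    this for flags like ``--seed``.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    for section, values in (overrides or {}).items():
        if isinstance(values, dict):
            data.setdefault(section, {}).update(values)
        else:
            data[section] = values
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        sect = data.get(section, {})
        if not isinstance(sect, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        if section == "transport" and "psi" in sect:
            sect["psi"] = tuple(sect["psi"])
        if section == "transport" and "xi_tiers" in sect:
            sect["xi_tiers"] = tuple(sect["xi_tiers"])
        kwargs[section] = _build_section(cls, sect, section)
    for key in _SCALARS:
        if key in data:
            kwargs[key] = float(data[key])
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
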