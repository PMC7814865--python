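"""Study configuration: YAML load/save with strict schema validation.

A study config collects everything a drying run or analysis needs —
vial geometry, formulation, heat- and mass-transfer parameters, microwave
coupling, schedule and layout references, and analysis options — in one
structured text file.  Unknown keys are rejected (typos should fail
loudly, not silently fall back to defaults) and physical invariants are
enforced on load by the parameter dataclasses themselves.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gravimetric import TrayLayout
from .heat_mass import HeatTransferParams, MassTransferParams, VialGeometry
from .simulator import Formulation, MvdPowerParams
from .thermo import IceCorrelation

_SECTIONS = {
    "geometry": VialGeometry,
    "formulation": Formulation,
    "heat_transfer": HeatTransferParams,
    "mass_transfer": MassTransferParams,
    "microwave": MvdPowerParams,
    "ice_correlation": IceCorrelation,
}
_TOP_LEVEL_SCALARS = {"schedule", "layout", "mode", "version",
                      "secondary_hold_min", "full_cycle_time_min",
                      "convergence_time_min", "empirical_factor",
                      "shelf_area_m2", "vial_area_m2"}


def mvd_default_heat_params() -> HeatTransferParams:
    """Background (non-microwave) heat leak in the microwave dryer.

    There is no heated shelf: the tray sees ambient chamber walls, so the
    conductive/radiative terms are small.  These defaults reproduce a
    zero-power background sublimation of a few hundredths of a g/h per
    vial, the order observed in zero-power front runs.
    """
    return HeatTransferParams(Kc=0.3, Kg=0.2, shelf_emissivity=0.0,
                              vial_top_emissivity=0.2,
                              shelf_temperature_K=293.15,
                              lid_temperature_K=293.15)


def lyo_default_heat_params() -> HeatTransferParams:
    """Typical lab lyophilizer heat-transfer parameters (shelf follows the cycle)."""
    return HeatTransferParams()


@dataclass
class StudyConfig:
    """Validated study configuration."""

    geometry: VialGeometry = field(default_factory=VialGeometry)
    formulation: Formulation = field(default_factory=Formulation)
    heat_transfer: HeatTransferParams = field(default_factory=HeatTransferParams)
    mass_transfer: MassTransferParams = field(default_factory=MassTransferParams)
    microwave: MvdPowerParams = field(default_factory=MvdPowerParams)
    ice_correlation: IceCorrelation = field(default_factory=IceCorrelation)
    schedule: str = "mvd_full"
    layout: str = "tight_wedge"
    mode: str = "mvd"
    version: str = "1"
    secondary_hold_min: float = 60.0
    full_cycle_time_min: float = 370.0
    convergence_time_min: float = 1120.0
    empirical_factor: float = 1.0
    shelf_area_m2: float = 0.20
    vial_area_m2: float = 2.3e-3

    def to_dict(self) -> dict:
        d = {}
        for name, cls in _SECTIONS.items():
            section = asdict(getattr(self, name))
            section.pop("kg_of_pressure", None)   # callables are code, not config
            d[name] = section
        for name in sorted(_TOP_LEVEL_SCALARS):
            d[name] = getattr(self, name)
        return d

    def tray_layout(self) -> TrayLayout:
        return TrayLayout(self.layout) if self.layout in (
            "tight_wedge", "loose_wedge", "lyo_rect") else TrayLayout()


def _build_section(cls, mapping: dict, section: str):
    import dataclasses
    allowed = {f.name for f in dataclasses.fields(cls) if f.name != "kg_of_pressure"}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"config section {section!r}: unknown keys {sorted(unknown)}")
    fixed = {k: (tuple(v) if isinstance(v, list) else v) for k, v in mapping.items()}
    return cls(**fixed)


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _TOP_LEVEL_SCALARS
    if unknown:
        raise ValueError(f"config {path}: unknown top-level keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ValueError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, raw[name], name)
    for name in _TOP_LEVEL_SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    return StudyConfig(**kwargs)


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Write a config as YAML; save -> load round-trips to an equal config."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: StudyConfig) -> str:
    """Short provenance hash of the canonicalized config content."""
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
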