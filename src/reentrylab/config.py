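"""Run configuration: a validated, round-trippable YAML schema.

Keys embed their units (``_ms``, ``_mm``, ``_s_per_m``) to keep unit
mistakes visible.  Unknown keys are rejected by name; every random draw in
a run is traceable to the named seeds in the config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class GeometrySpec:
    kind: str = "sheet"                 # sheet | strand | two_region_sheet
    nx: int = 121
    ny: int = 121
    h_mm: float = 0.5
    sigma_s_per_m: float = 0.2
    segments_k: int = 1
    fibrosis_preset: str | None = None  # UII | UIV | None
    fibrosis_seed: int = 0


@dataclass
class ProtocolSpec:
    name: str = "peerp"                 # peerp | rp | psd
    max_beats: int = 4
    erp_resolution_ms: float = 1.0
    rp_s_ms: float = 300.0
    rp_l_ms: float = 200.0
    rp_step_ms: float = 10.0
    rp_n_per_ci: int = 1
    rp_check_mode: str = "E"
    psd_cl_ms: float | None = None
    psd_chirality: str = "anticlockwise"


@dataclass
class SolverSpec:
    dt_ms: float = 0.02
    dt_out_ms: float = 1.0


@dataclass
class AnalysisSpec:
    phase_tau_ms: float = 10.0
    llps_min_ms: float = 500.0
    stable_bbox_mm: float = 50.0
    track_v_max_m_per_s: float = 1.0


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    membrane: str = "fast_test"         # fast_test | courtemanche
    remodeling: str = "control"         # control | AF | cytokine_fibrotic
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    solver: SolverSpec = field(default_factory=SolverSpec)
    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    seed: int = 0
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "geometry": GeometrySpec,
    "protocol": ProtocolSpec,
    "solver": SolverSpec,
    "analysis": AnalysisSpec,
}
_SCALARS = {"membrane", "remodeling", "seed", "output_dir"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise ``ValueError`` naming the offender; missing keys
    take their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(section) - valid
        if bad:
            raise ValueError(f"unknown keys in section {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**section)
    for key in _SCALARS:
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash identifying a configuration (embedded in outputs)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
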