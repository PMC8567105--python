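"""YAML/JSON pipeline configuration with strict validation.

Any document either yields a fully populated :class:`PipelineConfig` (with
defaults mirroring the reference settings: 5x5 patches, 21x21 search,
rho=10, tau at the 90th percentile, 128 histogram bins, 20 iterations,
gamma0=1.0, r_red=0.8) or raises :class:`ConfigError` naming the offending
key, so typos never pass silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .core import ScanGeometry, GridSpec, MU_WATER_DEFAULT
from .denoise import DenoiseParams

__all__ = [
    "ConfigError",
    "ReconOptions",
    "SimOptions",
    "PipelineConfig",
    "load_config",
    "config_from_dict",
]


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range configuration values."""


@dataclass
class ReconOptions:
    backprojector: str = "rdb"  # "rdb" | "pdb"
    pad_mode: str = "zero"
    parker_before_filter: bool = True
    mu_water: float = MU_WATER_DEFAULT

    def __post_init__(self) -> None:
        if self.backprojector not in ("rdb", "pdb"):
            raise ConfigError(f"recon.backprojector: unknown value {self.backprojector!r}")
        if self.pad_mode not in ("zero", "edge"):
            raise ConfigError(f"recon.pad_mode: unknown value {self.pad_mode!r}")
        if self.mu_water <= 0:
            raise ConfigError("recon.mu_water must be > 0")


@dataclass
class SimOptions:
    i0: Optional[float] = 2e4  # photons per pixel; None = noise-free
    benchmark_i0: Optional[float] = 3.2e5  # high-mAs benchmark scan
    seed: int = 1
    noise: bool = True
    electronic_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.i0 is not None and self.i0 <= 0:
            raise ConfigError("sim.i0 must be > 0 or null")
        if self.electronic_sigma < 0:
            raise ConfigError("sim.electronic_sigma must be >= 0")


@dataclass
class PipelineConfig:
    geometry: ScanGeometry
    grid: GridSpec
    recon: ReconOptions = field(default_factory=ReconOptions)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    sim: SimOptions = field(default_factory=SimOptions)
    output_dir: str = "minltv_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"log_level: unknown value {self.log_level!r}")


_DEFAULT_GEOMETRY = dict(
    n_views=60, arc_deg=360.0, sad=1000.0, sdd=1536.0,
    det_nu=128, det_nv=64, det_du=1.6, det_dv=1.0,
    det_offset_u=0.0, det_offset_v=0.0,
)
_DEFAULT_GRID = dict(shape=[16, 96, 96], spacing=[1.0, 1.0, 1.0])


def _build_section(cls, section: dict, prefix: str):
    """Instantiate a dataclass section, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {prefix!r}; "
            f"known keys: {sorted(known)}"
        )
    try:
        return cls(**section)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {prefix!r}: {exc}") from exc


def _build_geometry(section: dict) -> ScanGeometry:
    merged = {**_DEFAULT_GEOMETRY, **section}
    unknown = set(merged) - set(_DEFAULT_GEOMETRY) - {"angles", "start_deg"}
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'geometry'")
    try:
        if "angles" in merged:
            kwargs = {k: v for k, v in merged.items() if k not in ("n_views", "start_deg")}
            return ScanGeometry(**kwargs)
        n_views = merged.pop("n_views")
        start = merged.pop("start_deg", 0.0)
        arc = merged.pop("arc_deg")
        return ScanGeometry.circular(n_views=n_views, arc_deg=arc, start_deg=start, **merged)
    except ValueError as exc:
        raise ConfigError(f"section 'geometry': {exc}") from exc


def _build_grid(section: dict) -> GridSpec:
    merged = {**_DEFAULT_GRID, **section}
    unknown = set(merged) - {"shape", "spacing", "origin"}
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section 'grid'")
    try:
        shape = tuple(merged["shape"])
        spacing = tuple(merged["spacing"])
        if "origin" in merged:
            return GridSpec(shape=shape, spacing=spacing, origin=tuple(merged["origin"]))
        return GridSpec.centered(shape, spacing)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section 'grid': {exc}") from exc


def config_from_dict(doc: dict | None) -> PipelineConfig:
    doc = dict(doc or {})
    top_known = {"geometry", "grid", "recon", "denoise", "sim", "output_dir", "log_level"}
    unknown = set(doc) - top_known
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; known: {sorted(top_known)}"
        )
    geometry = _build_geometry(doc.get("geometry") or {})
    grid = _build_grid(doc.get("grid") or {})
    recon = _build_section(ReconOptions, doc.get("recon") or {}, "recon")
    try:
        denoise = _build_section(DenoiseParams, doc.get("denoise") or {}, "denoise")
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    sim = _build_section(SimOptions, doc.get("sim") or {}, "sim")
    return PipelineConfig(
        geometry=geometry,
        grid=grid,
        recon=recon,
        denoise=denoise,
        sim=sim,
        output_dir=str(doc.get("output_dir", "minltv_out")),
        log_level=str(doc.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML (or JSON) pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(doc)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Serializable snapshot of a config (used by the run manifest)."""
    g = cfg.geometry
    return {
        "geometry": {
            "sad": g.sad, "sdd": g.sdd,
            "det_nu": g.det_nu, "det_nv": g.det_nv,
            "det_du": g.det_du, "det_dv": g.det_dv,
            "angles": np.asarray(g.angles).tolist(), "arc_deg": g.arc_deg,
            "det_offset_u": g.det_offset_u, "det_offset_v": g.det_offset_v,
        },
        "grid": {
            "shape": list(cfg.grid.shape),
            "spacing": list(cfg.grid.spacing),
            "origin": list(cfg.grid.origin),
        },
        "recon": {f.name: getattr(cfg.recon, f.name) for f in fields(ReconOptions)},
        "denoise": {f.name: getattr(cfg.denoise, f.name) for f in fields(DenoiseParams)},
        "sim": {f.name: getattr(cfg.sim, f.name) for f in fields(SimOptions)},
        "output_dir": cfg.output_dir,
        "log_level": cfg.log_level,
    }
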