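"""Run configuration (YAML) and run manifests.

Config files are strict: unknown keys anywhere are rejected so a typo never
silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .quantify import QCThresholds
from .simulate import SimulationParams

__all__ = ["AcquisitionConfig", "AssayConfig", "FittingConfig", "RunConfig",
           "ConfigError", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


def _from_dict(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


@dataclass(frozen=True)
class AcquisitionConfig:
    roi_size: int = 432
    target_fraction: float = 0.5
    channel: str = "luminance"
    qc: QCThresholds = field(default_factory=QCThresholds)


@dataclass(frozen=True)
class AssayConfig:
    sample_volume: float = 2.5
    reagent_volume: float = 2.5
    reagent_stock_conc: float = 50.0   # µM amyloid working stock (25 µM final)
    probe_stock_conc: float = 50.0     # nM QD probe working stock (25 nM final)
    dilution_factor: float = 5.0
    n_steps: int = 8
    pipetting_count: int = 3


@dataclass(frozen=True)
class FittingConfig:
    method: str = "fourPL"
    exclude_flagged: bool = True
    free_asymptotes: bool = False
    domain: str = "extract"


@dataclass(frozen=True)
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    assay: AssayConfig = field(default_factory=AssayConfig)
    fitting: FittingConfig = field(default_factory=FittingConfig)
    seed: int = 0
    output_dir: str = "out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "acquisition" in data:
            acq = dict(data["acquisition"])
            qc = acq.pop("qc", None)
            if qc is not None:
                acq["qc"] = _from_dict(QCThresholds, qc, "acquisition.qc")
            kwargs["acquisition"] = _from_dict(AcquisitionConfig, acq, "acquisition")
        if "simulation" in data:
            sim = dict(data["simulation"])
            if "image_size" in sim:
                sim["image_size"] = tuple(sim["image_size"])
            kwargs["simulation"] = _from_dict(SimulationParams, sim, "simulation")
        if "assay" in data:
            kwargs["assay"] = _from_dict(AssayConfig, data["assay"], "assay")
        if "fitting" in data:
            kwargs["fitting"] = _from_dict(FittingConfig, data["fitting"], "fitting")
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "output_dir" in data:
            kwargs["output_dir"] = str(data["output_dir"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: RunConfig, stage: str,
                   inputs: list[str], outputs: list[str]) -> dict:
    """Write a per-stage run manifest (config hash, version, timestamps,
    input/output file lists) as JSON; returns the manifest dict."""
    from . import __version__

    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": sorted(map(str, inputs)),
        "outputs": sorted(map(str, outputs)),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
    return manifest
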