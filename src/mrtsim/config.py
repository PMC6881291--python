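"""Run configuration, bundled presets, and provenance digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .beamline import ApertureConfig, FilterElement, filtration_stack
from .errors import ConfigurationError
from .phantom import PhantomConfig, ScanConfig, ScoringMesh
from .source import MachineConfig, WigglerConfig

__all__ = ["RunConfig", "available_presets"]


def _load_preset_file() -> dict:
    with resources.files("mrtsim.presets").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_presets() -> list[str]:
    return sorted(_load_preset_file()["presets"])


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, hashable for provenance."""

    machine: MachineConfig
    wiggler: WigglerConfig
    filters: tuple[FilterElement, ...]
    apertures: ApertureConfig
    phantom: PhantomConfig
    mesh: ScoringMesh
    scan: ScanConfig
    seed: int = 1
    n_primaries: int = 100_000
    n_jobs: int = 1
    k_w: float = 1.0
    name: str = "custom"

    def __post_init__(self):
        if self.n_primaries <= 0 or self.n_jobs <= 0:
            raise ConfigurationError("n_primaries and n_jobs must be positive")
        if self.seed < 0:
            raise ConfigurationError("seed must be non-negative")

    @property
    def digest(self) -> str:
        """Stable provenance digest of the full configuration."""
        payload = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        """Build a configuration from a bundled preset such as '3T_bda1.053_mb'."""
        data = _load_preset_file()
        try:
            p = data["presets"][name]
        except KeyError:
            raise ConfigurationError(
                f"unknown preset {name!r}; available: {', '.join(sorted(data['presets']))}") from None
        d = data["defaults"]
        field_t = float(p["field"])
        kwargs = dict(
            machine=MachineConfig(**data["machine"]),
            wiggler=WigglerConfig(peak_field=field_t, **data["wiggler"]),
            filters=tuple(filtration_stack(field_t)),
            apertures=ApertureConfig(
                bda_height=float(p["bda_height"]),
                mask_width=float(p.get("mask_width", d["mask_width"])),
                msc_enabled=bool(p["msc"]),
            ),
            phantom=PhantomConfig(),
            mesh=ScoringMesh.mb() if p["mesh"] == "mb" else ScoringMesh.bb(),
            scan=ScanConfig(
                scan_speed=float(d["scan_speed"]),
                field_height=float(d["field_height"]),
                field_width=float(d["field_width"]),
                bda_height=float(p["bda_height"]),
            ),
            seed=int(d["seed"]),
            n_primaries=int(d["n_primaries"]),
            n_jobs=int(d["n_jobs"]),
            k_w=float(p.get("k_w", d["k_w"])),
            name=name,
        )
        kwargs.update(overrides)
        return cls(**kwargs)
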