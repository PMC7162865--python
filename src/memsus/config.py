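"""Run configuration: the YAML blocks every CLI entry point consumes.

A run config bundles the ``transducer:``, ``scan:``, ``pipeline:`` and
``phantom:`` blocks plus output options.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acoustics import TransducerSpec
from .beamline import PipelineParams
from .phantom_sim import PRESET_NAMES, SimulationConfig
from .scan_geometry import ScanGeometry

__all__ = ["RunConfig", "derive_seed"]


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed from one global seed.

    sha256 over ``"<base_seed>:<stage>"``, truncated to 31 bits, so each
    pipeline stage gets an independent, individually reproducible stream.
    """
    import hashlib

    digest = hashlib.sha256(f"{int(base_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF

_TOP_KEYS = {"transducer", "scan", "pipeline", "phantom", "output", "rng_seed",
             "log_level"}


@dataclass
class RunConfig:
    transducer: TransducerSpec
    scan: ScanGeometry
    pipeline: PipelineParams
    sim: SimulationConfig
    preset: str = "wire"
    duration: float = 1.0
    rng_seed: int = 0
    log_level: str = "INFO"
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: "
                f"{', '.join(PRESET_NAMES)}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @classmethod
    def default(cls) -> "RunConfig":
        spec = TransducerSpec.default()
        return cls(
            transducer=spec,
            scan=ScanGeometry.default(spec),
            pipeline=PipelineParams(),
            sim=SimulationConfig(),
        )

    def to_yaml_dict(self) -> dict:
        phantom = self.sim.to_yaml_dict()
        phantom.update({"preset": self.preset, "duration_s": self.duration})
        return {
            "transducer": self.transducer.to_yaml_dict(),
            "scan": self.scan.to_yaml_dict(),
            "pipeline": self.pipeline.to_yaml_dict(),
            "phantom": phantom,
            "rng_seed": self.rng_seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_yaml_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        spec = (
            TransducerSpec.from_yaml_dict(doc["transducer"])
            if "transducer" in doc else TransducerSpec.default()
        )
        scan = (
            ScanGeometry.from_yaml_dict(doc["scan"])
            if "scan" in doc else ScanGeometry.default(spec)
        )
        pipeline = (
            PipelineParams.from_yaml_dict(doc["pipeline"])
            if "pipeline" in doc else PipelineParams()
        )
        phantom = dict(doc.get("phantom", {}))
        preset = phantom.pop("preset", "wire")
        duration = phantom.pop("duration_s", 1.0)
        sim = SimulationConfig.from_yaml_dict(phantom)
        return cls(
            transducer=spec,
            scan=scan,
            pipeline=pipeline,
            sim=sim,
            preset=preset,
            duration=duration,
            rng_seed=int(doc.get("rng_seed", 0)),
            log_level=doc.get("log_level", "INFO"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"config file {path} is not a YAML mapping")
        return cls.from_yaml_dict(doc)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_yaml_dict(), fh, sort_keys=False)
        return path
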