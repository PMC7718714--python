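"""Pipeline configuration with YAML round-trip.

Collects every tunable of the three registration stages under one object
with a single seed.  ``PipelineConfig.load(PipelineConfig.dump(c)) == c``
holds exactly, and every CLI run writes its resolved config next to its
outputs for reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .attention import AttentionParams
from .preprocessing import PreprocessParams
from .rough import SearchGrid

__all__ = ["PipelineConfig"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All parameters of the registration pipeline.

    Stated-constant defaults: smoothing sigma 10 px, morphology radius
    20 px, 4 attention levels, 10 SIFT layers per octave, 8 strong matches.
    """

    preprocessing: PreprocessParams = field(default_factory=PreprocessParams)
    attention: AttentionParams = field(default_factory=AttentionParams)
    # rough-alignment stage
    rough_level: int = 2
    n_phases: int = 3
    lambda_boundary: float | None = None
    ms_iterations: int = 5
    grid: SearchGrid | None = None
    seed: int = 0

    # ------------------------------------------------------------- YAML I/O
    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "preprocessing": asdict(self.preprocessing),
            "attention": asdict(self.attention),
            "rough_level": self.rough_level,
            "n_phases": self.n_phases,
            "lambda_boundary": self.lambda_boundary,
            "ms_iterations": self.ms_iterations,
            "grid": None,
            "seed": self.seed,
        }
        if self.grid is not None:
            d["grid"] = {
                "theta_values": [float(v) for v in self.grid.theta_values],
                "dx_values": [float(v) for v in self.grid.dx_values],
                "dy_values": [float(v) for v in self.grid.dy_values],
                "level": self.grid.level,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        grid = None
        if d.get("grid"):
            g = d["grid"]
            grid = SearchGrid(np.asarray(g["theta_values"]), np.asarray(g["dx_values"]),
                              np.asarray(g["dy_values"]), int(g["level"]))
        return cls(
            preprocessing=PreprocessParams(**d.get("preprocessing", {})),
            attention=AttentionParams(**_untuple(d.get("attention", {}))),
            rough_level=int(d.get("rough_level", 2)),
            n_phases=int(d.get("n_phases", 3)),
            lambda_boundary=d.get("lambda_boundary"),
            ms_iterations=int(d.get("ms_iterations", 5)),
            grid=grid,
            seed=int(d.get("seed", 0)),
        )

    def dump(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValueError("config file does not contain a mapping")
        return cls.from_dict(d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PipelineConfig):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _untuple(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
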