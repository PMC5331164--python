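"""Run configuration: YAML/JSON schema and validation.

All lengths are SI meters, forces Newtons, elastic moduli Pascals; the
remodeling thresholds and healthy-strain window are in microstrain.  Any
omitted key falls back to the documented default, so an empty config is a
complete (toy-model) run specification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .geometry import ImplantModelParams
from .grid import MaterialSpec, Phase, default_materials
from .metrics import EvaluationParams
from .remodeling import RemodelingParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Complete, validated specification of a design run."""

    model: ImplantModelParams = field(default_factory=ImplantModelParams)
    materials: dict[Phase, MaterialSpec] = field(default_factory=default_materials)
    total_force: float = 3.0  # N, compressive, along -z on the abutment top
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    max_iter: int = 12
    seed: int = 0
    solver_rtol: float = 1e-9

    def __post_init__(self) -> None:
        self.model.validate()
        if self.total_force < 0:
            raise ValueError("total_force must be non-negative (magnitude)")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not (0 < self.solver_rtol < 1e-2):
            raise ValueError("solver_rtol out of range")
        for p in (Phase.CANCELLOUS, Phase.CORTICAL, Phase.IMPLANT):
            if p not in self.materials:
                raise ValueError(f"missing material for phase {p.name}")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "model": dataclasses.asdict(self.model),
            "materials": {
                p.name.lower(): dataclasses.asdict(m)
                for p, m in self.materials.items()
            },
            "total_force": self.total_force,
            "remodeling": dataclasses.asdict(self.remodeling),
            "evaluation": dataclasses.asdict(self.evaluation),
            "max_iter": self.max_iter,
            "seed": self.seed,
            "solver_rtol": self.solver_rtol,
        }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw or {})
        known = {
            "model", "materials", "total_force", "remodeling",
            "evaluation", "max_iter", "seed", "solver_rtol",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        model = ImplantModelParams(**raw.get("model", {}))
        materials = default_materials()
        for name, spec in (raw.get("materials") or {}).items():
            try:
                phase = Phase[name.upper()]
            except KeyError as exc:
                raise ValueError(f"unknown material phase {name!r}") from exc
            materials[phase] = MaterialSpec(**spec)
        return cls(
            model=model,
            materials=materials,
            total_force=raw.get("total_force", 3.0),
            remodeling=RemodelingParams(**raw.get("remodeling", {})),
            evaluation=EvaluationParams(**raw.get("evaluation", {})),
            max_iter=raw.get("max_iter", 12),
            seed=raw.get("seed", 0),
            solver_rtol=raw.get("solver_rtol", 1e-9),
        )


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load a YAML (or JSON) run config; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.from_dict(raw)
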