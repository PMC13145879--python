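"""Run configuration for the end-to-end experiment.

A single YAML file (or keyword overrides) fixes everything a run
needs: the data source (an existing manifest or a simulation block),
the classifier roster, the surface modes, fold count and every seed.
The configuration hash is recorded in all outputs so an experiment
tree is traceable to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cv import CLASSIFIER_NAMES

DEFAULT_SURFACES = ("adaxial", "abaxial", "combined")


@dataclass
class Seeds:
    data: int = 0
    folds: int = 0
    classifiers: int = 0
    layout: int = 0


@dataclass
class RunConfig:
    out_dir: Path = Path("leafcode_run")
    manifest: Path | None = None          # use an existing dataset ...
    simulate: bool = True                 # ... or generate one
    damage_rate: float | None = None      # override for the generator
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    surfaces: tuple[str, ...] = DEFAULT_SURFACES
    combined_mode: str = "combined_concat"
    k_folds: int = 10
    group_aware: bool = False
    include_damaged: bool = False
    standard_size: int = 512
    seeds: Seeds = field(default_factory=Seeds)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.manifest is not None:
            self.manifest = Path(self.manifest)
        if isinstance(self.seeds, dict):
            self.seeds = Seeds(**self.seeds)
        if not self.classifiers:
            raise ValueError("at least one classifier required")
        if not self.surfaces:
            raise ValueError("at least one surface mode required")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        unknown = set(self.surfaces) - {"adaxial", "abaxial", "combined"}
        if unknown:
            raise ValueError(f"unknown surfaces: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["manifest"] = str(self.manifest) if self.manifest else None
        d["classifiers"] = list(self.classifiers)
        d["surfaces"] = list(self.surfaces)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def surface_modes(self) -> list[str]:
        """Surface modes as feature-table modes (combined resolved)."""
        return [
            self.combined_mode if s == "combined" else s for s in self.surfaces
        ]
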