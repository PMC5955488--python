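"""Run configuration for the command-line pipeline.

One YAML (or JSON) file drives every stage; all randomness flows from the
seeds recorded here, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import THRESHOLDS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    thresholds: tuple[str, ...] = THRESHOLDS     # subset of ("1x","2x","3x")
    seed: int = 0
    output_dir: str = "povdyn_output"
    # generation
    design_scale: float = 1.0
    nonresponse: float = 0.05
    below_nonresponse_odds: float = 1.0
    # estimation
    age_degree: int = 1
    age_state_interaction: bool = True
    annualization: str = "probability"           # or "matrix"
    # analysis
    include_current_year: bool = True
    terminal_age: int = 100
    # simulation
    simulate_n: int = 10_000
    start_age: int | None = None                 # None: first fitted age
    initial_below: float | None = None           # None: quasi-stable share
    figures: bool = True

    def __post_init__(self):
        self.thresholds = tuple(self.thresholds)
        unknown = [t for t in self.thresholds if t not in THRESHOLDS]
        if unknown:
            raise ValueError(f"unknown thresholds {unknown}; "
                             f"choose from {THRESHOLDS}")
        if self.annualization not in ("probability", "matrix"):
            raise ValueError("annualization must be 'probability' or 'matrix'")
        if self.age_degree not in (1, 2):
            raise ValueError("age_degree must be 1 or 2")
        if not (0 <= self.nonresponse < 1):
            raise ValueError("nonresponse must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
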