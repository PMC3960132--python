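"""Pipeline configuration.

Defaults reproduce the published analysis settings: the pellet
discrimination thresholds (width:length ratio bounds 1.1 and 0.9-0.5,
weight cutoffs 0.5 g and 0.3 g), majority consensus over at least two
covering replicates, unit-cost global alignment scores, 1000
random-addition parsimony searches, and a 1-year calibration grid.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    # morphometric thresholds
    ratio_pronghorn_min: float = 1.1     # width:length above this -> pronghorn-like
    ratio_ovis_low: float = 0.5          # closed Ovis interval, lower bound
    ratio_ovis_high: float = 0.9         # closed Ovis interval, upper bound
    weight_large_g: float = 0.5          # above this: large ungulate
    weight_small_typical_g: float = 0.3  # small taxa typically below this

    # consensus calling
    min_coverage: int = 2                # covering replicates needed to call a site
    majority: float = 0.5                # strict-majority fraction

    # pairwise alignment scores (linear gap penalty)
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    # parsimony search
    n_starts: int = 1000
    swap: str = "SPR"                    # SPR | NNI | NONE
    seed: int = 0
    outgroup: str | None = None

    # radiocarbon calibration
    calib_step: float = 1.0              # calendar-year grid step

    # optional input/output paths (used by the CLI `run` subcommand)
    paths: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        for name in (
            "ratio_pronghorn_min", "ratio_ovis_low", "ratio_ovis_high",
            "weight_large_g", "weight_small_typical_g",
            "match_score", "mismatch_score", "gap_score", "majority",
        ):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"config field {name} must be finite, got {v!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.calib_step <= 0:
            raise ValueError("calib_step must be > 0")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.swap not in ("SPR", "NNI", "NONE"):
            raise ValueError(f"unknown swap strategy {self.swap!r}")
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineConfig":
        """Load a declarative config file; keyword overrides win (CLI flags)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data).validate()
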