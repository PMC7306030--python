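"""Run configuration: one seed and one set of knobs for the whole pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults shared by the CLI subcommands.

    All randomness in a run flows from ``seed``.  Units are fixed throughout:
    hours, mg, L, mg/L.
    """

    seed: int = 1
    output_dir: str = "."
    bootstrap_resamples: int = 1000
    vpc_replicates: int = 1000
    npde_replicates: int = 1000
    pta_virtual_subjects: int = 5000
    mic_grid: tuple[float, ...] = (0.0312, 0.0625, 0.125, 0.25, 0.5, 1.0,
                                   2.0, 4.0, 8.0)
    lloq: float = 0.04  # BLQ policy: discard below this concentration (M1)
    fit_method: str = "nm+bfgs"

    def __post_init__(self) -> None:
        for name in ("bootstrap_resamples", "vpc_replicates",
                     "npde_replicates", "pta_virtual_subjects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.seed = int(self.seed)
        self.mic_grid = tuple(float(m) for m in self.mic_grid)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
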