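"""Pipeline configuration: every threshold, window and seed in one place."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Analysis thresholds and windows.

    Defaults are the values used throughout the analysis: 5% high and 2-SD
    low activity thresholds, 15% high-responder cut, 10% QC peak, R^2 >= 0.7
    tuning-fit acceptance, >50% Jaccard similarity, >= 3 coactive neurons
    per ensemble frame, strict 95th-percentile surrogate rule with 1,000
    circular shifts, and 3 cm/s exploration speed.
    """

    high_threshold: float = 0.05  # dF/F0 fraction
    high_responder_threshold: float = 0.15
    qc_peak_threshold: float = 0.10
    r2_threshold: float = 0.7
    jaccard_threshold: float = 0.5
    min_coactive: int = 3
    surrogate_percentile: float = 95.0
    n_shifts: int = 1000
    speed_threshold_cm_s: float = 3.0
    alpha: float = 0.05
    neuropil_coeff: float = 0.5
    stimulus_window_s: float = 3.0
    plasticity_window_s: float = 10.0
    max_lag: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.surrogate_percentile < 100:
            raise ValueError("surrogate percentile must be in (0, 100)")
        for name in ("high_threshold", "high_responder_threshold",
                     "qc_peak_threshold", "r2_threshold", "jaccard_threshold",
                     "alpha", "neuropil_coeff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_coactive < 1 or self.n_shifts < 1 or self.max_lag < 1:
            raise ValueError("counts must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_toml(self, path: str | Path) -> None:
        lines = ["[pipeline]"]
        for k, v in self.to_dict().items():
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{k} = {v!r}")
            else:
                lines.append(f'{k} = "{v}"')
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("pipeline", data))
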