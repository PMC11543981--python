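"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationTable, default_calibration

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable settings of the analysis chain.

    baseline_frames
        Leading frames averaged for baseline normalization (>= 1).
    smooth_window
        Centered moving-average window for peak detection; 1 disables.
    plateau_epsilon
        Wash-out slope magnitude below which a curve counts as plateau,
        in normalized units per time unit.
    calibration
        Probability cut-offs for DL-PIRADS assignment.
    label_map
        Tissue name -> integer code in the label mask.
    """

    baseline_frames: int = 2
    smooth_window: int = 1
    plateau_epsilon: float = 0.01
    calibration: CalibrationTable = field(default_factory=default_calibration)
    label_map: dict[str, int] = field(
        default_factory=lambda: {"TSL": 1, "PLT": 2, "NAT": 3}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.plateau_epsilon < 0:
            raise ValueError("plateau_epsilon must be >= 0")
        if isinstance(self.calibration, dict):
            self.calibration = CalibrationTable(
                cut_offs=tuple(
                    (float(t), int(c)) for t, c in self.calibration["cut_offs"]
                ),
                floor_category=int(self.calibration.get("floor_category", 1)),
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration"] = {
            "cut_offs": [list(pair) for pair in self.calibration.cut_offs],
            "floor_category": self.calibration.floor_category,
        }
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
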