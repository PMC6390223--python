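"""Shared configuration: experiment layout constants and analysis settings.

The layout encodes the study geometry in the table frame (origin at the
object center, x right, y away from the actor, z up, cm): the hand start
location sits 11 cm from the table edge and 26 cm to the right of an
object placed 36 cm from the edge, i.e. at (26, -25, 0); the transport
goal is 28.5 cm to the right of the object and 3.7 cm above the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

START_POSITION = (26.0, -25.0, 0.0)
GOAL_CENTER = (28.5, 0.0, 3.7)

DEFAULT_OBJECT_LENGTH_CM = 10.0
DEFAULT_OBJECT_RADIUS_CM = 1.25

#: required logical fields -> default column names in delimited input files
DEFAULT_COLUMN_MAPPING = {
    "participant": "participant",
    "material": "material",
    "orientation_deg": "orientation_deg",
    "repetition": "repetition",
    "thumb_x": "thumb_x",
    "thumb_y": "thumb_y",
    "thumb_z": "thumb_z",
    "index_x": "index_x",
    "index_y": "index_y",
    "index_z": "index_z",
}


@dataclass
class AnalysisConfig:
    """Settings for the visibility-vs-reach grasp analysis.

    The bias is measured at ``reference_theta`` (where the two hypotheses
    agree) and predictions are built at ``target_theta`` (where they
    disagree); the target-orientation grasps are never used to fit
    anything.
    """

    reference_theta: float = 150.0
    target_theta: float = 60.0
    metric: str = "center"  # center | mean_digit
    exclusion_threshold_deg: float = 45.0
    object_length: float = DEFAULT_OBJECT_LENGTH_CM
    object_radius: float = DEFAULT_OBJECT_RADIUS_CM
    object_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    start: tuple[float, float, float] = START_POSITION
    bias_source: str = "per_participant"  # per_participant | group
    alpha: float = 0.05
    thumb_side: str = "near"
    hand: str = "right"
    column_mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_MAPPING)
    )
    delimiter: str = ","
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("center", "mean_digit"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.bias_source not in ("per_participant", "group"):
            raise ValueError(f"unknown bias_source {self.bias_source!r}")
        if not (self.object_length > 0 and self.object_radius > 0):
            raise ValueError("object dimensions must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        missing = set(DEFAULT_COLUMN_MAPPING) - set(self.column_mapping)
        if missing:
            raise ValueError(f"column_mapping missing fields: {sorted(missing)}")
        self.start = tuple(float(c) for c in self.start)
        self.object_center = tuple(float(c) for c in self.object_center)

    @property
    def start_point(self) -> np.ndarray:
        return np.asarray(self.start, dtype=float)

    @property
    def object_center_point(self) -> np.ndarray:
        return np.asarray(self.object_center, dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["start"] = list(d["start"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
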