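"""Synthetic grasp datasets with the structure the analysis assumes.

Emulates the study design — 14 participants grasping cylinders of 4
materials, 5 repetitions at each of two orientations (150° and 60°) —
under a chosen generative hypothesis:

* each participant draws a grasp-center bias magnitude from a truncated
  normal population (truncated below at 0, so biases never point away
  from the preferred side);
* each trial's intended grasp sits on the hypothesis's preferred side at
  that orientation, with idealised surface contacts perpendicular to the
  long axis (``null`` puts the grasp at the object center);
* isotropic Gaussian motor noise perturbs thumb and index independently,
  so the grasp-axis angle is noisy too and the exclusion filter is
  exercised realistically;
* a small fraction of trials are replaced by degenerate "long-axis"
  grasps spanning the cylinder ends, as occur in real sessions.

Material labels carry no geometric effect (the analysis pools across
materials); `material_bias_shift` exists as a hook for extensions and
defaults to off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .config import (
    DEFAULT_OBJECT_LENGTH_CM,
    DEFAULT_OBJECT_RADIUS_CM,
    START_POSITION,
)
from .geometry import GraspRecord, ObjectPose, surface_contacts
from .hypotheses import reach_side, visibility_side

__all__ = ["SimConfig", "sample_participant_bias", "generate_dataset"]

DEFAULT_MATERIALS = ("styrofoam", "wood", "brass", "brass_vaseline")


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study design counts."""

    n_participants: int = 14
    materials: Sequence[str] = DEFAULT_MATERIALS
    n_repetitions: int = 5
    orientations: Sequence[float] = (150.0, 60.0)
    generating_hypothesis: str = "visibility"  # visibility | reach | null
    bias_mean: float = 1.5  # cm, population mean of participant biases
    bias_sd: float = 0.5  # cm, population sd
    motor_noise_sd: float = 0.5  # cm, isotropic, per contact point
    long_axis_prob: float = 0.04
    object_length: float = DEFAULT_OBJECT_LENGTH_CM
    object_radius: float = DEFAULT_OBJECT_RADIUS_CM
    start: tuple[float, float, float] = START_POSITION
    thumb_side: str = "near"
    hand: str = "right"
    material_bias_shift: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_participants, len(self.materials), self.n_repetitions) < 1:
            raise ValueError("all design counts must be >= 1")
        if len(self.orientations) < 1:
            raise ValueError("at least one orientation is required")
        if self.generating_hypothesis not in ("visibility", "reach", "null"):
            raise ValueError(
                f"unknown generating hypothesis {self.generating_hypothesis!r}"
            )
        if self.bias_sd < 0 or self.motor_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.long_axis_prob <= 1:
            raise ValueError("long_axis_prob must be in [0, 1]")
        self.start = tuple(float(c) for c in self.start)


def sample_participant_bias(config: SimConfig, rng: np.random.Generator) -> float:
    """One participant's bias magnitude: normal truncated below at zero."""
    if config.bias_sd == 0.0:
        return float(config.bias_mean)
    a = (0.0 - config.bias_mean) / config.bias_sd
    return float(
        stats.truncnorm.rvs(
            a, np.inf, loc=config.bias_mean, scale=config.bias_sd, random_state=rng
        )
    )


def _trial_side(config: SimConfig, pose: ObjectPose, bias: float) -> int:
    h = config.generating_hypothesis
    if h == "null" or bias == 0.0:
        return 0
    if h == "visibility":
        return visibility_side(pose, config.hand)
    return reach_side(pose, config.start, bias)


def generate_dataset(config: SimConfig) -> list[GraspRecord]:
    """Emit one record per participant x orientation x material x repetition.

    The same seed always yields the identical sequence of records.
    """
    rng = np.random.default_rng(config.seed)
    poses = {
        th: ObjectPose(
            theta=th, length=config.object_length, radius=config.object_radius
        )
        for th in config.orientations
    }
    half = config.object_length / 2.0
    records: list[GraspRecord] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        bias = sample_participant_bias(config, rng)
        for theta in config.orientations:
            pose = poses[theta]
            side = _trial_side(config, pose, bias)
            for material in config.materials:
                u_intent = side * (bias + config.material_bias_shift.get(material, 0.0))
                u_intent = float(np.clip(u_intent, -half, half))
                for rep in range(1, config.n_repetitions + 1):
                    if rng.random() < config.long_axis_prob:
                        # degenerate grasp along the long axis, on the ends
                        end = rng.choice((-1.0, 1.0))
                        thumb = pose.center - end * half * pose.axis
                        index = pose.center + end * half * pose.axis
                    else:
                        thumb, index = surface_contacts(
                            pose, u_intent, config.thumb_side
                        )
                    thumb = thumb + rng.normal(0.0, config.motor_noise_sd, 3)
                    index = index + rng.normal(0.0, config.motor_noise_sd, 3)
                    records.append(
                        GraspRecord(
                            participant=pid,
                            material=str(material),
                            theta_condition=float(theta),
                            repetition=rep,
                            thumb=thumb,
                            index=index,
                        )
                    )
    return records
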