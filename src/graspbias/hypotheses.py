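"""Competing grasp-placement hypotheses on an oriented cylinder.

Two accounts of where along a cylinder people place a precision grip:

*Object visibility* — grasps shift toward the acting-hand side of the
object, leaving less of it occluded by the hand.  Operationalised purely
as side-of-midline: for a right hand the acting-hand side is the axis
end with the larger x-coordinate (no occlusion raycasting).

*Minimum reach* — grasps shift toward the side whose contact location is
closer to the hand's start position, shortening the reaching movement.
Computed from the actual candidate-to-start distances so any layout
works, not just the study's.

Both predictions are built from a bias *magnitude* measured at a
reference orientation where the hypotheses agree, then placed at the
target orientation on each hypothesis's preferred side, with idealised
contacts perpendicular to and on the surface of the object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ObjectPose, reach_distance, surface_contacts

__all__ = [
    "HYPOTHESES",
    "DegenerateSideError",
    "BiasEstimate",
    "HypothesisPrediction",
    "visibility_side",
    "reach_side",
    "build_prediction",
]

HYPOTHESES = ("visibility", "reach")


class DegenerateSideError(ValueError):
    """Neither axis end is preferred (e.g. theta = 90 for visibility)."""


@dataclass(frozen=True)
class BiasEstimate:
    """Unsigned grasp-center bias magnitude measured at a reference orientation."""

    magnitude: float
    reference_theta: float
    source: str = "per_participant"  # per_participant | group

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("bias magnitude must be non-negative")
        if self.source not in ("per_participant", "group"):
            raise ValueError(f"unknown bias source {self.source!r}")


@dataclass(frozen=True)
class HypothesisPrediction:
    """Predicted grasp at a target pose under one hypothesis."""

    hypothesis: str
    pose: ObjectPose
    u_offset: float
    thumb: np.ndarray
    index: np.ndarray

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.thumb + self.index)


def visibility_side(pose: ObjectPose, hand: str = "right") -> int:
    """Sign of the acting-hand axis end (+1 for the +axis direction).

    For the right hand this is the end with the larger x-coordinate; for
    the left hand, the smaller.  At theta = 90 the two ends share an
    x-coordinate and no side exists.
    """
    if hand not in ("right", "left"):
        raise ValueError(f"hand must be 'right' or 'left', got {hand!r}")
    ax = pose.axis[0]
    if abs(ax) < 1e-9:
        raise DegenerateSideError(
            f"theta = {pose.theta} deg: both axis ends have equal x; "
            "the hand side is undefined"
        )
    s = 1 if ax > 0 else -1
    return s if hand == "right" else -s


def reach_side(pose: ObjectPose, start, bias: float) -> int:
    """Sign of the axis end whose offset center is closer to the start."""
    if bias <= 0:
        raise ValueError("reach_side needs a strictly positive bias")
    d_plus = reach_distance(start, pose.center + bias * pose.axis)
    d_minus = reach_distance(start, pose.center - bias * pose.axis)
    if d_plus == d_minus:
        raise DegenerateSideError(
            f"theta = {pose.theta} deg: both candidate centers are "
            f"{d_plus:.6f} cm from the start; the reach side is undefined"
        )
    return 1 if d_plus < d_minus else -1


def build_prediction(
    hypothesis: str,
    bias: BiasEstimate,
    pose: ObjectPose,
    start,
    thumb_side: str = "near",
    hand: str = "right",
) -> HypothesisPrediction:
    """Place the measured bias on the hypothesis's preferred side of ``pose``.

    With zero bias both hypotheses predict a grasp at the object center.
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; choose from {HYPOTHESES}")
    if bias.magnitude == 0.0:
        u_offset = 0.0
    elif hypothesis == "visibility":
        u_offset = visibility_side(pose, hand) * bias.magnitude
    else:
        u_offset = reach_side(pose, start, bias.magnitude) * bias.magnitude
    thumb, index = surface_contacts(pose, u_offset, thumb_side)
    return HypothesisPrediction(
        hypothesis=hypothesis, pose=pose, u_offset=u_offset, thumb=thumb, index=index
    )
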