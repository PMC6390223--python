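"""Table-frame and object-frame geometry of cylinders and precision grips.

Coordinate convention (the *table frame*): origin at the object center on
the table surface, x toward the actor's right, y away from the actor,
z up.  All positions are in centimetres and the frame is right-handed.
The cylinder lies flat on the table; ``theta`` is the orientation of its
long axis in degrees, counterclockwise from +x when viewed from above.
The axis is undirected, so ``theta`` and ``theta + 180`` describe the
same pose and every pose is normalised into ``[0, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGraspError",
    "OffObjectError",
    "ObjectPose",
    "GraspRecord",
    "GraspSummary",
    "to_object_frame",
    "from_object_frame",
    "grasp_summary",
    "grasp_axis_angle",
    "is_long_axis_grasp",
    "surface_contacts",
    "reach_distance",
]

DEFAULT_LONG_AXIS_THRESHOLD_DEG = 45.0


class DegenerateGraspError(ValueError):
    """Thumb and index contact coincide; the grasp axis is undefined."""


class OffObjectError(ValueError):
    """A requested contact location falls beyond the cylinder's ends."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"non-finite coordinates: {a}")
    return a


@dataclass(frozen=True)
class ObjectPose:
    """A cylinder lying on the table: center, long-axis angle, size (cm)."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta: float = 0.0
    length: float = 10.0
    radius: float = 1.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_point(self.center))
        object.__setattr__(self, "theta", float(self.theta) % 180.0)
        if not (self.length > 0 and self.radius > 0):
            raise ValueError("length and radius must be positive")
        if not self.length > 2 * self.radius:
            raise ValueError("cylinder must be longer than its diameter")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the long axis (one of the two directions)."""
        t = np.deg2rad(self.theta)
        return np.array([np.cos(t), np.sin(t), 0.0])

    @property
    def normal(self) -> np.ndarray:
        """In-plane unit vector perpendicular to the long axis."""
        t = np.deg2rad(self.theta)
        return np.array([-np.sin(t), np.cos(t), 0.0])


@dataclass(frozen=True)
class GraspRecord:
    """One trial: design labels plus the two fingertip contact points."""

    participant: str
    material: str
    theta_condition: float
    repetition: int
    thumb: np.ndarray
    index: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "thumb", _as_point(self.thumb))
        object.__setattr__(self, "index", _as_point(self.index))
        if np.array_equal(self.thumb, self.index):
            raise DegenerateGraspError(
                f"thumb and index coincide at {self.thumb} "
                f"(participant={self.participant}, material={self.material}, "
                f"repetition={self.repetition})"
            )

    @property
    def center(self) -> np.ndarray:
        """Grasp center: midpoint of the thumb and index contacts."""
        return 0.5 * (self.thumb + self.index)

    def sort_key(self) -> tuple:
        return (str(self.participant), str(self.material), int(self.repetition))


@dataclass(frozen=True)
class GraspSummary:
    """Per-grasp derived quantities in the object frame."""

    center: np.ndarray
    u: float
    grasp_axis_angle: float


def to_object_frame(p, pose: ObjectPose) -> tuple[float, float, float]:
    """Express a table-frame point in the object frame.

    Returns ``(u, v, w)``: u along the long axis (signed; the object
    midline is the plane u = 0), v transverse in the table plane, w
    vertical.
    """
    d = _as_point(p) - pose.center
    return float(d @ pose.axis), float(d @ pose.normal), float(d[2])


def from_object_frame(uvw, pose: ObjectPose) -> np.ndarray:
    """Inverse of :func:`to_object_frame`."""
    u, v, w = (float(c) for c in uvw)
    return pose.center + u * pose.axis + v * pose.normal + np.array([0.0, 0.0, w])


def grasp_axis_angle(g: GraspRecord, pose: ObjectPose) -> float:
    """Acute angle (degrees) between the thumb–index line and the long axis.

    Both lines are undirected, so the result is in [0, 90].
    """
    d = g.index - g.thumb
    cos = abs(d @ pose.axis) / np.linalg.norm(d)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def grasp_summary(g: GraspRecord, pose: ObjectPose) -> GraspSummary:
    """Grasp center, its signed long-axis deviation, and the grasp-axis angle."""
    center = g.center
    u, _, _ = to_object_frame(center, pose)
    return GraspSummary(center=center, u=u, grasp_axis_angle=grasp_axis_angle(g, pose))


def is_long_axis_grasp(
    g: GraspRecord,
    pose: ObjectPose,
    angle_threshold: float = DEFAULT_LONG_AXIS_THRESHOLD_DEG,
) -> bool:
    """True for grasps oriented along the long axis (on the cylinder ends).

    A grasp is flagged when the acute angle between its thumb–index line
    and the long axis is below ``angle_threshold`` (default 45°, which
    splits grasps into across-the-axis vs along-the-axis with no gap).
    Flagged grasps are excluded from the bias analysis.
    """
    return grasp_axis_angle(g, pose) < float(angle_threshold)


def surface_contacts(
    pose: ObjectPose, u_offset: float, thumb_side: str = "near"
) -> tuple[np.ndarray, np.ndarray]:
    """Idealised precision-grip contacts on the cylinder's curved surface.

    Contacts are diametrically opposite in the table plane at long-axis
    coordinate ``u_offset``: the grasp axis is perpendicular to the long
    axis and the contacts are ``2 * radius`` apart.  ``thumb_side='near'``
    puts the thumb on the actor-near side (smaller y), as in a right-hand
    precision grip approaching from the right; ``'far'`` swaps the digits.
    """
    u_offset = float(u_offset)
    if abs(u_offset) > pose.length / 2:
        raise OffObjectError(
            f"|u_offset| = {abs(u_offset):.3f} cm exceeds half-length "
            f"{pose.length / 2:.3f} cm"
        )
    if thumb_side not in ("near", "far"):
        raise ValueError(f"thumb_side must be 'near' or 'far', got {thumb_side!r}")
    on_axis = pose.center + u_offset * pose.axis
    n = pose.normal
    a, b = on_axis - pose.radius * n, on_axis + pose.radius * n
    # thumb on the smaller-y side; at theta=90 (n along -x) fall back to smaller x
    if abs(a[1] - b[1]) > 1e-9:
        thumb, index = (a, b) if a[1] < b[1] else (b, a)
    else:
        thumb, index = (a, b) if a[0] < b[0] else (b, a)
    if thumb_side == "far":
        thumb, index = index, thumb
    return thumb, index


def reach_distance(start, p) -> float:
    """Euclidean distance (cm) from the hand start location to a point."""
    return float(np.linalg.norm(_as_point(p) - _as_point(start)))
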