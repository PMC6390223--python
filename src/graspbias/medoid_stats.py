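"""Medoid statistics over grasps and the paired comparison test.

The medoid of a set, under a distance, is the *element* of the set that
minimises its summed distance to all other elements — unlike the mean it
is always a member of the set, which keeps a summary grasp physically
realisable (actual contact points on the object).

Two grasp distances are provided:

``center``
    Euclidean distance between grasp centers.  Robust to thumb/index
    labelling errors; the default, since the bias and the hypothesis
    predictions are stated in terms of the grasp center.
``mean_digit``
    Mean of the thumb–thumb and index–index Euclidean distances.  A
    sensitivity-analysis alternative that is sensitive to full grasp
    configuration.

Both satisfy the metric axioms (non-negativity, symmetry, triangle
inequality) because each is a norm of differences / a mean of norms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .geometry import GraspRecord

__all__ = [
    "GRASP_METRICS",
    "DegenerateTestError",
    "PairedTestResult",
    "grasp_distance",
    "pairwise_distances",
    "medoid",
    "medoid_index",
    "paired_t_test",
]

GRASP_METRICS = ("center", "mean_digit")


class DegenerateTestError(ValueError):
    """The paired differences have zero variance but a nonzero mean."""


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired-samples t-test outcome."""

    t: float
    df: int
    p: float
    mean_difference: float


def _check_metric(metric: str) -> None:
    if metric not in GRASP_METRICS:
        raise ValueError(f"unknown grasp metric {metric!r}; choose from {GRASP_METRICS}")


def grasp_distance(a: GraspRecord, b: GraspRecord, metric: str = "center") -> float:
    """Distance in cm between two grasps under the chosen metric."""
    _check_metric(metric)
    if metric == "center":
        return float(np.linalg.norm(a.center - b.center))
    return float(
        0.5 * (np.linalg.norm(a.thumb - b.thumb) + np.linalg.norm(a.index - b.index))
    )


def pairwise_distances(
    grasps: Sequence[GraspRecord], metric: str = "center"
) -> np.ndarray:
    """Full pairwise distance matrix for a sequence of grasps."""
    _check_metric(metric)
    if metric == "center":
        centers = np.array([g.center for g in grasps])
        return cdist(centers, centers)
    thumbs = np.array([g.thumb for g in grasps])
    indexes = np.array([g.index for g in grasps])
    return 0.5 * (cdist(thumbs, thumbs) + cdist(indexes, indexes))


def medoid_index(grasps: Sequence[GraspRecord], metric: str = "center") -> int:
    """Index of the medoid; ties broken by earliest position in the input."""
    if len(grasps) == 0:
        raise ValueError("medoid of an empty sequence is undefined")
    sums = pairwise_distances(grasps, metric).sum(axis=1)
    return int(np.argmin(sums))  # argmin returns the first minimiser


def medoid(grasps: Sequence[GraspRecord], metric: str = "center") -> GraspRecord:
    """The element minimising its summed distance to all elements."""
    return grasps[medoid_index(grasps, metric)]


def paired_t_test(d1: Sequence[float], d2: Sequence[float]) -> PairedTestResult:
    """Two-sided paired-samples t-test on ``d1 - d2``.

    Identical samples (all differences zero) return t = 0, p = 1; a
    zero-variance difference with nonzero mean has no finite statistic
    and raises :class:`DegenerateTestError`.
    """
    x = np.asarray(d1, dtype=float)
    y = np.asarray(d2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("d1 and d2 must be equal-length 1-D sequences")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    diff = x - y
    mean_diff = float(diff.mean())
    if np.ptp(diff) == 0.0:
        if mean_diff == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_difference=0.0)
        raise DegenerateTestError(
            "all paired differences are identical and nonzero; t is undefined"
        )
    res = stats.ttest_rel(x, y)
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean_difference=mean_diff
    )
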