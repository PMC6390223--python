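"""Scatter figure of per-participant medoid grasp centers vs. both predictions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import AnalysisConfig
from .hypotheses import BiasEstimate, build_prediction
from .geometry import ObjectPose
from .pipeline import ComparisonResult


def plot_comparison(
    result: ComparisonResult, config: AnalysisConfig, path: str | Path
) -> Path:
    """Plot target-orientation medoid deviations against the two predictions.

    The long-axis coordinate u (cm from the object midline) is the only
    axis the hypotheses disagree on, so the figure is a one-dimensional
    strip plot: small markers per participant, large markers for the two
    predicted offsets built from the group-level bias.
    """
    tgt = float(config.target_theta) % 180.0
    pose = ObjectPose(
        center=config.object_center_point,
        theta=tgt,
        length=config.object_length,
        radius=config.object_radius,
    )
    bias = BiasEstimate(
        magnitude=result.bias_reference_cm,
        reference_theta=float(config.reference_theta) % 180.0,
        source="group",
    )
    fig, ax = plt.subplots(figsize=(6, 2.8))
    ax.axvline(0.0, color="0.6", lw=1, label="object midline")
    ax.plot(
        result.target_medoid_u,
        [0.0] * len(result.target_medoid_u),
        "o",
        ms=5,
        alpha=0.6,
        color="k",
        label="participant medoids",
    )
    for h, color in (("visibility", "tab:blue"), ("reach", "tab:orange")):
        pred = build_prediction(
            h, bias, pose, config.start_point, config.thumb_side, config.hand
        )
        ax.plot(pred.u_offset, 0.0, "D", ms=12, mfc="none", mec=color,
                label=f"{h} prediction")
    ax.set_yticks([])
    ax.set_xlabel(f"deviation from midline along the long axis (cm), {tgt:g}°")
    ax.legend(loc="upper left", fontsize=8, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
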