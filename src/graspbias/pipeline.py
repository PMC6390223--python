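"""End-to-end analysis: load, filter, summarise, predict, test, report.

The analysis logic, in order:

1. keep only the reference (150°) and target (60°) orientations and drop
   long-axis grasps (thumb–index line within the exclusion threshold of
   the long axis);
2. per participant and orientation, compute the medoid grasp over the
   retained materials x repetitions trials;
3. compute the group medoid across the per-participant medoids (same
   metric throughout);
4. measure the grasp-center bias along the long axis at the reference
   orientation, where the visibility and reach accounts agree;
5. build both hypotheses' predicted grasps at the target orientation
   from that bias (the target-orientation data never feed the
   predictions, so the comparison is not circular);
6. per participant, measure the distance from the target-orientation
   medoid to each predicted grasp;
7. compare the two distance samples with a two-sided paired t-test and
   declare a winner at the configured alpha.

Medoid ties are broken on (participant, material, repetition) sort order
so every reported number is independent of input row order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_COLUMN_MAPPING
from .geometry import (
    GraspRecord,
    ObjectPose,
    grasp_summary,
    is_long_axis_grasp,
)
from .hypotheses import BiasEstimate, HypothesisPrediction, build_prediction
from .medoid_stats import PairedTestResult, medoid, paired_t_test

__all__ = [
    "ComparisonResult",
    "load_records",
    "write_records",
    "run_analysis",
    "report",
    "load_result",
    "format_report",
]

logger = logging.getLogger("graspbias")

_COORD_FIELDS = ("thumb_x", "thumb_y", "thumb_z", "index_x", "index_y", "index_z")


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the visibility-vs-reach comparison."""

    n_participants: int
    participants: tuple[str, ...]
    d_visibility: tuple[float, ...]
    d_reach: tuple[float, ...]
    excluded_fraction: float
    excluded_by_orientation: dict[float, tuple[int, int]]  # theta -> (excluded, total)
    bias_reference_cm: float
    per_participant_bias_cm: tuple[float, ...]
    test: PairedTestResult
    alpha: float
    winner: str  # visibility | reach | inconclusive
    target_medoid_u: tuple[float, ...]
    group_medoid_u: dict[float, float]  # theta -> group-medoid long-axis deviation


def load_records(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[GraspRecord]:
    """Read grasp records from a delimited text file with a header row.

    ``column_mapping`` maps the logical field names (participant,
    material, orientation_deg, repetition, thumb_x .. index_z) to the
    file's column names.  Malformed rows raise with their line numbers.
    """
    mapping = dict(column_mapping or DEFAULT_COLUMN_MAPPING)
    missing_fields = set(DEFAULT_COLUMN_MAPPING) - set(mapping)
    if missing_fields:
        raise ValueError(f"column_mapping missing fields: {sorted(missing_fields)}")
    df = pd.read_csv(path, sep=delimiter)
    missing_cols = [c for c in mapping.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    bad: list[str] = []
    records: list[GraspRecord] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        coords = [row[mapping[f]] for f in _COORD_FIELDS]
        try:
            coords = [float(c) for c in coords]
        except (TypeError, ValueError):
            bad.append(f"line {line_no}: non-numeric coordinate")
            continue
        if not np.all(np.isfinite(coords)):
            bad.append(f"line {line_no}: non-finite coordinate")
            continue
        try:
            theta = float(row[mapping["orientation_deg"]])
            records.append(
                GraspRecord(
                    participant=str(row[mapping["participant"]]),
                    material=str(row[mapping["material"]]),
                    theta_condition=theta,
                    repetition=int(row[mapping["repetition"]]),
                    thumb=np.array(coords[:3]),
                    index=np.array(coords[3:]),
                )
            )
        except (TypeError, ValueError) as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise ValueError(f"{path}: {len(bad)} malformed row(s):\n" + "\n".join(bad))
    logger.info("loaded %d grasp records from %s", len(records), path)
    return records


def write_records(
    records: Sequence[GraspRecord],
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write records in the dialect :func:`load_records` reads.

    Coordinates are written with 6 decimals, so identical record
    sequences produce byte-identical files.
    """
    mapping = dict(column_mapping or DEFAULT_COLUMN_MAPPING)
    rows = []
    for g in records:
        rows.append(
            {
                mapping["participant"]: g.participant,
                mapping["material"]: g.material,
                mapping["orientation_deg"]: g.theta_condition,
                mapping["repetition"]: g.repetition,
                mapping["thumb_x"]: g.thumb[0],
                mapping["thumb_y"]: g.thumb[1],
                mapping["thumb_z"]: g.thumb[2],
                mapping["index_x"]: g.index[0],
                mapping["index_y"]: g.index[1],
                mapping["index_z"]: g.index[2],
            }
        )
    cols = [mapping[f] for f in DEFAULT_COLUMN_MAPPING]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=delimiter, index=False, float_format="%.6f"
    )


def _prediction_distance(
    g: GraspRecord, pred: HypothesisPrediction, metric: str
) -> float:
    if metric == "center":
        return float(np.linalg.norm(g.center - pred.center))
    return float(
        0.5
        * (np.linalg.norm(g.thumb - pred.thumb) + np.linalg.norm(g.index - pred.index))
    )


def run_analysis(
    records: Sequence[GraspRecord], config: AnalysisConfig | None = None
) -> ComparisonResult:
    """Run the full visibility-vs-reach comparison on grasp records."""
    config = config or AnalysisConfig()
    ref_theta = float(config.reference_theta) % 180.0
    tgt_theta = float(config.target_theta) % 180.0
    if ref_theta == tgt_theta:
        raise ValueError("reference and target orientations must differ")
    poses = {
        th: ObjectPose(
            center=config.object_center_point,
            theta=th,
            length=config.object_length,
            radius=config.object_radius,
        )
        for th in (ref_theta, tgt_theta)
    }
    analyzed = [r for r in records if float(r.theta_condition) % 180.0 in poses]
    if not analyzed:
        raise ValueError(
            f"no records at orientations {sorted(poses)} among {len(records)} rows"
        )
    # stable, file-order-independent processing order
    analyzed.sort(key=lambda g: (g.sort_key(), float(g.theta_condition)))

    retained: dict[float, dict[str, list[GraspRecord]]] = {th: {} for th in poses}
    excl_counts = {th: [0, 0] for th in poses}  # theta -> [excluded, total]
    for g in analyzed:
        th = float(g.theta_condition) % 180.0
        excl_counts[th][1] += 1
        if is_long_axis_grasp(g, poses[th], config.exclusion_threshold_deg):
            excl_counts[th][0] += 1
            continue
        retained[th].setdefault(g.participant, []).append(g)
    n_excl = sum(c[0] for c in excl_counts.values())
    n_tot = sum(c[1] for c in excl_counts.values())
    excluded_fraction = n_excl / n_tot
    for th in poses:
        logger.info(
            "orientation %g deg: %d/%d grasps excluded as long-axis",
            th,
            *excl_counts[th],
        )

    participants = sorted(set(retained[ref_theta]) | set(retained[tgt_theta]))
    empty = [
        p
        for p in participants
        if not retained[ref_theta].get(p) or not retained[tgt_theta].get(p)
    ]
    if empty:
        raise ValueError(
            "participant(s) with no retained grasps at a required orientation: "
            + ", ".join(empty)
        )

    # per-participant medoids, then the group medoid over them
    p_medoid: dict[float, dict[str, GraspRecord]] = {
        th: {p: medoid(retained[th][p], config.metric) for p in participants}
        for th in poses
    }
    group_medoid_u = {}
    for th, pose in poses.items():
        group_med = medoid([p_medoid[th][p] for p in participants], config.metric)
        group_medoid_u[th] = grasp_summary(group_med, pose).u

    ref_pose, tgt_pose = poses[ref_theta], poses[tgt_theta]
    per_bias = tuple(
        grasp_summary(p_medoid[ref_theta][p], ref_pose).u for p in participants
    )
    group_bias = abs(float(np.mean(per_bias)))

    d_vis, d_reach, tgt_u = [], [], []
    for p, u_ref in zip(participants, per_bias):
        magnitude = abs(u_ref) if config.bias_source == "per_participant" else group_bias
        bias = BiasEstimate(
            magnitude=magnitude,
            reference_theta=ref_theta,
            source=config.bias_source,
        )
        preds = {
            h: build_prediction(
                h, bias, tgt_pose, config.start_point, config.thumb_side, config.hand
            )
            for h in ("visibility", "reach")
        }
        g_tgt = p_medoid[tgt_theta][p]
        d_vis.append(_prediction_distance(g_tgt, preds["visibility"], config.metric))
        d_reach.append(_prediction_distance(g_tgt, preds["reach"], config.metric))
        tgt_u.append(grasp_summary(g_tgt, tgt_pose).u)

    # difference taken as reach - visibility: t > 0 when visibility wins
    test = paired_t_test(d_reach, d_vis)
    if test.p < config.alpha:
        winner = "visibility" if np.mean(d_vis) < np.mean(d_reach) else "reach"
    else:
        winner = "inconclusive"
    logger.info(
        "t(%d) = %.3f, p = %.3g -> winner: %s", test.df, test.t, test.p, winner
    )

    return ComparisonResult(
        n_participants=len(participants),
        participants=tuple(participants),
        d_visibility=tuple(d_vis),
        d_reach=tuple(d_reach),
        excluded_fraction=excluded_fraction,
        excluded_by_orientation={
            th: (c[0], c[1]) for th, c in excl_counts.items()
        },
        bias_reference_cm=group_bias,
        per_participant_bias_cm=per_bias,
        test=test,
        alpha=config.alpha,
        winner=winner,
        target_medoid_u=tuple(tgt_u),
        group_medoid_u=group_medoid_u,
    )


def _result_dict(result: ComparisonResult) -> dict:
    return {
        "n_participants": result.n_participants,
        "participants": list(result.participants),
        "d_visibility": list(result.d_visibility),
        "d_reach": list(result.d_reach),
        "excluded_fraction": result.excluded_fraction,
        "excluded_by_orientation": {
            str(th): list(c) for th, c in result.excluded_by_orientation.items()
        },
        "bias_reference_cm": result.bias_reference_cm,
        "per_participant_bias_cm": list(result.per_participant_bias_cm),
        "test": {
            "t": result.test.t,
            "df": result.test.df,
            "p": result.test.p,
            "mean_difference": result.test.mean_difference,
        },
        "alpha": result.alpha,
        "winner": result.winner,
        "target_medoid_u": list(result.target_medoid_u),
        "group_medoid_u": {str(th): u for th, u in result.group_medoid_u.items()},
    }


def format_report(result: ComparisonResult) -> str:
    """Human-readable text block summarising a comparison result."""
    mv, mr = np.mean(result.d_visibility), np.mean(result.d_reach)
    smaller = "visibility" if mv < mr else "reach"
    lines = [
        "Grasp-bias comparison: object visibility vs. minimum reach",
        f"  participants:            {result.n_participants}",
        f"  long-axis grasps excluded: {100 * result.excluded_fraction:.1f}%",
        f"  reference bias (group):  {result.bias_reference_cm:.3f} cm",
        f"  mean distance to visibility prediction: {mv:.3f} cm",
        f"  mean distance to reach prediction:      {mr:.3f} cm",
        f"  smaller mean distance:   {smaller} prediction",
        f"  paired t-test: t({result.test.df}) = {result.test.t:.3f}, "
        f"p = {result.test.p:.3g} (alpha = {result.alpha})",
        f"  winner: {result.winner}",
    ]
    return "\n".join(lines)


def report(result: ComparisonResult, path: str | Path) -> Path:
    """Write a machine-readable JSON summary plus the text block.

    The JSON keeps full float precision, so a result survives a
    write/read round-trip unchanged.
    """
    path = Path(path)
    payload = _result_dict(result)
    payload["text"] = format_report(result)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    logger.info("wrote report to %s", path)
    return path


def load_result(path: str | Path) -> ComparisonResult:
    """Parse a JSON report back into a :class:`ComparisonResult`."""
    with open(path) as fh:
        d = json.load(fh)
    return ComparisonResult(
        n_participants=int(d["n_participants"]),
        participants=tuple(d["participants"]),
        d_visibility=tuple(d["d_visibility"]),
        d_reach=tuple(d["d_reach"]),
        excluded_fraction=float(d["excluded_fraction"]),
        excluded_by_orientation={
            float(th): tuple(c) for th, c in d["excluded_by_orientation"].items()
        },
        bias_reference_cm=float(d["bias_reference_cm"]),
        per_participant_bias_cm=tuple(d["per_participant_bias_cm"]),
        test=PairedTestResult(
            t=float(d["test"]["t"]),
            df=int(d["test"]["df"]),
            p=float(d["test"]["p"]),
            mean_difference=float(d["test"]["mean_difference"]),
        ),
        alpha=float(d["alpha"]),
        winner=d["winner"],
        target_medoid_u=tuple(d["target_medoid_u"]),
        group_medoid_u={float(th): u for th, u in d["group_medoid_u"].items()},
    )
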