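"""Accuracy metrics and detection/ground-truth matching.

Per needle, the axis error is the angular deviation beta (degrees, folded
into [0, 90]) and the tip error xi is the Euclidean distance (mm) on the
slice.  Detections are matched to ground-truth needles by a one-to-one
assignment minimising beta with xi as the tie-break; the detection rate is
matched detections / implanted needles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import LineModel, Point2D, angular_deviation, tip_deviation
from .pipeline import NeedleDetection

__all__ = [
    "NeedleTruth",
    "match_detections",
    "evaluate_detections",
    "write_detections",
    "read_detections",
]


@dataclass(frozen=True)
class NeedleTruth:
    axis: LineModel
    tip: Point2D


def match_detections(detections, truths,
                     beta_gate: float | None = None,
                     xi_gate: float | None = None) -> list[tuple[int, int]]:
    """One-to-one (detection, truth) index pairs minimising beta then xi.

    Optional gates discard assigned pairs whose beta (degrees) or xi (mm)
    exceed the bound; unmatched entries on either side are simply absent
    from the result (missed / spurious, not an error).
    """
    if not detections or not truths:
        return []
    beta = np.array([[angular_deviation(d.axis, t.axis) for t in truths]
                     for d in detections])
    xi = np.array([[tip_deviation(d.tip, t.tip) for t in truths]
                   for d in detections])
    # beta dominates; xi only breaks near-ties (both are bounded quantities).
    cost = beta + 1e-3 * xi
    ri, ci = linear_sum_assignment(cost)
    pairs = []
    for i, j in zip(ri, ci):
        if beta_gate is not None and beta[i, j] > beta_gate:
            continue
        if xi_gate is not None and xi[i, j] > xi_gate:
            continue
        pairs.append((int(i), int(j)))
    return pairs


def evaluate_detections(detections, truths,
                        beta_gate: float | None = None,
                        xi_gate: float | None = None):
    """Per-needle error table and summary statistics.

    Returns ``(table, summary)``: the table has one row per matched pair
    (needle_id, truth_id, beta_deg, xi_mm); the summary dict holds
    mean/sd of both metrics, the counts, and the detection rate.
    """
    pairs = match_detections(detections, truths, beta_gate, xi_gate)
    rows = [{"needle_id": i, "truth_id": j,
             "beta_deg": angular_deviation(detections[i].axis, truths[j].axis),
             "xi_mm": tip_deviation(detections[i].tip, truths[j].tip)}
            for i, j in pairs]
    table = pd.DataFrame(rows, columns=["needle_id", "truth_id", "beta_deg", "xi_mm"])
    n_matched = len(pairs)
    sd = (lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"))
    summary = {
        "n_true": len(truths),
        "n_detected": len(detections),
        "n_matched": n_matched,
        "detection_rate": (n_matched / len(truths) if truths else float("nan")),
        "beta_mean_deg": float(table.beta_deg.mean()) if n_matched else float("nan"),
        "beta_sd_deg": sd(table.beta_deg.to_numpy()) if n_matched else float("nan"),
        "xi_mean_mm": float(table.xi_mm.mean()) if n_matched else float("nan"),
        "xi_sd_mm": sd(table.xi_mm.to_numpy()) if n_matched else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------------
# Detection serialisation (JSON; CSV via the same records)
# ---------------------------------------------------------------------------

def _detection_record(det: NeedleDetection) -> dict:
    return {
        "needle_id": int(det.order),
        "anchor_x_mm": det.axis.anchor.x,
        "anchor_y_mm": det.axis.anchor.y,
        "dir_x": det.axis.direction[0],
        "dir_y": det.axis.direction[1],
        "tip_x_mm": det.tip.x,
        "tip_y_mm": det.tip.y,
        "entry_x_mm": det.entry.x,
        "entry_y_mm": det.entry.y,
        "n_inliers": int(det.support),
        "sigma_mm": float(det.sigma),
    }


def write_detections(detections, json_path=None, csv_path=None) -> None:
    records = [_detection_record(d) for d in detections]
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump({"needles": records}, fh, indent=2)
    if csv_path is not None:
        pd.DataFrame(records, columns=list(_detection_record(
            _dummy_detection()).keys()) if not records else None).to_csv(
                csv_path, index=False)


def read_detections(json_path) -> list[NeedleDetection]:
    """Read detections written by :func:`write_detections` (field-by-field
    round trip; inlier index sets are not serialised)."""
    with open(json_path) as fh:
        obj = json.load(fh)
    out = []
    for rec in obj["needles"]:
        axis = LineModel(Point2D(rec["anchor_x_mm"], rec["anchor_y_mm"]),
                         (rec["dir_x"], rec["dir_y"]))
        out.append(NeedleDetection(
            axis=axis,
            tip=Point2D(rec["tip_x_mm"], rec["tip_y_mm"]),
            entry=Point2D(rec["entry_x_mm"], rec["entry_y_mm"]),
            inlier_indices=np.arange(rec["n_inliers"]),
            order=rec["needle_id"],
            sigma=rec["sigma_mm"],
        ))
    return out


def _dummy_detection() -> NeedleDetection:
    axis = LineModel(Point2D(0.0, 0.0), (1.0, 0.0))
    return NeedleDetection(axis, Point2D(1.0, 0.0), Point2D(0.0, 0.0),
                           np.array([], dtype=int), 0, 0.0)
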