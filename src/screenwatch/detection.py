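"""Face-detection harness: thresholding, ROC analysis, operating-point
selection and evaluation against gold face annotations.

The convolutional detector itself is a pluggable backend (any callable
mapping a frame to candidate faces with scores); the simulator supplies a
synthetic one. What this module owns is the score-threshold machinery: the
receiver operating curve over thresholds, the operating point trading
sensitivity against false positives per second of recording, and the
sensitivity/PPV evaluation. True negatives are meaningless for detection
(everything that is not a face), so accuracy, specificity and NPV are
deliberately not reported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .session import (
    WATCHING,
    NOT_WATCHING,
    CandidateFace,
    FrameObservation,
    GoldLog,
    TARGET,
)

#: a detector backend maps one frame to candidate faces with scores
DetectorBackend = Callable[[FrameObservation], list[CandidateFace]]

DEFAULT_IOU_MIN = 0.5
#: operating-point constraints mirroring the calibrated device
DEFAULT_MIN_SENSITIVITY = 0.925
DEFAULT_MAX_FP_PER_S = 0.79


class OperatingPointError(ValueError):
    """No threshold satisfies the requested constraints."""


def apply_threshold(faces: Sequence[CandidateFace], tau_d: float) -> list[CandidateFace]:
    """Keep the faces with detector score >= tau_d, order preserved."""
    if not 0.0 <= tau_d <= 1.0:
        raise ValueError("tau_d must be in [0, 1]")
    return [f for f in faces if f.score >= tau_d]


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def match_to_gold(
    pred_boxes: Sequence[Sequence[float]],
    gold_boxes: Sequence[Sequence[float]],
    iou_min: float = DEFAULT_IOU_MIN,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one box matching in descending IoU.

    Returns (matched (pred_idx, gold_idx) pairs, unmatched pred indices,
    unmatched gold indices). Pairs below ``iou_min`` never match. Matched
    pairs are detection true positives, unmatched predictions false
    positives, unmatched gold faces false negatives.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must be in (0, 1]")
    pairs = []
    for pi, pb in enumerate(pred_boxes):
        for gi, gb in enumerate(gold_boxes):
            val = iou(pb, gb)
            if val >= iou_min:
                pairs.append((val, pi, gi))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    matched = []
    for _, pi, gi in pairs:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        matched.append((pi, gi))
    unmatched_pred = [i for i in range(len(pred_boxes)) if i not in used_p]
    unmatched_gold = [i for i in range(len(gold_boxes)) if i not in used_g]
    return matched, unmatched_pred, unmatched_gold


@dataclass
class RocTable:
    """Detector ROC: one row per score threshold, thresholds strictly
    decreasing; sensitivity and FP/s are both non-decreasing downward."""

    table: pd.DataFrame  # columns: threshold, sensitivity, fp_per_second

    def __post_init__(self) -> None:
        cols = ["threshold", "sensitivity", "fp_per_second"]
        if list(self.table.columns) != cols:
            raise ValueError(f"RocTable columns must be {cols}")
        thr = self.table["threshold"].to_numpy()
        if len(thr) and not np.all(np.diff(thr) < 0):
            raise ValueError("thresholds must be strictly decreasing")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RocTable":
        return cls(pd.read_csv(path))


def build_roc(
    frames: Iterable[FrameObservation],
    thresholds: Sequence[float],
    fps: float,
    iou_min: float = DEFAULT_IOU_MIN,
) -> RocTable:
    """ROC over score thresholds against per-frame gold boxes.

    sensitivity = TP / (TP + FN) over all gold faces; FP/s = total false
    positives divided by the total wall-time the frames span (frame count
    / fps), not just frames containing faces.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    frames = list(frames)
    n_gold = sum(len(f.gold_faces) for f in frames)
    if n_gold == 0:
        raise ValueError("no gold faces: sensitivity undefined")
    seconds = len(frames) / fps
    rows = []
    for tau in sorted(set(float(t) for t in thresholds), reverse=True):
        tp = fp = 0
        for frame in frames:
            kept = apply_threshold(frame.faces, tau)
            matched, unmatched_pred, _ = match_to_gold(
                [f.box for f in kept], [g.box for g in frame.gold_faces], iou_min)
            tp += len(matched)
            fp += len(unmatched_pred)
        rows.append((tau, tp / n_gold, fp / seconds))
    return RocTable(pd.DataFrame(rows, columns=["threshold", "sensitivity",
                                                "fp_per_second"]))


def select_operating_point(
    roc: RocTable,
    min_sensitivity: float = DEFAULT_MIN_SENSITIVITY,
    max_fp_per_s: float = DEFAULT_MAX_FP_PER_S,
) -> float:
    """Largest threshold with sensitivity >= min_sensitivity and
    FP/s <= max_fp_per_s; failing that, the threshold maximizing
    sensitivity subject to the FP/s cap alone.

    The chosen point deliberately tolerates false positives in exchange
    for few missed faces — downstream verification screens most spurious
    detections out.
    """
    df = roc.table
    if df.empty:
        raise OperatingPointError("empty ROC table")
    feasible = df[(df["sensitivity"] >= min_sensitivity)
                  & (df["fp_per_second"] <= max_fp_per_s)]
    if len(feasible):
        return float(feasible["threshold"].max())
    fallback = df[df["fp_per_second"] <= max_fp_per_s]
    if len(fallback):
        best = fallback.loc[fallback["sensitivity"].idxmax()]
        return float(best["threshold"])
    frontier = df[["threshold", "sensitivity", "fp_per_second"]].to_dict("records")
    raise OperatingPointError(
        f"no threshold satisfies FP/s <= {max_fp_per_s}; attainable frontier: "
        f"{frontier}")


def _metrics(tp: int, fp: int, fn: int, seconds: float) -> dict:
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "fp_per_second": fp / seconds if seconds > 0 else None,
    }


def evaluate_detection(
    frames: Iterable[FrameObservation],
    gold_log: GoldLog,
    tau_d: float,
    fps: float,
    iou_min: float = DEFAULT_IOU_MIN,
) -> dict:
    """Sensitivity, PPV and FP/s at threshold tau_d, overall and stratified
    by the gold gaze code of the frame.

    The overall row counts every person's gold face; the gaze-on /
    gaze-off strata restrict the gold set to the target child's face on
    frames coded watching / not watching, the regime in which the device
    must perform. Frames coded out-of-frame or cannot-tell contribute only
    to the overall row. Empty strata yield ``None`` metrics, never 0.
    """
    frames = list(frames)
    codes = gold_log.codes()
    seconds = len(frames) / fps
    overall = {"tp": 0, "fp": 0, "fn": 0}
    strata = {WATCHING: {"tp": 0, "fp": 0, "fn": 0, "n_frames": 0},
              NOT_WATCHING: {"tp": 0, "fp": 0, "fn": 0, "n_frames": 0}}
    for frame in frames:
        kept = apply_threshold(frame.faces, tau_d)
        pred_boxes = [f.box for f in kept]
        matched, unmatched_pred, unmatched_gold = match_to_gold(
            pred_boxes, [g.box for g in frame.gold_faces], iou_min)
        overall["tp"] += len(matched)
        overall["fp"] += len(unmatched_pred)
        overall["fn"] += len(unmatched_gold)
        code = codes[frame.frame_index] if frame.frame_index < len(codes) else None
        if code in strata:
            s = strata[code]
            s["n_frames"] += 1
            tgt_gold = [g.box for g in frame.gold_faces if g.identity == TARGET]
            m, up, ug = match_to_gold(pred_boxes, tgt_gold, iou_min)
            s["tp"] += len(m)
            s["fp"] += len(up)
            s["fn"] += len(ug)
    report = {"overall": _metrics(seconds=seconds, **overall)}
    for code, s in strata.items():
        sec = s.pop("n_frames") / fps
        report["gaze_on" if code == WATCHING else "gaze_off"] = _metrics(
            seconds=sec, **s)
    return report


def summarize_across_families(reports: Sequence[dict], keys: Sequence[str],
                              how: str = "family_mean") -> dict:
    """Aggregate per-family metric dicts.

    ``family_mean`` (default) averages each family's metric with equal
    weight and reports mean plus (min, max) range, the presentation style
    of small-cohort device studies; ``pooled`` re-derives each metric from
    summed confusion counts.
    """
    if how == "family_mean":
        out = {}
        for key in keys:
            vals = [r[key] for r in reports if r.get(key) is not None]
            out[key] = {
                "mean": float(np.mean(vals)) if vals else None,
                "range": (float(np.min(vals)), float(np.max(vals))) if vals else None,
                "n_families": len(vals),
            }
        return out
    if how == "pooled":
        tp = sum(r.get("tp", 0) for r in reports)
        fp = sum(r.get("fp", 0) for r in reports)
        fn = sum(r.get("fn", 0) for r in reports)
        return {
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "ppv": tp / (tp + fp) if tp + fp else None,
        }
    raise ValueError("how must be 'family_mean' or 'pooled'")
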