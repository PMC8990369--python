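"""Gaze dichotomization: region-conditional angular windows on the gaze
direction vector, fitted from gold-coded watching frames, with
leave-one-family-out evaluation.

A gaze estimator yields a unit direction vector per face. Whether that
direction means "looking at the television" depends on where the face is
in the frame and where the television stands in the room, so the frame is
partitioned into an equal grid of regions and yaw/pitch windows are
calibrated per region (and per television position) as central quantile
intervals of the angles observed while the gold standard says the child
was watching. Classification is a simple inclusive window test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session import (
    TARGET,
    WATCHING,
    NOT_WATCHING,
    FrameObservation,
    GoldLog,
    logger,
)

DEFAULT_GRID = (3, 3)
DEFAULT_COVERAGE = 0.90  # central 5th-95th percentile interval
DEFAULT_MIN_SAMPLES = 30


def gaze_angles(gaze: np.ndarray) -> tuple[float, float]:
    """(yaw, pitch) in degrees of a unit gaze vector.

    yaw = atan2(x, z), pitch = atan2(-y, sqrt(x^2 + z^2)); camera axes
    x right, y down, z toward the camera, so (0, 0, 1) — looking straight
    at the camera-plane normal — maps to (0, 0).
    """
    g = np.asarray(gaze, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("gaze must be a unit vector")
    yaw = math.degrees(math.atan2(g[0], g[2]))
    pitch = math.degrees(math.atan2(-g[1], math.hypot(g[0], g[2])))
    return yaw, pitch


def region_of(center: tuple[float, float], frame_size: tuple[int, int],
              grid: tuple[int, int] = DEFAULT_GRID) -> int:
    """Row-major index of the equal-sized grid cell containing a pixel;
    the right/bottom frame edges belong to the last cell."""
    x, y = center
    w, h = frame_size
    rows, cols = grid
    if not (0 <= x <= w and 0 <= y <= h):
        raise ValueError("center outside frame")
    col = min(int(x * cols / w), cols - 1)
    row = min(int(y * rows / h), rows - 1)
    return row * cols + col


@dataclass
class CellWindow:
    yaw_lo: float
    yaw_hi: float
    pitch_lo: float
    pitch_hi: float
    n: int

    def contains(self, yaw: float, pitch: float, yaw_only: bool = False) -> bool:
        ok_yaw = self.yaw_lo <= yaw <= self.yaw_hi
        if yaw_only:
            return ok_yaw
        return ok_yaw and self.pitch_lo <= pitch <= self.pitch_hi

    def scaled(self, factor: float) -> "CellWindow":
        """Window shrunk/widened about its center by ``factor``."""
        yc = (self.yaw_lo + self.yaw_hi) / 2
        pc = (self.pitch_lo + self.pitch_hi) / 2
        yh = (self.yaw_hi - self.yaw_lo) / 2 * factor
        ph = (self.pitch_hi - self.pitch_lo) / 2 * factor
        return CellWindow(yc - yh, yc + yh, pc - ph, pc + ph, self.n)


@dataclass
class AngularLimitMap:
    """Per-region yaw/pitch windows defining "gaze on television" for one
    television position; cells with too few calibration samples fall back
    to the global pooled window."""

    grid: tuple[int, int]
    frame_size: tuple[int, int]
    tv_position: str
    cells: dict[int, CellWindow] = field(default_factory=dict)
    global_window: CellWindow | None = None
    yaw_only: bool = False

    def window_for(self, cell: int) -> CellWindow:
        win = self.cells.get(cell, self.global_window)
        if win is None:
            raise ValueError("no fitted window (empty limits map)")
        return win

    def scaled(self, factor: float) -> "AngularLimitMap":
        return AngularLimitMap(
            self.grid, self.frame_size, self.tv_position,
            {c: w.scaled(factor) for c, w in self.cells.items()},
            self.global_window.scaled(factor) if self.global_window else None,
            self.yaw_only,
        )

    # -- human-readable serialization --------------------------------------

    def to_txt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# angular limits, tv_position={self.tv_position}, "
                     f"grid={self.grid[0]}x{self.grid[1]}, "
                     f"frame={self.frame_size[0]}x{self.frame_size[1]}, "
                     f"yaw_only={int(self.yaw_only)}\n")
            fh.write("cell,yaw_lo,yaw_hi,pitch_lo,pitch_hi,n\n")
            if self.global_window is not None:
                g = self.global_window
                fh.write(f"global,{g.yaw_lo!r},{g.yaw_hi!r},"
                         f"{g.pitch_lo!r},{g.pitch_hi!r},{g.n}\n")
            for cell in sorted(self.cells):
                c = self.cells[cell]
                fh.write(f"{cell},{c.yaw_lo!r},{c.yaw_hi!r},"
                         f"{c.pitch_lo!r},{c.pitch_hi!r},{c.n}\n")

    @classmethod
    def from_txt(cls, path) -> "AngularLimitMap":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in header.split(", ") if "=" in kv)
            rows_cols = meta["grid"].split("x")
            fw, fh_ = meta["frame"].split("x")
            out = cls((int(rows_cols[0]), int(rows_cols[1])),
                      (int(fw), int(fh_)), meta["tv_position"],
                      yaw_only=bool(int(meta.get("yaw_only", "0"))))
            fh.readline()  # column header
            for line in fh:
                cell_s, *vals = line.strip().split(",")
                win = CellWindow(float(vals[0]), float(vals[1]),
                                 float(vals[2]), float(vals[3]), int(vals[4]))
                if cell_s == "global":
                    out.global_window = win
                else:
                    out.cells[int(cell_s)] = win
        return out


def _watching_angles(
    sessions: Sequence[tuple[Sequence[FrameObservation], GoldLog]],
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Collect (yaw, pitch, box center) of the target child's gaze vector
    on every gold-coded watching frame across sessions."""
    yaws, pitches, centers = [], [], []
    for frames, gold in sessions:
        watching = gold.watching_indicator()
        for frame in frames:
            if frame.frame_index >= len(watching) or not watching[frame.frame_index]:
                continue
            for face in frame.faces:
                if face.true_identity == TARGET:
                    yaw, pitch = gaze_angles(face.gaze)
                    yaws.append(yaw)
                    pitches.append(pitch)
                    centers.append(face.center)
                    break
    return np.asarray(yaws), np.asarray(pitches), centers


def fit_angular_limits(
    sessions: Sequence[tuple[Sequence[FrameObservation], GoldLog]],
    tv_position: str,
    frame_size: tuple[int, int],
    grid: tuple[int, int] = DEFAULT_GRID,
    coverage_quantile: float = DEFAULT_COVERAGE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    yaw_only: bool = False,
) -> AngularLimitMap:
    """Calibrate per-region angular windows from training sessions.

    Per cell, the yaw and pitch windows are the central
    ``coverage_quantile`` interval (default 5th-95th percentile) of the
    angles observed on frames gold-coded watching; cells with fewer than
    ``min_samples`` such frames inherit the global window pooled over all
    cells.
    """
    if not 0.0 < coverage_quantile <= 1.0:
        raise ValueError("coverage_quantile must be in (0, 1]")
    yaws, pitches, centers = _watching_angles(sessions)
    if len(yaws) == 0:
        raise ValueError("no gold-coded watching frames: cannot fit limits")
    lo_q = (1.0 - coverage_quantile) / 2.0
    hi_q = 1.0 - lo_q

    def window(y: np.ndarray, p: np.ndarray) -> CellWindow:
        return CellWindow(
            float(np.quantile(y, lo_q)), float(np.quantile(y, hi_q)),
            float(np.quantile(p, lo_q)), float(np.quantile(p, hi_q)),
            len(y),
        )

    limits = AngularLimitMap(grid, frame_size, tv_position, yaw_only=yaw_only)
    limits.global_window = window(yaws, pitches)
    cell_idx = np.array([region_of(c, frame_size, grid) for c in centers])
    for cell in np.unique(cell_idx):
        mask = cell_idx == cell
        if mask.sum() >= min_samples:
            limits.cells[int(cell)] = window(yaws[mask], pitches[mask])
    return limits


def classify_gaze(gaze: np.ndarray, box_center: tuple[float, float],
                  limits: AngularLimitMap,
                  tv_position: str | None = None) -> bool:
    """True iff the gaze vector's yaw and pitch both fall inside the
    window of the grid cell containing the face (boundaries inclusive)."""
    if tv_position is not None and tv_position != limits.tv_position:
        raise ValueError(
            f"limits fitted for tv_position={limits.tv_position!r}, "
            f"session has {tv_position!r}")
    yaw, pitch = gaze_angles(gaze)
    cell = region_of(box_center, limits.frame_size, limits.grid)
    return limits.window_for(cell).contains(yaw, pitch, limits.yaw_only)


def evaluate_gaze(
    frames: Sequence[FrameObservation],
    gold: GoldLog,
    limits: AngularLimitMap,
) -> dict:
    """Frame-level gaze metrics for the target child on codable frames.

    Uses the target's true face (calibration-time knowledge); frames where
    the target is absent or the gold code is cannot-tell are skipped.
    """
    codes = gold.codes()
    tp = tn = fp = fn = 0
    for frame in frames:
        code = codes[frame.frame_index]
        if code not in (WATCHING, NOT_WATCHING):
            continue
        face = next((f for f in frame.faces if f.true_identity == TARGET), None)
        if face is None:
            continue
        pred = classify_gaze(face.gaze, face.center, limits)
        truth = code == WATCHING
        if pred and truth:
            tp += 1
        elif pred:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    total = tp + tn + fp + fn
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / total if total else None,
        "sensitivity": tp / (tp + fn) if tp + fn else None,
        "specificity": tn / (tn + fp) if tn + fp else None,
        "ppv": tp / (tp + fp) if tp + fp else None,
        "npv": tn / (tn + fn) if tn + fn else None,
        "fpr": fp / (fp + tn) if fp + tn else None,
    }


def loo_evaluate(
    families: Sequence[dict],
    grid: tuple[int, int] = DEFAULT_GRID,
    coverage_quantile: float = DEFAULT_COVERAGE,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """Leave-one-family-out gaze calibration and evaluation.

    ``families`` is a sequence of dicts with keys ``family_id``,
    ``tv_position``, ``frame_size`` and ``sessions`` (list of
    (frames, gold) pairs). For each family, windows are fitted on the
    remaining families sharing its television position and applied to the
    held-out family. Positions represented by a single family are skipped
    with a warning (they cannot be cross-validated), mirroring the
    exclusion of a uniquely positioned setup.

    Returns one metrics row per evaluated family.
    """
    rows = []
    for fam in families:
        peers = [g for g in families
                 if g["tv_position"] == fam["tv_position"]
                 and g["family_id"] != fam["family_id"]]
        if not peers:
            logger.warning(
                "family %s: unique tv_position %r, skipped from "
                "leave-one-out gaze evaluation", fam["family_id"],
                fam["tv_position"])
            continue
        train = [pair for g in peers for pair in g["sessions"]]
        limits = fit_angular_limits(
            train, fam["tv_position"], fam["frame_size"], grid,
            coverage_quantile, min_samples)
        agg = {k: 0 for k in ("tp", "tn", "fp", "fn")}
        for frames, gold in fam["sessions"]:
            res = evaluate_gaze(frames, gold, limits)
            for k in agg:
                agg[k] += res[k]
        total = sum(agg.values())
        tp, tn, fp, fn = agg["tp"], agg["tn"], agg["fp"], agg["fn"]
        rows.append({
            "family_id": fam["family_id"],
            "tv_position": fam["tv_position"],
            **agg,
            "accuracy": (tp + tn) / total if total else None,
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "ppv": tp / (tp + fp) if tp + fp else None,
            "npv": tn / (tn + fn) if tn + fn else None,
            "fpr": fp / (fp + tn) if fp + tn else None,
        })
    return pd.DataFrame(rows)


def loo_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and (min, max) range of each metric per television position,
    the presentation used for small per-family cohorts."""
    metrics = ["accuracy", "sensitivity", "specificity", "ppv", "npv", "fpr"]
    out = []
    for pos, sub in table.groupby("tv_position"):
        row: dict = {"tv_position": pos, "n_families": len(sub)}
        for m in metrics:
            vals = sub[m].dropna()
            row[f"{m}_mean"] = float(vals.mean()) if len(vals) else None
            row[f"{m}_min"] = float(vals.min()) if len(vals) else None
            row[f"{m}_max"] = float(vals.max()) if len(vals) else None
        out.append(row)
    return pd.DataFrame(out)
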