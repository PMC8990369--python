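"""Sequential composition of the three stages into a per-frame viewing
log and the total television-viewing-time estimate.

Per frame: detector-score thresholding -> track building, gallery match
scoring and temporal identity smoothing -> angular-window gaze
classification of the verified target face. Frames with no verified
target contribute "not viewing" — the device's operational definition of
viewing requires the child's verified presence. Total viewing time is the
count of viewing frames divided by the frame rate, reported in
minutes:seconds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .session import FrameObservation, Gallery, GoldLog
from .detection import apply_threshold
from .verification import (
    DEFAULT_IOU_ASSOC,
    DEFAULT_SMOOTH_WINDOW,
    DEFAULT_TAU_V,
    track_verify,
)
from .gaze import AngularLimitMap, classify_gaze


@dataclass
class PipelineConfig:
    """Every calibrated pipeline parameter, serializable to YAML so a run
    is fully reproducible from its recorded configuration."""

    tau_d: float = 0.5
    tau_v: float = DEFAULT_TAU_V
    iou_assoc: float = DEFAULT_IOU_ASSOC
    smooth_window: int = DEFAULT_SMOOTH_WINDOW

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class ViewingLog:
    """Per-frame binary viewing decisions for the target child."""

    def __init__(self, decisions, fps: float):
        self.decisions = np.asarray(decisions, dtype=bool)
        self.fps = float(fps)

    @property
    def n_frames(self) -> int:
        return len(self.decisions)

    @property
    def total_viewing_s(self) -> float:
        return float(self.decisions.sum()) / self.fps

    def formatted_total(self) -> str:
        return format_mmss(self.total_viewing_s)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "viewing"])
            for i, d in enumerate(self.decisions):
                writer.writerow([i, int(d)])

    @classmethod
    def from_csv(cls, path, fps: float) -> "ViewingLog":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            decisions = [bool(int(row[1])) for row in reader]
        return cls(decisions, fps)

    def summary(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "fps": self.fps,
            "viewing_frames": int(self.decisions.sum()),
            "total_viewing_s": self.total_viewing_s,
            "total_viewing_mmss": self.formatted_total(),
        }

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def format_mmss(seconds: float) -> str:
    """Whole minutes and zero-padded seconds, e.g. 100 s -> '1:40'."""
    total = int(round(seconds))
    return f"{total // 60}:{total % 60:02d}"


def total_viewing_time(log: ViewingLog) -> tuple[float, str]:
    """Total viewing seconds and the minutes:seconds string."""
    return log.total_viewing_s, log.formatted_total()


def run_pipeline(
    frames: list[FrameObservation],
    gallery: Gallery,
    limits: AngularLimitMap,
    config: PipelineConfig | None = None,
    fps: float | None = None,
) -> ViewingLog:
    """Run detection thresholding, verification with identity smoothing,
    and gaze dichotomization over a frame stream.

    ``fps`` defaults to the rate implied by the frame timestamps.
    Deterministic given its inputs; the output has one decision per frame
    index in ``[0, max_frame_index]``.
    """
    cfg = config or PipelineConfig()
    if not frames:
        return ViewingLog([], fps or 15.0)
    if fps is None:
        fps = _infer_fps(frames)
    n = frames[-1].frame_index + 1

    try:
        kept_frames = [
            FrameObservation(f.frame_index, f.t,
                             apply_threshold(f.faces, cfg.tau_d), f.gold_faces)
            for f in frames
        ]
    except Exception as exc:  # pragma: no cover - defensive context
        raise RuntimeError(f"detection stage failed: {exc}") from exc

    try:
        _, per_frame = track_verify(kept_frames, gallery, cfg.tau_v,
                                    cfg.iou_assoc, cfg.smooth_window)
    except Exception as exc:
        raise RuntimeError(f"verification stage failed: {exc}") from exc

    decisions = np.zeros(n, dtype=bool)
    try:
        for fpos, frame in enumerate(kept_frames):
            decs = per_frame[fpos]
            best_bi = None
            best_score = -np.inf
            for bi, (score, is_target) in decs.items():
                if is_target and score > best_score:
                    best_bi, best_score = bi, score
            if best_bi is None:
                continue
            face = frame.faces[best_bi]
            decisions[frame.frame_index] = classify_gaze(
                face.gaze, face.center, limits)
    except Exception as exc:
        raise RuntimeError(f"gaze stage failed: {exc}") from exc
    return ViewingLog(decisions, fps)


def _infer_fps(frames: list[FrameObservation]) -> float:
    if len(frames) >= 2 and frames[-1].t > frames[0].t:
        span = frames[-1].frame_index - frames[0].frame_index
        return span / (frames[-1].t - frames[0].t)
    return 15.0


def epoch_smooth(log: ViewingLog, epoch_s: float) -> ViewingLog:
    """Relabel viewing over fixed time epochs by frame-majority vote.

    Each epoch is viewing iff at least half of its frames are viewing
    (ties count as viewing); a final partial epoch is judged by the
    majority of the frames it actually contains. Decisions are returned
    at frame resolution (epoch labels broadcast back to frames) so total
    -time arithmetic stays frame-based.
    """
    epoch_frames = int(round(epoch_s * log.fps))
    if epoch_frames < 1:
        raise ValueError("epoch_s * fps must be >= 1")
    out = np.empty_like(log.decisions)
    for start in range(0, log.n_frames, epoch_frames):
        block = log.decisions[start:start + epoch_frames]
        out[start:start + epoch_frames] = 2 * int(block.sum()) >= len(block)
    return ViewingLog(out, log.fps)
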