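"""Target-child verification: embedding match scores against the
enrollment gallery, thresholding, IoU track building, and temporal
identity smoothing.

Each detected face's embedding is compared with the gallery of the target
child's enrollment embeddings by Pearson correlation; the per-face match
score is the maximum over gallery rows (robust to pose-diverse
enrollment). A face is a raw "target" candidate when its score reaches the
match threshold (default 0.93); continuity of identity across successive
frames is then exploited by associating boxes into tracks and replacing
each frame's raw decision with the majority decision over a centered
window along its track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .session import (
    CANNOT_TELL,
    NOT_WATCHING,
    OUT_OF_FRAME,
    TARGET,
    WATCHING,
    CandidateFace,
    FrameObservation,
    Gallery,
    GoldLog,
)
from .detection import iou

DEFAULT_TAU_V = 0.93
DEFAULT_IOU_ASSOC = 0.3
DEFAULT_SMOOTH_WINDOW = 15  # frames, ~1 s at 15 fps


def match_score(embedding: np.ndarray, gallery: Gallery) -> float:
    """Maximum Pearson correlation between the embedding and the gallery
    rows. In [-1, 1]; close to 1 for the target child."""
    e = np.asarray(embedding, dtype=float)
    if e.shape[-1] != gallery.dim:
        raise ValueError("embedding dimension does not match gallery")
    return float(np.max(_pearson_rows(e[None, :], gallery.embeddings)))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    if np.any(an == 0) or np.any(bn == 0):
        raise ValueError("zero-variance vector: correlation undefined")
    return (ac @ bc.T) / np.outer(an, bn)


def batch_match_scores(embeddings: np.ndarray, gallery: Gallery) -> np.ndarray:
    """Vectorized ``match_score`` for a stack of embeddings (m x dim)."""
    emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if emb.shape[1] != gallery.dim:
        raise ValueError("embedding dimension does not match gallery")
    return _pearson_rows(emb, gallery.embeddings).max(axis=1)


def verify_frame(
    faces: Sequence[CandidateFace],
    gallery: Gallery,
    tau_v: float = DEFAULT_TAU_V,
) -> int | None:
    """Index of the verified target face in this frame, or None.

    Among faces with match score >= tau_v the highest-scoring one wins;
    an exact tie goes to the lowest face index. At most one target per
    frame.
    """
    if not -1.0 < tau_v < 1.0:
        raise ValueError("tau_v must be in (-1, 1)")
    best: int | None = None
    best_score = -np.inf
    for i, face in enumerate(faces):
        s = match_score(face.embedding, gallery)
        if s >= tau_v and s > best_score:
            best, best_score = i, s
    return best


@dataclass
class Track:
    """One face track: strictly increasing frame indices, consecutive
    boxes overlapping at the association threshold."""

    track_id: int
    frame_indices: list[int] = field(default_factory=list)
    face_indices: list[int] = field(default_factory=list)
    boxes: list[tuple[float, float, float, float]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)  # match scores
    raw_decisions: list[bool] = field(default_factory=list)
    smoothed: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame_indices)


def build_tracks(
    frames: Iterable[FrameObservation],
    iou_assoc: float = DEFAULT_IOU_ASSOC,
    gap: int = 0,
) -> list[Track]:
    """Frame-to-frame greedy IoU association of face boxes into tracks.

    A box associates with the active track of highest IoU >= iou_assoc
    (one-to-one, descending IoU); unassociated boxes start new tracks. A
    track becomes inactive after ``gap`` consecutive frames without an
    associated box (default 0: any missed frame ends it).
    """
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for frame in frames:
        boxes = [f.box for f in frame.faces]
        pairs = []
        for ti, tr in enumerate(active):
            for bi, box in enumerate(boxes):
                val = iou(tr.boxes[-1], box)
                if val >= iou_assoc:
                    pairs.append((val, ti, bi))
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        used_t: set[int] = set()
        used_b: set[int] = set()
        assoc: dict[int, int] = {}
        for _, ti, bi in pairs:
            if ti in used_t or bi in used_b:
                continue
            used_t.add(ti)
            used_b.add(bi)
            assoc[bi] = ti
        new_active: list[Track] = []
        for bi, box in enumerate(boxes):
            if bi in assoc:
                tr = active[assoc[bi]]
            else:
                tr = Track(next_id)
                next_id += 1
                tracks.append(tr)
            tr.frame_indices.append(frame.frame_index)
            tr.face_indices.append(bi)
            tr.boxes.append(box)
            new_active.append(tr)
        for ti, tr in enumerate(active):
            if ti in used_t:
                continue
            missed = frame.frame_index - tr.frame_indices[-1]
            if missed <= gap:
                new_active.append(tr)
        active = new_active
    return tracks


def smooth_identity(raw_decisions: Sequence[bool], window_frames: int = DEFAULT_SMOOTH_WINDOW) -> list[bool]:
    """Majority-vote smoothing of raw per-frame target decisions along a
    track, with a centered window clipped to the track ends; exact ties
    keep the raw frame decision."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 1")
    raw = np.asarray(raw_decisions, dtype=bool)
    n = len(raw)
    if n == 0:
        return []
    half = window_frames // 2
    csum = np.concatenate([[0], np.cumsum(raw.astype(int))])
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        trues = csum[hi] - csum[lo]
        length = hi - lo
        if 2 * trues > length:
            out.append(True)
        elif 2 * trues < length:
            out.append(False)
        else:
            out.append(bool(raw[i]))
    return out


def track_verify(
    frames: Sequence[FrameObservation],
    gallery: Gallery,
    tau_v: float = DEFAULT_TAU_V,
    iou_assoc: float = DEFAULT_IOU_ASSOC,
    window_frames: int = DEFAULT_SMOOTH_WINDOW,
) -> tuple[list[Track], list[dict[int, tuple[float, bool]]]]:
    """Score, threshold and smooth every face along its track.

    Returns the tracks (with scores, raw and smoothed decisions filled in)
    and, per frame, a mapping ``face_index -> (match_score, smoothed
    target decision)``.
    """
    frames = list(frames)
    tracks = build_tracks(frames, iou_assoc)
    # vectorized scores for all faces at once
    all_emb = [face.embedding for frame in frames for face in frame.faces]
    offsets: dict[int, int] = {}
    pos = 0
    for frame in frames:
        offsets[frame.frame_index] = pos
        pos += len(frame.faces)
    if all_emb:
        scores = batch_match_scores(np.vstack(all_emb), gallery)
    else:
        scores = np.empty(0)
    per_frame: list[dict[int, tuple[float, bool]]] = [dict() for _ in frames]
    index_of = {frame.frame_index: i for i, frame in enumerate(frames)}
    for tr in tracks:
        tr.scores = [float(scores[offsets[fi] + bi])
                     for fi, bi in zip(tr.frame_indices, tr.face_indices)]
        tr.raw_decisions = [s >= tau_v for s in tr.scores]
        tr.smoothed = smooth_identity(tr.raw_decisions, window_frames)
        for fi, bi, s, dec in zip(tr.frame_indices, tr.face_indices,
                                  tr.scores, tr.smoothed):
            per_frame[index_of[fi]][bi] = (s, dec)
    return tracks, per_frame


def evaluate_verification(
    frames: Sequence[FrameObservation],
    per_frame_decisions: Sequence[dict[int, tuple[float, bool]]],
    gold_log: GoldLog,
) -> dict:
    """Face-box-level confusion metrics for target verification, overall
    and stratified by the frame's gold gaze code.

    Positive = "this box is the target child". Counts are at the bounding
    -box level; frames coded cannot-tell are excluded from all strata.
    Empty-denominator metrics are ``None``.
    """
    codes = gold_log.codes()
    buckets = {"overall": [0, 0, 0, 0], "gaze_on": [0, 0, 0, 0],
               "gaze_off": [0, 0, 0, 0]}  # tp, tn, fp, fn
    for fpos, frame in enumerate(frames):
        code = codes[frame.frame_index] if frame.frame_index < len(codes) else None
        if code == CANNOT_TELL:
            continue
        decs = per_frame_decisions[fpos]
        for bi, face in enumerate(frame.faces):
            truth = face.true_identity == TARGET
            pred = decs.get(bi, (None, False))[1]
            idx = 0 if (pred and truth) else 1 if (not pred and not truth) \
                else 2 if pred else 3
            buckets["overall"][idx] += 1
            if code == WATCHING:
                buckets["gaze_on"][idx] += 1
            elif code in (NOT_WATCHING, OUT_OF_FRAME):
                buckets["gaze_off"][idx] += 1
    out = {}
    for name, (tp, tn, fp, fn) in buckets.items():
        total = tp + tn + fp + fn
        out[name] = {
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "accuracy": (tp + tn) / total if total else None,
            "sensitivity": tp / (tp + fn) if tp + fn else None,
            "specificity": tn / (tn + fp) if tn + fp else None,
            "ppv": tp / (tp + fp) if tp + fp else None,
            "npv": tn / (tn + fn) if tn + fn else None,
        }
    return out
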