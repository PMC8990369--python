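"""Synthetic multi-person viewing sessions with frame-level ground truth.

This module emulates the raw material of a screen-time measurement study:
a camera mounted on top of a television records a target child, a sibling
and a parent at 15-30 frames/s. Each frame yields candidate face boxes with
detector confidence scores, per-face identity embeddings and per-face gaze
direction vectors, while trained-coder "gold standard" logs record whether
the target child was watching the screen, not watching, out of frame, or
could not be judged (duration coding: one code persists until behavior
changes).

Everything downstream (detection thresholds, verification, gaze windows,
agreement statistics) is testable against the simulator's known ground
truth without any video data or trained networks.

Geometry and conventions
------------------------
* Pixel coordinates: origin top-left, x rightward, y downward. Face boxes
  are (x_min, y_min, width, height).
* Camera coordinates: x right, y down, z positive toward the camera, so a
  person looking straight at the camera has gaze (0, 0, 1). The camera sits
  at the top-center of the screen; the screen center is a 3-D point just
  below (and, for a left-corner television, lateral to) the camera.
* Frame intervals are half-open [start, end) with 0-based frame indices.
* A pinhole camera with focal length ``frame_width / 2`` (90-degree
  horizontal field of view, matching a wide-angle webcam) projects 3-D
  head positions to face-box centers.

Lighting enters only as multiplicative degradation (detector miss
probability, embedding noise, gaze noise). All stochastic draws are made in
a lighting-independent order so that two sessions sharing a seed but
differing in lighting are coupled through common random numbers: dimming
the lights can only degrade, never improve, any individual observation.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("screenwatch")

# ---------------------------------------------------------------------------
# Gold codes
# ---------------------------------------------------------------------------

WATCHING = "watching"
NOT_WATCHING = "not_watching"
OUT_OF_FRAME = "out_of_frame"
CANNOT_TELL = "cannot_tell"
GOLD_CODES = (WATCHING, NOT_WATCHING, OUT_OF_FRAME, CANNOT_TELL)

TARGET = "target"
SIBLING = "sibling"
PARENT = "parent"
NONE = "none"
IDENTITIES = (TARGET, SIBLING, PARENT, NONE)

#: lighting -> (miss-probability, embedding-noise, gaze-noise) multipliers
LIGHTING_MULTIPLIERS = {
    "bright": (1.0, 1.0, 1.0),
    "dim": (2.0, 2.0, 2.0),
    "dark": (4.0, 4.0, 4.0),
}

TV_POSITIONS = ("center", "left", "other")


class ConfigError(ValueError):
    """Raised when a SessionConfig field fails validation."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one simulated observation session.

    Defaults reproduce the study conditions: a 90-minute observation at
    15 frames/s of a parent-sibling triad in a bright room, with the
    television centered on the wall and the child watching about a quarter
    of the time at steady state.
    """

    n_persons: int = 3
    duration_s: float = 5400.0
    fps: float = 15.0
    frame_size: tuple[int, int] = (1280, 720)
    tv_position: str = "center"
    screen_box: tuple[float, float, float, float] | None = None
    screen_center_3d: tuple[float, float, float] | None = None
    embedding_dim: int = 128
    centroid_separation_deg: float = 90.0
    embedding_noise_sd: float = 0.013
    gaze_noise_deg: float = 5.0
    p_watch_to_notwatch: float = 0.06
    p_notwatch_to_watch: float = 0.02
    p_exit: float = 0.002
    mean_exit_s: float = 20.0
    reposition_interval_s: float = 60.0
    lighting: str = "bright"
    # plumbing knobs (not behaviour of the persons, but of the sensor chain)
    p_miss_base: float = 0.01
    spurious_fp_per_s: float = 2.0
    pos_jitter_m: float = 0.05
    offscreen_margin_deg: float = 12.0
    true_score_mean: float = 0.82
    true_score_sd: float = 0.10
    spurious_score_mean: float = 0.50
    spurious_score_sd: float = 0.15
    screen_half_extent_m: float = 0.55
    initial_state_watching: bool = True
    gallery_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.frame_size
        checks = [
            (self.n_persons >= 1, "n_persons"),
            (self.duration_s > 0, "duration_s"),
            (15.0 <= self.fps <= 30.0, "fps"),
            (w > 0 and h > 0, "frame_size"),
            (self.tv_position in TV_POSITIONS, "tv_position"),
            (self.embedding_dim >= 2, "embedding_dim"),
            (self.centroid_separation_deg >= 0, "centroid_separation_deg"),
            (self.embedding_noise_sd >= 0, "embedding_noise_sd"),
            (self.gaze_noise_deg >= 0, "gaze_noise_deg"),
            (0 <= self.p_watch_to_notwatch <= 1, "p_watch_to_notwatch"),
            (0 <= self.p_notwatch_to_watch <= 1, "p_notwatch_to_watch"),
            (0 <= self.p_exit <= 1, "p_exit"),
            (self.mean_exit_s > 0, "mean_exit_s"),
            (self.reposition_interval_s > 0, "reposition_interval_s"),
            (self.offscreen_margin_deg >= 0, "offscreen_margin_deg"),
            (1 <= self.n_persons <= len(SEATS), "n_persons"),
            (self.lighting in LIGHTING_MULTIPLIERS, "lighting"),
            (0 <= self.p_miss_base <= 1, "p_miss_base"),
            (self.spurious_fp_per_s >= 0, "spurious_fp_per_s"),
            (self.pos_jitter_m >= 0, "pos_jitter_m"),
            (self.gallery_size >= 1, "gallery_size"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigError(f"invalid SessionConfig field: {name}")
        if self.tv_position == "other" and self.screen_center_3d is None:
            raise ConfigError(
                "invalid SessionConfig field: screen_center_3d "
                "(required when tv_position='other')"
            )
        box = self.screen_box
        if box is not None:
            x, y, bw, bh = box
            if not (bw > 0 and bh > 0 and 0 <= x and 0 <= y
                    and x + bw <= w and y + bh <= h):
                raise ConfigError("invalid SessionConfig field: screen_box")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def lighting_multipliers(self) -> tuple[float, float, float]:
        return LIGHTING_MULTIPLIERS[self.lighting]

    def default_screen_box(self) -> tuple[float, float, float, float]:
        """Descriptor screen box in frame coordinates (bottom strip)."""
        if self.screen_box is not None:
            return self.screen_box
        w, h = self.frame_size
        bw, bh = w / 3.0, h / 6.0
        x = (w - bw) / 2.0 if self.tv_position == "center" else 0.0
        return (x, h - bh, bw, bh)

    def screen_center(self) -> np.ndarray:
        """3-D screen-center gaze target in camera coordinates (meters)."""
        if self.screen_center_3d is not None:
            return np.asarray(self.screen_center_3d, dtype=float)
        # camera mounted at top-center of the screen: the screen center is
        # ~0.35 m below the camera; a left-corner TV viewed by people seated
        # toward the room center shifts the target laterally.
        if self.tv_position == "center":
            return np.array([0.0, 0.35, 0.0])
        return np.array([-0.8, 0.35, 0.0])

    def noiseless(self, **overrides) -> "SessionConfig":
        """Copy with every stochastic corruption zeroed.

        Gaze noise, embedding noise, detector misses and score noise,
        spurious candidates and position jitter are all removed; room
        exits and gaze switching (ground-truth events, not noise) are
        retained.
        """
        return replace(
            self,
            gaze_noise_deg=0.0,
            embedding_noise_sd=0.0,
            p_miss_base=0.0,
            spurious_fp_per_s=0.0,
            pos_jitter_m=0.0,
            true_score_sd=0.0,
            **overrides,
        )


# ---------------------------------------------------------------------------
# Frame-level types
# ---------------------------------------------------------------------------


@dataclass
class CandidateFace:
    """One detected face candidate within a frame.

    ``true_identity`` and ``true_gaze_on_tv`` are simulator-only ground
    truth; a real detector backend leaves them at their defaults.
    """

    box: tuple[float, float, float, float]
    score: float
    embedding: np.ndarray
    gaze: np.ndarray
    true_identity: str = NONE
    true_gaze_on_tv: bool = False

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class GoldFace:
    """Ground-truth face annotation (present even if the detector missed it)."""

    box: tuple[float, float, float, float]
    identity: str
    gaze_on_tv: bool


@dataclass
class FrameObservation:
    """All candidate faces of one frame, plus gold annotations."""

    frame_index: int
    t: float
    faces: list[CandidateFace]
    gold_faces: list[GoldFace] = field(default_factory=list)


class GoldLog:
    """Duration-coded gold labels for the target child.

    Stored as runs ``(code, start_frame, end_frame)`` over half-open
    intervals that tile ``[0, n_frames)``; consecutive runs carry distinct
    codes.
    """

    def __init__(self, runs: Sequence[tuple[str, int, int]], fps: float):
        runs = [(str(c), int(s), int(e)) for c, s, e in runs]
        if not runs:
            raise ValueError("GoldLog needs at least one run")
        prev_end = 0
        prev_code = None
        for code, start, end in runs:
            if code not in GOLD_CODES:
                raise ValueError(f"unknown gold code {code!r}")
            if start != prev_end or end <= start:
                raise ValueError("runs must tile [0, n_frames) without gaps")
            if code == prev_code:
                raise ValueError("consecutive runs must have distinct codes")
            prev_end, prev_code = end, code
        self.runs = runs
        self.fps = float(fps)

    @classmethod
    def from_codes(cls, codes: Sequence[str], fps: float) -> "GoldLog":
        runs: list[tuple[str, int, int]] = []
        for i, code in enumerate(codes):
            if runs and runs[-1][0] == code:
                runs[-1] = (code, runs[-1][1], i + 1)
            else:
                runs.append((code, i, i + 1))
        return cls(runs, fps)

    @property
    def n_frames(self) -> int:
        return self.runs[-1][2]

    def codes(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=object)
        for code, start, end in self.runs:
            out[start:end] = code
        return out

    def watching_indicator(self) -> np.ndarray:
        """Per-frame boolean: gold code is 'watching'."""
        return self.codes() == WATCHING

    def gold_viewing_s(self) -> float:
        return float(self.watching_indicator().sum()) / self.fps

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code", "start_frame", "end_frame"])
            writer.writerows(self.runs)

    @classmethod
    def from_csv(cls, path, fps: float) -> "GoldLog":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header != ["code", "start_frame", "end_frame"]:
                raise ValueError("unexpected gold-log CSV header")
            runs = [(row[0], int(row[1]), int(row[2])) for row in reader]
        return cls(runs, fps)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GoldLog) and self.runs == other.runs
                and self.fps == other.fps)


class Gallery:
    """Enrollment embeddings of the target child (k rows, unit-norm)."""

    def __init__(self, embeddings: np.ndarray):
        arr = np.atleast_2d(np.asarray(embeddings, dtype=float))
        if arr.shape[0] < 1:
            raise ValueError("gallery needs at least one embedding")
        norms = np.linalg.norm(arr, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gallery rows must be unit-norm")
        self.embeddings = arr

    @property
    def k(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def to_txt(self, path) -> None:
        np.savetxt(path, self.embeddings, fmt="%.17g")

    @classmethod
    def from_txt(cls, path) -> "Gallery":
        return cls(np.atleast_2d(np.loadtxt(path)))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def focal_length(frame_size: tuple[int, int]) -> float:
    return frame_size[0] / 2.0


def project_point(p: np.ndarray, frame_size: tuple[int, int]) -> tuple[float, float]:
    """Pinhole projection of a camera-coordinate point to pixels."""
    f = focal_length(frame_size)
    cx, cy = frame_size[0] / 2.0, frame_size[1] / 2.0
    z = p[2]
    return (cx + f * p[0] / z, cy + f * p[1] / z)


def angles_to_vector(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Unit gaze vector from yaw/pitch in degrees (inverse of gaze_angles)."""
    yaw = np.deg2rad(yaw_deg)
    pitch = np.deg2rad(pitch_deg)
    return np.array([
        np.cos(pitch) * np.sin(yaw),
        -np.sin(pitch),
        np.cos(pitch) * np.cos(yaw),
    ])


def _direction_to_screen(p: np.ndarray, screen: np.ndarray) -> np.ndarray:
    """Gaze direction from head position toward screen center.

    Mirrored camera convention: z positive toward the camera, so looking at
    the screen (which sits beside the camera) gives z > 0.
    """
    d = screen - p
    d = np.array([d[0], d[1], -d[2]])
    return d / np.linalg.norm(d)


def _vector_angles_deg(v: np.ndarray) -> tuple[float, float]:
    yaw = np.degrees(np.arctan2(v[0], v[2]))
    pitch = np.degrees(np.arctan2(-v[1], np.hypot(v[0], v[2])))
    return float(yaw), float(pitch)


def _sample_outside_cone(axis: np.ndarray, half_angle_deg: float,
                         u1: float, u2: float) -> np.ndarray:
    """Uniform direction on the sphere outside a cone around ``axis``.

    Deterministic in (u1, u2); no rejection, so the draw count never
    depends on the cone width.
    """
    cos_max = np.cos(np.deg2rad(min(half_angle_deg, 179.0)))
    cos_t = -1.0 + u1 * (cos_max + 1.0)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * np.pi * u2
    # orthonormal basis around the axis
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b1 = np.cross(a, helper)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(a, b1)
    return cos_t * a + sin_t * (np.cos(phi) * b1 + np.sin(phi) * b2)


def _identity_centroids(rng: np.random.Generator, n: int, dim: int,
                        separation_deg: float) -> np.ndarray:
    """Unit centroids with pairwise angle ``separation_deg``.

    Simplex construction: c_i = sqrt(1-r^2) m + r v_i with orthonormal
    {m, v_1..v_n} gives pairwise cosine 1 - r^2 exactly.
    """
    if n + 1 > dim:
        raise ConfigError("invalid SessionConfig field: embedding_dim "
                          "(need n_persons + 1 <= embedding_dim)")
    raw = rng.standard_normal((n + 1, dim))
    q, _ = np.linalg.qr(raw.T)
    basis = q.T[: n + 1]
    cos_sep = np.cos(np.deg2rad(separation_deg))
    r = np.sqrt(max(0.0, 1.0 - cos_sep))
    m, vs = basis[0], basis[1:]
    cents = np.sqrt(max(0.0, 1.0 - r * r)) * m + r * vs
    return cents / np.linalg.norm(cents, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

#: fixed sofa/chair seat positions (camera coordinates, meters). A seat
#: determines head position exactly; people occupy distinct seats and
#: periodically move to new ones. A shared discrete seat grid is what
#: lets angular windows calibrated on some families transfer exactly to
#: others in the noiseless limit.
SEATS = np.array([
    [-1.3, 0.25, 2.4], [0.0, 0.25, 2.4], [1.3, 0.25, 2.4],
    [-1.3, 0.30, 3.0], [0.0, 0.30, 3.0], [1.3, 0.30, 3.0],
    [-1.3, 0.35, 3.6], [0.0, 0.35, 3.6], [1.3, 0.35, 3.6],
])

_FACE_WIDTH_M = 0.16


def _per_frame_prob(p_per_s: float, fps: float) -> float:
    """Per-second switch probability -> per-frame probability."""
    return 1.0 - (1.0 - p_per_s) ** (1.0 / fps)


def _simulate_truth(config: SessionConfig, rng: np.random.Generator):
    """Ground-truth processes: gaze state, exits, head positions."""
    n = config.n_frames
    p_wn = _per_frame_prob(config.p_watch_to_notwatch, config.fps)
    p_nw = _per_frame_prob(config.p_notwatch_to_watch, config.fps)
    u_state = rng.uniform(size=n)
    watch = np.empty(n, dtype=bool)
    state = config.initial_state_watching
    for i in range(n):
        watch[i] = state
        if state:
            state = not (u_state[i] < p_wn)
        else:
            state = u_state[i] < p_nw

    # exit process for the target: enter w.p. p_exit per second; geometric
    # duration with mean mean_exit_s
    p_enter = _per_frame_prob(config.p_exit, config.fps)
    p_return = min(1.0, 1.0 / (config.mean_exit_s * config.fps))
    u_exit = rng.uniform(size=n)
    present = np.empty(n, dtype=bool)
    inside = True
    for i in range(n):
        present[i] = inside
        if inside:
            inside = not (u_exit[i] < p_enter)
        else:
            inside = u_exit[i] < p_return

    # seating: distinct seats per person, resampled every
    # reposition_interval_s (the task protocol has people move around)
    k = config.n_persons
    interval = max(1, int(round(config.reposition_interval_s * config.fps)))
    positions = np.empty((n, k, 3))
    for start in range(0, n, interval):
        seats = rng.choice(len(SEATS), size=k, replace=False)
        positions[start:start + interval] = SEATS[seats]
    jitter = rng.standard_normal((n, k, 3)) * config.pos_jitter_m
    positions += jitter

    # sibling/parent own gaze behaviour (for stratified evaluation realism)
    u_other_watch = rng.uniform(size=(n, k))
    other_watch = u_other_watch < 0.5
    return watch, present, positions, other_watch


def simulate_session(
    config: SessionConfig,
) -> tuple[list[FrameObservation], GoldLog, Gallery]:
    """Simulate one observation session.

    Returns per-frame candidate-face observations (with simulator-only
    ground truth attached), the duration-coded gold log for the target
    child, and an enrollment gallery taken from the earliest frames where
    the target appears.

    Deterministic for a fixed config (including seed). Sessions sharing a
    seed but differing only in ``lighting`` share every underlying random
    draw, so degradation is pointwise monotone in the lighting multipliers.
    """
    n = config.n_frames
    k = config.n_persons
    dim = config.embedding_dim
    m_miss, m_emb, m_gaze = config.lighting_multipliers
    fps = config.fps
    w, h = config.frame_size
    f = focal_length(config.frame_size)
    screen = config.screen_center()

    rng_truth = np.random.default_rng([config.seed, 0])
    rng_obs = np.random.default_rng([config.seed, 1])

    centroids = _identity_centroids(rng_truth, k, dim, config.centroid_separation_deg)
    watch, present, positions, other_watch = _simulate_truth(config, rng_truth)

    # observation-noise draws, lighting-independent order and count
    miss_u = rng_obs.uniform(size=(n, k))
    score_z = rng_obs.standard_normal((n, k))
    gaze_z = rng_obs.standard_normal((n, k, 2))
    gaze_u = rng_obs.uniform(size=(n, k, 2))
    spurious_counts = rng_obs.poisson(config.spurious_fp_per_s / fps, size=n)

    p_miss = min(1.0, config.p_miss_base * m_miss)
    emb_sd = config.embedding_noise_sd * m_emb
    gaze_sd = config.gaze_noise_deg * m_gaze
    score_mu = config.true_score_mean - 0.08 * (m_miss - 1.0)

    identities = [TARGET, SIBLING, PARENT] + [f"person{j}" for j in range(3, k)]
    identities = identities[:k]

    frames: list[FrameObservation] = []
    chunk = 4096
    emb_noise: np.ndarray | None = None
    for i in range(n):
        if i % chunk == 0:
            m = min(chunk, n - i)
            emb_noise = rng_obs.standard_normal((m, k, dim))
        t = i / fps
        faces: list[CandidateFace] = []
        gold_faces: list[GoldFace] = []
        for j in range(k):
            is_target = j == 0
            if is_target and not present[i]:
                continue
            p = positions[i, j]
            u, v = project_point(p, config.frame_size)
            size = f * _FACE_WIDTH_M / p[2]
            box = (
                float(np.clip(u - size / 2, 0, w - 1)),
                float(np.clip(v - size / 2, 0, h - 1)),
                float(min(size, w - np.clip(u - size / 2, 0, w - 1))),
                float(min(size, h - np.clip(v - size / 2, 0, h - 1))),
            )
            on_tv = bool(watch[i]) if is_target else bool(other_watch[i, j])
            gold_faces.append(GoldFace(box, identities[j], on_tv))
            if miss_u[i, j] < p_miss:
                continue  # detector miss: gold only
            emb = centroids[j] + emb_sd * emb_noise[i % chunk, j]
            emb = emb / np.linalg.norm(emb)
            center_dir = _direction_to_screen(p, screen)
            if on_tv:
                yaw0, pitch0 = _vector_angles_deg(center_dir)
                gaze = angles_to_vector(yaw0 + gaze_sd * gaze_z[i, j, 0],
                                        pitch0 + gaze_sd * gaze_z[i, j, 1])
            else:
                # "not watching" means looking clearly away: outside the
                # screen's angular extent plus twice the gaze noise plus a
                # behavioral margin (marginal directions would be coded
                # cannot-tell by a human rater, not not-watching)
                screen_radius = np.degrees(
                    np.arctan2(config.screen_half_extent_m, p[2]))
                excl = (2.0 * gaze_sd + screen_radius
                        + config.offscreen_margin_deg)
                gaze = _sample_outside_cone(center_dir, excl,
                                            gaze_u[i, j, 0], gaze_u[i, j, 1])
            score = float(np.clip(score_mu + config.true_score_sd * score_z[i, j],
                                  0.0, 1.0))
            faces.append(CandidateFace(box, score, emb, gaze,
                                       identities[j], on_tv))
        for _ in range(spurious_counts[i]):
            cx_s = rng_obs.uniform(0, w)
            cy_s = rng_obs.uniform(0, h)
            size = rng_obs.uniform(20, 80)
            box = (
                float(np.clip(cx_s - size / 2, 0, w - 1)),
                float(np.clip(cy_s - size / 2, 0, h - 1)),
                float(min(size, w - np.clip(cx_s - size / 2, 0, w - 1))),
                float(min(size, h - np.clip(cy_s - size / 2, 0, h - 1))),
            )
            score = float(np.clip(
                config.spurious_score_mean
                + config.spurious_score_sd * rng_obs.standard_normal(),
                0.0, 1.0))
            emb = rng_obs.standard_normal(dim)
            emb = emb / np.linalg.norm(emb)
            gdir = _sample_outside_cone(np.array([0.0, 0.0, 1.0]), 0.0,
                                        rng_obs.uniform(), rng_obs.uniform())
            faces.append(CandidateFace(box, score, emb, gdir, NONE, False))
        frames.append(FrameObservation(i, t, faces, gold_faces))

    codes = np.where(~present, OUT_OF_FRAME,
                     np.where(watch, WATCHING, NOT_WATCHING))
    gold = GoldLog.from_codes(codes.tolist(), fps)
    n_target_frames = sum(
        any(f.true_identity == TARGET for f in frame.faces) for frame in frames)
    if n_target_frames == 0:
        raise ValueError("target never captured: cannot enroll a gallery")
    k_enroll = min(config.gallery_size, n_target_frames)
    if k_enroll < config.gallery_size:
        logger.warning("only %d target frames available; enrolling a "
                       "gallery of %d instead of %d", n_target_frames,
                       k_enroll, config.gallery_size)
    gallery = enroll_gallery(frames, k_enroll)
    return frames, gold, gallery


def enroll_gallery(frames: Iterable[FrameObservation], k: int) -> Gallery:
    """Enrollment gallery: target embeddings from the earliest k frames
    in which the target child's face was captured."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    for frame in frames:
        for face in frame.faces:
            if face.true_identity == TARGET:
                rows.append(face.embedding)
                break
        if len(rows) == k:
            break
    if len(rows) < k:
        raise ValueError(
            f"only {len(rows)} frames contain the target; need {k}")
    return Gallery(np.vstack(rows))


def corrupt_codes(gold: GoldLog, error_rate: float, seed: int) -> GoldLog:
    """Optional coder-noise injection: each frame's code is replaced by a
    uniformly random different code with probability ``error_rate``.

    Used only to exercise inter-rater statistics; the simulator's own gold
    logs are error-free.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = gold.codes()
    flip = rng.uniform(size=len(codes)) < error_rate
    for i in np.flatnonzero(flip):
        choices = [c for c in GOLD_CODES if c != codes[i]]
        codes[i] = choices[rng.integers(len(choices))]
    return GoldLog.from_codes(codes.tolist(), gold.fps)


# ---------------------------------------------------------------------------
# JSONL round-trip for frame streams
# ---------------------------------------------------------------------------


def _face_to_dict(face: CandidateFace) -> dict:
    return {
        "box": list(face.box),
        "score": face.score,
        "embedding": face.embedding.tolist(),
        "gaze": face.gaze.tolist(),
        "true_identity": face.true_identity,
        "true_gaze_on_tv": face.true_gaze_on_tv,
    }


def _gold_face_to_dict(gf: GoldFace) -> dict:
    return {"box": list(gf.box), "identity": gf.identity,
            "gaze_on_tv": gf.gaze_on_tv}


def write_frames_jsonl(frames: Iterable[FrameObservation], path) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            rec = {
                "frame_index": frame.frame_index,
                "t": frame.t,
                "faces": [_face_to_dict(f) for f in frame.faces],
                "gold_faces": [_gold_face_to_dict(g) for g in frame.gold_faces],
            }
            fh.write(json.dumps(rec) + "\n")


def read_frames_jsonl(path) -> list[FrameObservation]:
    frames = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            faces = [
                CandidateFace(
                    tuple(f["box"]), f["score"],
                    np.asarray(f["embedding"], dtype=float),
                    np.asarray(f["gaze"], dtype=float),
                    f["true_identity"], f["true_gaze_on_tv"],
                )
                for f in rec["faces"]
            ]
            gold_faces = [
                GoldFace(tuple(g["box"]), g["identity"], g["gaze_on_tv"])
                for g in rec["gold_faces"]
            ]
            frames.append(FrameObservation(rec["frame_index"], rec["t"],
                                           faces, gold_faces))
    return frames


def frames_jsonl_string(frames: Iterable[FrameObservation]) -> str:
    buf = io.StringIO()
    for frame in frames:
        rec = {
            "frame_index": frame.frame_index,
            "t": frame.t,
            "faces": [_face_to_dict(f) for f in frame.faces],
            "gold_faces": [_gold_face_to_dict(g) for g in frame.gold_faces],
        }
        buf.write(json.dumps(rec) + "\n")
    return buf.getvalue()
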