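# Methods

## The measurement model

The device estimates one quantity — the total time a target child's gaze
is on a television — by making a binary *viewing* decision per video
frame and summing. A frame counts as viewing only if all three stages
agree: a face was detected, that face was verified as the target child,
and its gaze direction fell inside the calibrated angular limits.
Frames failing any stage (including frames where the child is absent)
contribute "not viewing". This asymmetric construction means stage
errors compound toward *under*-estimation: the pipeline cannot credit
viewing time it did not positively observe, but it can lose time at any
stage.

### Detection

The detector backend is any callable producing scored boxes; the package
owns only the thresholding machinery. The ROC is computed over score
thresholds against per-frame gold boxes (greedy one-to-one IoU ≥ 0.5
matching; true negatives are meaningless for detection, so only
sensitivity, PPV and FP/s are reported). FP/s is normalized by total
recording wall-time, not by frames containing faces. The operating-point
rule returns the largest threshold meeting a sensitivity floor (default
0.925) under an FP/s cap (default 0.79); if the floor is unreachable it
maximizes sensitivity under the cap; if the cap is unreachable it raises
with the attainable frontier. The permissive defaults encode the design
philosophy that false negatives are the expensive error — downstream
verification screens nearly all spurious boxes, since a random image
patch's embedding essentially never correlates 0.93 with the child's
gallery.

### Verification

Match score = max over gallery rows of the Pearson correlation between
embeddings. Max (not mean) aggregation keeps a pose-diverse gallery
useful: one good match suffices. The 0.93 threshold is the calibrated
operating value of the embedding network this harness emulates; the
config records whatever value a run uses. Identity continuity: boxes are
associated frame-to-frame by greedy IoU ≥ 0.3 into tracks (a track ends
after `gap` unmatched frames, default 0), and each frame's raw
threshold decision is replaced by the majority of raw decisions in a
15-frame centered window (~1 s at 15 fps) clipped to the track, ties
keeping the raw decision. Smoothing operates on *decisions*, not scores
— a deliberate choice where the design was open; it makes the smoothed
output invariant to monotone rescaling of scores and keeps the majority
oracle exact in tests. At most one face per frame is accepted as the
target (highest score among smoothed positives; ties to the lowest
index).

### Gaze

Angles use the mirrored camera convention — x right, y down, z positive
*toward* the camera — so a viewer looking straight at the camera (which
sits on top of the screen) has gaze (0,0,1) and yaw/pitch near zero.
With the textbook "z into scene" convention, on-screen gaze vectors
cluster at yaw ±180° and quantile windows on yaw become meaningless at
the wrap-around; the mirrored convention puts all on-screen angles in a
contiguous range. Windows are fitted per cell of an equal 3×3 grid over
the frame (the frame must be partitioned because the correct "looking at
the TV" direction depends on where the face is), per television position
(center / left; "other" requires user-supplied screen geometry), as the
central 90% quantile interval of watching-frame angles. Cells with fewer
than 30 watching frames inherit the globally pooled window.
Classification is inclusive on boundaries. Both yaw and pitch are tested
by default; a yaw-only mode is a config switch, since a one-angle
formulation is also defensible and cheaper to calibrate. Evaluation is
leave-one-family-out within television position; a position represented
by a single family cannot be cross-validated and is skipped with a
warning.

### Totals, epochs, evaluation denominators

Total time = viewing frames / fps, formatted m:ss. Epoch smoothing
relabels fixed windows (e.g. 5/15/30 s) by frame majority, ties →
viewing, the final partial epoch judged on the frames it has; output
stays at frame resolution so time arithmetic is unchanged. In agreement
analyses, gold *cannot tell* frames are excluded from denominators but
the device log keeps its predictions for them (a measurement device must
emit output); *out of frame* counts as not-watching, because the
operational definition of viewing requires presence.

## Agreement statistics

Confusion-matrix metrics follow the standard formulas with the contract
that a zero denominator yields an explicit undefined (`None`), never 0.
PABAK = 2·P₀ − 1; its 95% CI treats observed agreement as a binomial
proportion (a standard large-sample interval — the CI method behind the
published-style intervals is not otherwise specified). Cohen's κ is the
usual (P₀−Pe)/(1−Pe) over the four duration codes. The frame-level ICC
is a two-way absolute-agreement ICC(A,1) computed by ANOVA mean squares
on the 0/1 ratings, with the (family, frame) pair as subject — i.e.
frames nested in families — as a linear-probability stand-in for a
binary GLMM; the divergence is recorded in report metadata, and the
estimator is cross-checked against an independent implementation
(pingouin) in the tests. The total-time ICC applies the same estimator
to log-transformed per-family totals (totals treated as lognormal).
Interpretation bands: ≤ 0.35 weak, 0.36–0.67 moderate, ≥ 0.68 high,
≥ 0.9 very high. Cross-visit reliability uses the two-sided Wilcoxon
signed-rank test (exact distribution for ≤ 25 untied nonzero
differences, tie-corrected normal approximation otherwise; all-zero
differences return p = 1 with a degenerate flag). Group-stratified
viewing-time summaries report mean (SD) only — the family counts per
group are too small for inference.

## The synthetic session generator

The generator emulates the study conditions, not pixels. Defaults: a
90-minute session at 15 fps, 1280×720 frames (≈1 MP wide-angle webcam,
90° horizontal FOV pinhole model), three people (target child, sibling,
parent) seated on a fixed 9-seat grid 2.4–3.6 m from the camera,
re-seating every 60 s (the protocol has people move around the room),
128-dimensional identity embeddings with centroids separated 90° on the
unit hypersphere, per-second gaze switching rates 0.06 (watch→not) and
0.02 (not→watch) giving ≈25% stationary watching — about the observed
gold fraction of a 90-minute session — and a room-exit process (0.002/s,
mean 20 s) during which the child is *out of frame*.

The discrete shared seat grid is load-bearing: it gives all simulated
families the same support of face-position/gaze-angle atoms, which is
what makes noiseless leave-one-family-out calibration exactly
transferable. Head position is a property of the seat, not the person.

Noise model, all per-frame and independent: detector miss probability
(base 0.01), detector score noise (true faces N(0.82, 0.10) clipped to
[0,1], spurious N(0.50, 0.15)), spurious candidates at 2/s with random
boxes and isotropic random embeddings, embedding noise (Gaussian around
the identity centroid, then renormalized), angular gaze noise (Gaussian
on yaw and pitch), and seat jitter (σ = 0.05 m). Lighting multiplies
miss probability, embedding noise and gaze noise by (1,1,1) bright,
(2,2,2) dim, (4,4,4) dark, and shifts the true-score mean down 0.08 per
multiplier step. The embedding noise scale (0.013) was calibrated once
so that, against the 0.93 match threshold, the three lighting conditions
reproduce the qualitative regimes reported for this class of device:
near-perfect verification in bright light, visibly degraded (~0.8
sensitivity) in dim light, collapse in darkness.

When watching, the gaze vector points from the seat to the 3-D screen
center (just below the camera; laterally offset for a left-corner
television) with the angular noise above. When not watching, the
direction is uniform on the sphere *outside* an exclusion cone around
the to-screen direction of half-angle 2×(effective gaze noise) + the
screen's angular radius + a 12° behavioral margin. The margin encodes
that human coders label marginal directions *cannot tell* rather than
*not watching*; technically it also guarantees that off-screen
directions from one seat cannot fall inside the angular window
contributed by another seat of the same grid cell, keeping the classes
separable in the noiseless limit. Off-cone sampling is direct (no
rejection), so the number of random draws per frame never depends on
parameters; combined with a fixed draw order and a truth/observation
stream split, sessions sharing a seed but differing in lighting are
coupled through common random numbers and degrade pointwise
monotonically.

A `noiseless()` preset zeroes every stochastic corruption (gaze,
embedding, score noise, misses, spurious boxes, jitter) while keeping
ground-truth events (switching, exits, re-seating); on such sessions the
pipeline must reproduce the gold watching indicator frame for frame, and
the tests assert that it does, including over a full 90-minute session.

What the generator does **not** model: real image content (pose,
occlusion, expression), coder labeling error (gold logs are exact; an
optional code-corruption helper exists only to exercise inter-rater
statistics), correlated noise over time, multiple screens, furniture
occlusion, and any systematic dependence of embedding quality on
demographics. Consequently, passing tests demonstrate the correctness
and calibration of the measurement logic under the stated noise model —
not the field performance of any particular detector, embedder or gaze
network, which enter as backends.

## Numerical and design choices

- Half-open frame intervals [start, end), 0-based indices everywhere.
- Greedy descending-IoU matching for detection evaluation (standard
  practice; ties broken by index), IoU 0.5 for evaluation, 0.3 for
  track association.
- Per-family metrics are aggregated as unweighted family means with
  (min, max) ranges by default — the presentation style of small-cohort
  device studies; pooled-count aggregation is provided alongside.
- Detection strata (gaze-on / gaze-off) restrict gold faces to the
  target child on frames with the corresponding code; stratum PPV counts
  unmatched predictions on stratum frames as false positives.
- Quantile windows rather than discriminative optimization for gaze
  calibration: simplest estimator consistent with "set angular limits",
  with the coverage quantile exposed in config.
- Undefined metrics propagate as `None` in all reports, never imputed.
- Study sizes in the acceptance script (15 families × 7 minutes at
  15 fps) keep a full from-scratch rerun under a minute while leaving
  every per-family metric well-determined; the statistics scale
  unchanged to longer sessions.

## Known limitations

The frame-level ICC's linear-probability approximation understates the
GLMM's latent-scale ICC for extreme prevalences. The PABAK CI assumes
exchangeable frames and ignores serial correlation, so it is anti-
conservative on strongly autocorrelated logs (the same caveat applies to
any frame-level interval here). Verification sensitivity interacts with
the track-gap setting: with gap 0, a single missed detection splits a
track and resets the smoothing window. The simulator's independence
assumptions make frame-level agreement statistics optimistic relative to
video data with correlated errors.
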