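"""Agreement and performance statistics for binary viewing time series.

Covers the confusion-matrix metrics (accuracy, sensitivity, specificity,
PPV, NPV, FPR), the prevalence- and bias-adjusted kappa (PABAK = 2*Po - 1),
Cohen's kappa over the four duration codes, intraclass correlation for
frame-level binary agreement (frames nested in families) and for
log-transformed total viewing times, the cross-visit Wilcoxon signed-rank
test, interpretation bands, and group-stratified summaries of viewing
totals.

The frame-level ICC is an ANOVA-style two-way absolute-agreement
estimator, ICC(A,1), applied to the 0/1 ratings with the (family, frame)
pair as the subject — a linear-probability stand-in for a binary
generalized linear mixed model, recorded as such in report metadata.
Undefined metrics (zero denominators) propagate as ``None``, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import CANNOT_TELL, GOLD_CODES, OUT_OF_FRAME, WATCHING, GoldLog
from .pipeline import ViewingLog

#: interpretation cut points for correlation-type agreement coefficients
ICC_BANDS = ((0.35, "weak"), (0.68, "moderate"), (0.90, "high"))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV and FPR from a
    confusion matrix; zero denominators yield ``None``."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return {
        "accuracy": ratio(c.tp + c.tn, c.total),
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "fpr": ratio(c.fp, c.fp + c.tn),
    }


def counts_from_series(pred: Sequence[bool], gold: Sequence[bool]) -> ConfusionCounts:
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("series lengths differ")
    return ConfusionCounts(
        tp=int(np.sum(p & g)), tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)), fn=int(np.sum(~p & g)),
    )


def pabak(pred: Sequence[bool], gold: Sequence[bool]) -> float:
    """Prevalence- and bias-adjusted kappa: 2 * observed agreement - 1.

    Robust to the skewed prevalence of viewing frames, unlike plain
    kappa.
    """
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    if p.shape != g.shape:
        raise ValueError("series lengths differ")
    if p.size == 0:
        raise ValueError("empty series")
    po = float(np.mean(p == g))
    return 2.0 * po - 1.0


def pabak_ci(pred: Sequence[bool], gold: Sequence[bool],
             level: float = 0.95) -> tuple[float, float]:
    """Large-sample proportion-based confidence interval for PABAK.

    Treats observed agreement as a binomial proportion and maps its normal
    -approximation interval through 2*Po - 1. A standard large-sample
    interval; the frames are assumed exchangeable.
    """
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    n = p.size
    if n == 0:
        raise ValueError("empty series")
    po = float(np.mean(p == g))
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(po * (1 - po), 0.0) / n)
    return (2 * (po - half) - 1, 2 * (po + half) - 1)


def cohen_kappa(coder1: Sequence, coder2: Sequence) -> float | None:
    """Cohen's kappa for two categorical raters (e.g. the four duration
    codes). ``None`` when expected agreement is 1 (kappa undefined)."""
    a = np.asarray(coder1)
    b = np.asarray(coder2)
    if a.shape != b.shape:
        raise ValueError("series lengths differ")
    if a.size == 0:
        raise ValueError("empty series")
    cats = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a.tolist(), b.tolist()):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    po = np.trace(table) / n
    pe = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    if pe >= 1.0 - 1e-15:
        return None
    return float((po - pe) / (1.0 - pe))


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


def _icc_a1(ratings: np.ndarray) -> float | None:
    """Two-way absolute-agreement ICC(A,1) from an n x k ratings matrix
    (McGraw & Wong), via ANOVA mean squares."""
    n, k = ratings.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = ratings - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if abs(denom) < 1e-300:
        return None
    return float((msr - mse) / denom)


def icc_frame(pred: Sequence[bool], gold: Sequence[bool],
              family_ids: Sequence) -> dict:
    """Frame-level binary agreement ICC between the device and the gold
    standard, with frames nested in families.

    Each (family, frame) pair is one subject rated by two raters (device,
    coder) on a 0/1 scale; the estimator is absolute-agreement ICC(A,1).
    Returns the value plus metadata noting the linear-probability
    approximation of a binary mixed model.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    fam = np.asarray(family_ids)
    if not (p.shape == g.shape == fam.shape):
        raise ValueError("series lengths differ")
    if len(set(fam.tolist())) < 2:
        raise ValueError("need at least 2 families")
    value = _icc_a1(np.column_stack([p, g]))
    return {
        "icc": value,
        "n_frames": int(p.size),
        "n_families": len(set(fam.tolist())),
        "estimator": "ANOVA ICC(A,1) on 0/1 ratings, subject = frame "
                     "nested in family (linear-probability approximation "
                     "of a binary mixed model)",
    }


def icc_total_time(est_minutes: Sequence[float],
                   gold_minutes: Sequence[float]) -> float | None:
    """Absolute-agreement ICC of log-transformed per-family viewing
    totals (the totals are modeled as lognormal)."""
    est = np.asarray(est_minutes, dtype=float)
    gold = np.asarray(gold_minutes, dtype=float)
    if est.shape != gold.shape:
        raise ValueError("series lengths differ")
    if est.size < 3:
        raise ValueError("need at least 3 families")
    if np.any(est <= 0) or np.any(gold <= 0):
        raise ValueError("totals must be positive for the log transform")
    return _icc_a1(np.column_stack([np.log(est), np.log(gold)]))


def classify_icc(value: float) -> str:
    """Interpretation band: <=0.35 weak, 0.36-0.67 moderate, >=0.68 high,
    >=0.9 very high."""
    if not -1.0 <= value <= 1.0:
        raise ValueError("ICC must be in [-1, 1]")
    for cut, band in ICC_BANDS:
        if value <= cut if band == "weak" else value < cut:
            return band
    return "very_high"


# ---------------------------------------------------------------------------
# Cross-visit reliability
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_pairs: int
    degenerate: bool = False
    method: str = ""


def wilcoxon_visits(visit1: Sequence[float], visit2: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of paired per-family metrics
    across visits.

    Exact null distribution when <= 25 nonzero untied differences, tie
    -corrected normal approximation otherwise. All-zero differences give
    p = 1 with a degenerate-data flag.
    """
    x = np.asarray(visit1, dtype=float)
    y = np.asarray(visit2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series lengths differ")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return WilcoxonResult(0.0, 1.0, int(x.size), degenerate=True,
                              method="degenerate")
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if nonzero.size <= 25 and not ties else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          int(x.size), method=method)


# ---------------------------------------------------------------------------
# Stratified summaries and composite reports
# ---------------------------------------------------------------------------


def stratified_summary(est_minutes: Sequence[float],
                       gold_minutes: Sequence[float],
                       group_labels: Sequence) -> pd.DataFrame:
    """Per-group mean (SD) of estimated and gold viewing minutes.

    Descriptive only — no inferential comparisons are attached, since the
    per-group family counts in this design are far too small. Singleton
    groups have undefined (NaN) SD.
    """
    est = np.asarray(est_minutes, dtype=float)
    gold = np.asarray(gold_minutes, dtype=float)
    labels = list(group_labels)
    if not (len(est) == len(gold) == len(labels)):
        raise ValueError("every family needs a label and both totals")
    df = pd.DataFrame({"group": labels, "estimated": est, "gold": gold})
    out = df.groupby("group", sort=True).agg(
        n=("estimated", "size"),
        estimated_mean=("estimated", "mean"),
        estimated_sd=("estimated", lambda s: s.std(ddof=1)),
        gold_mean=("gold", "mean"),
        gold_sd=("gold", lambda s: s.std(ddof=1)),
    ).reset_index()
    return out


@dataclass
class AgreementReport:
    """Full frame-level agreement report between a viewing log and a gold
    log (plus optional family-level ICCs)."""

    counts: ConfusionCounts
    metrics: dict
    pabak: float
    pabak_ci95: tuple[float, float]
    kappa: float | None
    icc_frame: float | None = None
    icc_frame_band: str | None = None
    icc_total: float | None = None
    icc_total_band: str | None = None
    n_excluded_cannot_tell: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "counts": {"tp": self.counts.tp, "tn": self.counts.tn,
                       "fp": self.counts.fp, "fn": self.counts.fn},
            "metrics": self.metrics,
            "pabak": self.pabak,
            "pabak_ci95": list(self.pabak_ci95),
            "kappa": self.kappa,
            "icc_frame": self.icc_frame,
            "icc_frame_band": self.icc_frame_band,
            "icc_total": self.icc_total,
            "icc_total_band": self.icc_total_band,
            "n_excluded_cannot_tell": self.n_excluded_cannot_tell,
            "metadata": self.metadata,
        }


def align_binary(log: ViewingLog, gold: GoldLog) -> tuple[np.ndarray, np.ndarray, int]:
    """Binary (device, gold) series on codable frames.

    Gold 'watching' maps to True; 'not watching' and 'out of frame' to
    False (viewing requires presence); 'cannot tell' frames are excluded
    from both series. The device log keeps its predicted values on the
    excluded frames — only the comparison drops them.
    """
    codes = gold.codes()
    n = min(log.n_frames, len(codes))
    codes = codes[:n]
    pred = log.decisions[:n]
    keep = codes != CANNOT_TELL
    return pred[keep], (codes[keep] == WATCHING), int(n - keep.sum())


def agreement_report(log: ViewingLog, gold: GoldLog,
                     family_ids: Sequence | None = None) -> AgreementReport:
    """Frame-level agreement between a device viewing log and a gold log."""
    pred, truth, n_excl = align_binary(log, gold)
    counts = counts_from_series(pred, truth)
    pk = pabak(pred, truth)
    report = AgreementReport(
        counts=counts,
        metrics=metrics_from_counts(counts),
        pabak=pk,
        pabak_ci95=pabak_ci(pred, truth),
        kappa=cohen_kappa(pred, truth),
        n_excluded_cannot_tell=n_excl,
    )
    if family_ids is not None:
        fam = np.asarray(family_ids)
        codes = gold.codes()[: len(fam)]
        fam = fam[: len(pred) + n_excl][codes[: len(pred) + n_excl] != CANNOT_TELL]
        frame_res = icc_frame(pred, truth, fam)
        report.icc_frame = frame_res["icc"]
        if report.icc_frame is not None:
            report.icc_frame_band = classify_icc(report.icc_frame)
        report.metadata["icc_estimator"] = frame_res["estimator"]
    return report
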