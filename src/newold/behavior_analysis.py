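"""Session-level recognition-memory behavior: confidence ROC, AUC, zROC.

The recognition block yields, per trial, a ground-truth label (old/new) and a
six-level confidence response (codes 31-36, new-confident through
old-confident).  Treating each confidence level as a decision criterion gives
six cumulative (false-alarm, hit) points; the area under that curve (AUC)
measures how well the subject separates old from new items (0.5 = chance),
and the slope of the probit-transformed curve (zROC) measures asymmetry —
slopes below 1 are the signature of unequal-variance memory-strength
distributions typical of declarative memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .core_model import RECOGNITION, RECOGNITION_RESPONSE_CODES, TrialRecord

__all__ = [
    "ConfusionCounts",
    "ROCResult",
    "confidence_counts",
    "roc_points",
    "auc_trapezoid",
    "mann_whitney_auc",
    "zroc_slope",
    "confidence_accuracy_split",
    "session_behavior_summary",
]

_CODES = np.array(RECOGNITION_RESPONSE_CODES)


@dataclass
class ConfusionCounts:
    """2x6 response-count table: rows (old, new) x columns codes 31..36."""

    old: np.ndarray
    new: np.ndarray

    def __post_init__(self):
        self.old = np.asarray(self.old, dtype=np.int64)
        self.new = np.asarray(self.new, dtype=np.int64)
        if self.old.shape != (6,) or self.new.shape != (6,):
            raise ValueError("count rows must each have 6 entries (codes 31..36)")
        if (self.old < 0).any() or (self.new < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class ROCResult:
    """Confidence-ROC summary for one session."""

    points: np.ndarray  # 6 x 2 array of (false_alarm, hit), strictest first
    auc: float
    zroc_slope: Optional[float]
    slope_ci: Optional[Tuple[float, float]]
    asymmetric: Optional[bool]


def confidence_counts(trials: Sequence[TrialRecord]) -> ConfusionCounts:
    """Tabulate responses by ground truth over recognition trials."""
    old = np.zeros(6, dtype=np.int64)
    new = np.zeros(6, dtype=np.int64)
    for t in trials:
        if t.phase != RECOGNITION or t.new_old_label not in (0, 1):
            raise ValueError("confidence_counts requires labeled recognition trials")
        if t.response_value not in RECOGNITION_RESPONSE_CODES:
            raise ValueError(f"illegal recognition response {t.response_value}")
        row = old if t.new_old_label == 0 else new
        row[t.response_value - 31] += 1
    return ConfusionCounts(old=old, new=new)


def roc_points(counts: ConfusionCounts) -> np.ndarray:
    """Cumulative (false-alarm, hit) points, most conservative criterion first.

    For criterion code t in 36, 35, ..., 31: hit(t) = P(response >= t | old),
    fa(t) = P(response >= t | new).  The last point (t = 31) is (1, 1).
    """
    n_old, n_new = counts.old.sum(), counts.new.sum()
    if n_old == 0 or n_new == 0:
        raise ValueError("both old and new trials are required for an ROC")
    hits = np.cumsum(counts.old[::-1]) / n_old
    fas = np.cumsum(counts.new[::-1]) / n_new
    return np.column_stack([fas, hits])


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoidal area under the ROC anchored at (0, 0)."""
    pts = np.asarray(points, dtype=float)
    if (np.diff(pts, axis=0) < -1e-12).any():
        raise ValueError("ROC points must be nondecreasing in both coordinates")
    fa = np.concatenate([[0.0], pts[:, 0]])
    hit = np.concatenate([[0.0], pts[:, 1]])
    return float(np.trapezoid(hit, fa))


def mann_whitney_auc(labels: Sequence[int], responses: Sequence[int]) -> float:
    """Rank-based AUC oracle: P(resp_old > resp_new) + 0.5 P(tie).

    Equivalent to the normalized Mann-Whitney U statistic on the
    (label, response) pairs; used as an independent cross-check of the
    trapezoidal confidence-ROC area.
    """
    labels = np.asarray(labels)
    resp = np.asarray(responses, dtype=float)
    old = resp[labels == 0]
    new = resp[labels == 1]
    if len(old) == 0 or len(new) == 0:
        raise ValueError("need both old and new trials")
    greater = (old[:, None] > new[None, :]).sum()
    ties = (old[:, None] == new[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(old) * len(new)))


def _interior_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    ok = (
        (pts[:, 0] > 0) & (pts[:, 0] < 1) & (pts[:, 1] > 0) & (pts[:, 1] < 1)
    )
    return pts[ok]


def _probit_slope(points: np.ndarray) -> Optional[float]:
    interior = _interior_points(points)
    if len(interior) < 2:
        return None
    zf = norm.ppf(interior[:, 0])
    zh = norm.ppf(interior[:, 1])
    if np.ptp(zf) == 0:
        return None
    slope = np.polyfit(zf, zh, 1)[0]
    return float(slope)


def zroc_slope(
    trials: Sequence[TrialRecord],
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> Tuple[Optional[float], Optional[Tuple[float, float]], Optional[bool]]:
    """Least-squares slope of probit(hit) on probit(fa) over interior points.

    Points with a hit or false-alarm rate of exactly 0 or 1 fall outside the
    probit domain and are excluded.  The confidence interval comes from a
    nonparametric bootstrap over trials; the session is flagged asymmetric
    when the CI excludes 1.  Returns (None, None, None) when fewer than two
    usable points exist.
    """
    trials = list(trials)
    slope = _probit_slope(roc_points(confidence_counts(trials)))
    if slope is None:
        return None, None, None
    rng = np.random.default_rng(seed)
    labels = np.array([t.new_old_label for t in trials])
    resp = np.array([t.response_value for t in trials])
    n = len(trials)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab_b, resp_b = labels[idx], resp[idx]
        old = np.bincount(resp_b[lab_b == 0] - 31, minlength=6)
        new = np.bincount(resp_b[lab_b == 1] - 31, minlength=6)
        if old.sum() == 0 or new.sum() == 0:
            continue
        s = _probit_slope(roc_points(ConfusionCounts(old=old, new=new)))
        if s is not None:
            boot.append(s)
    if len(boot) < max(10, n_boot // 10):
        return slope, None, None
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return slope, (float(lo), float(hi)), not (lo <= 1.0 <= hi)


def confidence_accuracy_split(
    trials: Sequence[TrialRecord],
    high_codes: Sequence[int] = (31, 36),
) -> Tuple[Optional[float], Optional[float], int, int]:
    """Old/new judgment accuracy separately for high- vs low-confidence trials.

    A judgment is correct when it matches the ground truth (codes >= 34 mean
    "old", labels use 0 = old).  By default "high confidence" means the two
    extreme (confident) codes; the grouping is a parameter.  Empty groups
    yield accuracy None.
    """
    high_codes = set(high_codes)
    n_high = n_low = c_high = c_low = 0
    for t in trials:
        if t.phase != RECOGNITION or t.new_old_label not in (0, 1):
            raise ValueError("requires labeled recognition trials")
        judged_old = t.response_value >= 34
        correct = judged_old == (t.new_old_label == 0)
        if t.response_value in high_codes:
            n_high += 1
            c_high += correct
        else:
            n_low += 1
            c_low += correct
    acc_high = c_high / n_high if n_high else None
    acc_low = c_low / n_low if n_low else None
    return acc_high, acc_low, n_high, n_low


def session_behavior_summary(
    trials: Sequence[TrialRecord],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Flat per-session behavior summary (one row of the export table)."""
    recog = [t for t in trials if t.phase == RECOGNITION]
    counts = confidence_counts(recog)
    pts = roc_points(counts)
    auc = auc_trapezoid(pts)
    slope, ci, asym = zroc_slope(recog, n_boot=n_boot, seed=seed)
    acc_high, acc_low, n_high, n_low = confidence_accuracy_split(recog)
    return {
        "n_trials": len(recog),
        "auc": auc,
        "zroc_slope": slope,
        "zroc_slope_ci_low": None if ci is None else ci[0],
        "zroc_slope_ci_high": None if ci is None else ci[1],
        "asymmetric": asym,
        "acc_high": acc_high,
        "acc_low": acc_low,
        "n_high": n_high,
        "n_low": n_low,
    }
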