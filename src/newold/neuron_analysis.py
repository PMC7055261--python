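"""Single-neuron analyses: firing rates, PSTH, VS/MS screening, unit QC.

Two functional cell classes are screened for in the medial temporal lobe
during the new/old task:

* **VS (visually selective) cells** — firing rate in a 1 s window starting
  200 ms after stimulus onset depends on the image's visual category
  (one-way ANOVA across the five categories, on recognition trials).
* **MS (memory selective) cells** — firing rate in the same window differs
  between the 50 novel and 50 familiar recognition trials (two-tailed
  bootstrap comparison of means, 1000 resamples).

Units passing both screens are "dual".  Sorting-quality metrics (ISI
refractory violations, waveform SNR, isolation distance) follow the standard
definitions used for human microwire recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import RECOGNITION, TrialRecord, UnitRecord

__all__ = [
    "AnalysisWindow",
    "SelectionConfig",
    "UnitSelectionResult",
    "PopulationSummary",
    "trial_rates",
    "psth",
    "select_vs_anova",
    "select_ms_bootstrap",
    "classify_units_population",
    "screen_units",
    "isi_violation_fraction",
    "compute_snr",
    "isolation_distance",
    "plot_raster_psth",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open rate window [onset + offset_s, onset + offset_s + length_s)."""

    offset_s: float = 0.2
    length_s: float = 1.0

    def __post_init__(self):
        if self.length_s <= 0:
            raise ValueError("window length must be > 0")


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    window: AnalysisWindow = field(default_factory=AnalysisWindow)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass
class UnitSelectionResult:
    unit_id: int
    p_vs: float
    p_ms: float
    label: str  # none | VS | MS | dual


@dataclass
class PopulationSummary:
    n_units: int
    n_vs: int
    n_ms: int
    n_dual: int

    @property
    def prop_vs(self) -> float:
        return self.n_vs / self.n_units if self.n_units else 0.0

    @property
    def prop_ms(self) -> float:
        return self.n_ms / self.n_units if self.n_units else 0.0

    @property
    def prop_dual(self) -> float:
        return self.n_dual / self.n_units if self.n_units else 0.0


# ---------------------------------------------------------------------------
# Rates and PSTH
# ---------------------------------------------------------------------------


def trial_rates(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    window: AnalysisWindow = AnalysisWindow(),
) -> np.ndarray:
    """Per-trial firing rate (Hz) in the analysis window after stimulus onset.

    Spikes are counted in the half-open window [t0, t0 + length); a spike
    exactly at the right edge belongs to the next window, never to two.
    """
    st = np.asarray(spike_times, dtype=float)
    onsets = np.array([t.start_time for t in trials])
    lo = onsets + window.offset_s
    hi = lo + window.length_s
    counts = np.searchsorted(st, hi, side="left") - np.searchsorted(
        st, lo, side="left"
    )
    return counts / window.length_s


def psth(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    bin_s: float = 0.1,
    range_s: tuple = (-0.5, 2.0),
):
    """Trial-aligned binned spike counts plus the mean rate curve.

    Returns ``(matrix, rate, edges)`` where ``matrix`` is trials x bins
    counts, ``rate`` is the across-trial mean count per bin divided by the
    bin width (Hz), and ``edges`` are the bin edges in seconds relative to
    stimulus onset.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    st = np.asarray(spike_times, dtype=float)
    edges = np.arange(range_s[0], range_s[1] + bin_s / 2, bin_s)
    mat = np.zeros((len(trials), len(edges) - 1), dtype=np.int64)
    for i, t in enumerate(trials):
        aligned = st - t.start_time
        mat[i], _ = np.histogram(aligned, bins=edges)
    rate = mat.mean(axis=0) / bin_s if len(trials) else np.zeros(len(edges) - 1)
    return mat, rate, edges


# ---------------------------------------------------------------------------
# Selection screens
# ---------------------------------------------------------------------------


def select_vs_anova(
    spike_times: np.ndarray,
    recognition_trials: Sequence[TrialRecord],
    cfg: SelectionConfig = SelectionConfig(),
) -> float:
    """One-way ANOVA p-value for category tuning (visual selectivity).

    Trial rates in the analysis window are grouped by the five visual
    categories; requires all five levels present with at least two trials
    each, and raises otherwise rather than silently testing fewer groups.
    """
    trials = list(recognition_trials)
    rates = trial_rates(spike_times, trials, cfg.window)
    cats = np.array([t.category_name for t in trials])
    levels = sorted(set(cats))
    if len(levels) != 5:
        raise ValueError(f"expected 5 category levels, found {len(levels)}")
    groups = [rates[cats == c] for c in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each category needs at least 2 trials")
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0  # identical rates everywhere: F = 0
    f, p = stats.f_oneway(*groups)
    return float(p)


def select_ms_bootstrap(
    spike_times: np.ndarray,
    recognition_trials: Sequence[TrialRecord],
    cfg: SelectionConfig = SelectionConfig(),
) -> float:
    """Two-tailed bootstrap p-value for a new-vs-old mean rate difference.

    The null is built by pooling the rates of both conditions and resampling
    with replacement into two groups of the original sizes, ``n_boot``
    times; p = (1 + #{|d*| >= |d|}) / (n_boot + 1), which is positive by
    construction and deterministic given the seed.
    """
    trials = list(recognition_trials)
    rates = trial_rates(spike_times, trials, cfg.window)
    labels = np.array([t.new_old_label for t in trials])
    new_r, old_r = rates[labels == 1], rates[labels == 0]
    if len(new_r) == 0 or len(old_r) == 0:
        raise ValueError("both new and old trials are required")
    observed = abs(new_r.mean() - old_r.mean())
    pooled = np.concatenate([new_r, old_r])
    rng = np.random.default_rng(cfg.seed)
    n_new = len(new_r)
    idx = rng.integers(0, len(pooled), size=(cfg.n_boot, len(pooled)))
    draws = pooled[idx]
    diffs = np.abs(
        draws[:, :n_new].mean(axis=1) - draws[:, n_new:].mean(axis=1)
    )
    return float((1 + np.sum(diffs >= observed - 1e-15)) / (cfg.n_boot + 1))


def classify_units_population(
    results: Sequence[UnitSelectionResult],
    cfg: SelectionConfig = SelectionConfig(),
) -> PopulationSummary:
    """Count VS / MS / dual units at the configured threshold.

    Dual units pass both screens and are counted in all three tallies, so
    ``n_dual <= min(n_vs, n_ms)``.
    """
    n_vs = sum(r.p_vs < cfg.alpha for r in results)
    n_ms = sum(r.p_ms < cfg.alpha for r in results)
    n_dual = sum(r.p_vs < cfg.alpha and r.p_ms < cfg.alpha for r in results)
    return PopulationSummary(
        n_units=len(results), n_vs=n_vs, n_ms=n_ms, n_dual=n_dual
    )


def screen_units(
    units: Sequence[UnitRecord],
    recognition_trials: Sequence[TrialRecord],
    cfg: SelectionConfig = SelectionConfig(),
) -> List[UnitSelectionResult]:
    """Run both screens on every unit; per-unit seeds derive from cfg.seed."""
    out = []
    for k, u in enumerate(units):
        unit_cfg = SelectionConfig(
            alpha=cfg.alpha,
            n_boot=cfg.n_boot,
            seed=(cfg.seed + 7919 * k) % (2**31),
            window=cfg.window,
        )
        p_vs = select_vs_anova(u.spike_times, recognition_trials, unit_cfg)
        p_ms = select_ms_bootstrap(u.spike_times, recognition_trials, unit_cfg)
        vs, ms = p_vs < cfg.alpha, p_ms < cfg.alpha
        label = "dual" if vs and ms else "VS" if vs else "MS" if ms else "none"
        out.append(
            UnitSelectionResult(unit_id=u.unit_id, p_vs=p_vs, p_ms=p_ms, label=label)
        )
    return out


# ---------------------------------------------------------------------------
# Sorting-quality metrics
# ---------------------------------------------------------------------------


def isi_violation_fraction(
    spike_times: np.ndarray, isi_threshold_s: float = 0.003
):
    """Fraction of inter-spike intervals below the refractory threshold.

    Returns ``(fraction, qc_pass)``; a unit passes only when strictly fewer
    than 3% of its ISIs violate the 3 ms refractory period.
    """
    st = np.asarray(spike_times, dtype=float)
    if len(st) < 2:
        return 0.0, True
    isis = np.diff(st)
    frac = float(np.mean(isis < isi_threshold_s))
    return frac, frac < 0.03


def compute_snr(waveform_mean: np.ndarray, noise_sd: float) -> float:
    """Peak absolute amplitude of the mean waveform over the noise sd."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    w = np.asarray(waveform_mean, dtype=float)
    if w.size == 0:
        return 0.0
    return float(np.max(np.abs(w)) / noise_sd)


def isolation_distance(
    cluster_features: np.ndarray, other_features: np.ndarray
) -> Optional[float]:
    """Mahalanobis isolation distance of a sorted cluster.

    The squared Mahalanobis distance (under the cluster's own covariance)
    of the n-th closest non-cluster spike, with n the cluster size.  Large
    values mean the cluster is well separated in feature space.  Returns
    None when undefined: fewer outside spikes than cluster spikes, or a
    singular cluster covariance.
    """
    X = np.asarray(cluster_features, dtype=float)
    Y = np.asarray(other_features, dtype=float)
    n = len(X)
    if len(Y) < n or n <= X.shape[1]:
        return None
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov_inv)):
        return None
    d = Y - mu
    md2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
    md2.sort()
    return float(md2[n - 1])


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------


def plot_raster_psth(
    spike_times: np.ndarray,
    trials: Sequence[TrialRecord],
    bin_s: float = 0.1,
    range_s: tuple = (-0.5, 2.0),
    ax_pair=None,
):
    """Raster (top) and PSTH (bottom) aligned to stimulus onset."""
    import matplotlib

    if ax_pair is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, (ax_r, ax_p) = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    else:
        ax_r, ax_p = ax_pair
        fig = ax_r.figure
    st = np.asarray(spike_times, dtype=float)
    for i, t in enumerate(trials):
        aligned = st - t.start_time
        sel = aligned[(aligned >= range_s[0]) & (aligned < range_s[1])]
        ax_r.vlines(sel, i + 0.5, i + 1.5, color="k", lw=0.5)
    ax_r.set_ylabel("trial")
    _, rate, edges = psth(st, trials, bin_s, range_s)
    ax_p.bar(edges[:-1], rate, width=bin_s, align="edge", color="steelblue")
    ax_p.axvline(0.0, color="r", ls="--", lw=0.8)
    ax_p.set_xlabel("time from stimulus onset (s)")
    ax_p.set_ylabel("rate (Hz)")
    return fig
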