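"""Simulation experiments that characterize the pipeline's statistics.

Each function builds its inputs from the synthetic-session machinery, runs
the corresponding analysis exactly as the pipeline would, and returns the
measured quantities.  They back the repository's analysis drivers and the
reproducibility script.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .behavior_analysis import (
    auc_trapezoid,
    confidence_counts,
    roc_points,
)
from .core_model import RECOGNITION, TrialRecord
from .neuron_analysis import (
    SelectionConfig,
    UnitSelectionResult,
    classify_units_population,
    select_ms_bootstrap,
    select_vs_anova,
)
from .synthetic_session import (
    BehaviorParams,
    NeuronSpec,
    simulate_recognition_behavior,
    simulate_spike_train,
)

__all__ = [
    "recognition_trial_template",
    "ms_bootstrap_null_calibration",
    "vs_anova_power",
    "population_recovery",
    "chance_auc_distribution",
    "auc_at_dprime",
]

_CATS = ["animals", "houses", "landscapes", "mobility", "phones"]


def recognition_trial_template(
    n_trials: int = 100, gap_s: float = 3.0
) -> List[TrialRecord]:
    """Balanced recognition block: categories cycle, labels alternate.

    50 new / 50 old and 20 trials per category at the default size — the
    condition the selection screens are defined over.
    """
    out = []
    for i in range(n_trials):
        t0 = i * gap_s
        out.append(
            TrialRecord(
                phase=RECOGNITION,
                start_time=t0,
                stop_time=t0 + 1.0,
                delay1_time=t0 + 1.5,
                response_time=t0 + 2.0,
                delay2_time=t0 + 2.5,
                response_value=35,
                category_name=_CATS[i % 5],
                stim_category=i % 5,
                stimulus_id=f"s{i}",
                new_old_label=i % 2,
            )
        )
    return out


def ms_bootstrap_null_calibration(
    n_units: int = 400,
    baseline_hz: float = 5.0,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """False-positive rate of the memory-selectivity screen on null units.

    Simulates homogeneous Poisson units (no tuning whatsoever) over a
    standard 50-new/50-old recognition block and runs the two-tailed pooled
    bootstrap mean comparison on each.  A calibrated test rejects close to
    the nominal alpha.
    """
    trials = recognition_trial_template()
    master = np.random.default_rng(seed)
    unit_seeds = master.integers(0, 2**31, size=n_units)
    pvals = np.empty(n_units)
    for k, s in enumerate(unit_seeds):
        rng = np.random.default_rng(s)
        spikes = simulate_spike_train(
            NeuronSpec(kind="none", baseline_hz=baseline_hz), trials, rng
        )
        cfg = SelectionConfig(alpha=alpha, n_boot=n_boot, seed=int(s))
        pvals[k] = select_ms_bootstrap(spikes, trials, cfg)
    rate = float(np.mean(pvals < alpha))
    return {"rejection_rate": rate, "n_units": n_units, "pvals": pvals}


def vs_anova_power(
    n_seeds: int = 100,
    baseline_hz: float = 5.0,
    category_gain: float = 3.0,
    alpha: float = 0.05,
    seed: int = 1,
) -> dict:
    """Detection rate of the category-tuning ANOVA on gain-tuned units."""
    trials = recognition_trial_template()
    master = np.random.default_rng(seed)
    unit_seeds = master.integers(0, 2**31, size=n_seeds)
    detected = 0
    for s in unit_seeds:
        rng = np.random.default_rng(s)
        spec = NeuronSpec(
            kind="VS",
            baseline_hz=baseline_hz,
            category_gain=category_gain,
            pref_category=_CATS[int(s) % 5],
        )
        spikes = simulate_spike_train(spec, trials, rng)
        detected += select_vs_anova(spikes, trials) < alpha
    return {"power": detected / n_seeds, "n_seeds": n_seeds}


def population_recovery(
    n_units: int = 200,
    frac_vs: float = 0.2,
    frac_ms: float = 0.1,
    baseline_hz: float = 5.0,
    gain: float = 3.0,
    n_boot: int = 1000,
    seed: int = 1,
) -> dict:
    """Recover a known VS/MS composition from simulated spike trains.

    Screens every unit with both selection tests and compares the estimated
    population proportions with the generating composition.  Estimates carry
    a small upward bias from false positives at the screening alpha.
    """
    trials = recognition_trial_template()
    master = np.random.default_rng(seed)
    n_vs = int(round(frac_vs * n_units))
    n_ms = int(round(frac_ms * n_units))
    kinds = ["VS"] * n_vs + ["MS"] * n_ms + ["none"] * (n_units - n_vs - n_ms)
    results = []
    cfg0 = SelectionConfig(n_boot=n_boot)
    for i, kind in enumerate(kinds):
        s = int(master.integers(0, 2**31))
        rng = np.random.default_rng(s)
        spec = NeuronSpec(
            kind=kind,
            baseline_hz=baseline_hz,
            category_gain=gain,
            memory_gain=gain,
            pref_category=_CATS[s % 5],
            pref_condition="new" if s % 2 else "old",
        )
        spikes = simulate_spike_train(spec, trials, rng)
        p_vs = select_vs_anova(spikes, trials, cfg0)
        p_ms = select_ms_bootstrap(
            spikes, trials, SelectionConfig(n_boot=n_boot, seed=s)
        )
        vs, ms = p_vs < cfg0.alpha, p_ms < cfg0.alpha
        label = "dual" if vs and ms else "VS" if vs else "MS" if ms else "none"
        results.append(UnitSelectionResult(i, p_vs, p_ms, label))
    pop = classify_units_population(results, cfg0)
    return {
        "true_frac_vs": n_vs / n_units,
        "true_frac_ms": n_ms / n_units,
        "est_frac_vs": pop.prop_vs,
        "est_frac_ms": pop.prop_ms,
        "est_frac_dual": pop.prop_dual,
        "n_units": n_units,
    }


def chance_auc_distribution(
    n_sessions: int = 200, n_trials: int = 100, seed: int = 1
) -> dict:
    """Mean session AUC under a memoryless (d' = 0) subject."""
    master = np.random.default_rng(seed)
    labels = np.array([0] * (n_trials // 2) + [1] * (n_trials // 2))
    params = BehaviorParams(d_prime=0.0)
    aucs = []
    for _ in range(n_sessions):
        codes, _ = simulate_recognition_behavior(labels, params, master)
        old = np.bincount(codes[labels == 0] - 31, minlength=6)
        new = np.bincount(codes[labels == 1] - 31, minlength=6)
        from .behavior_analysis import ConfusionCounts

        aucs.append(auc_trapezoid(roc_points(ConfusionCounts(old=old, new=new))))
    aucs = np.asarray(aucs)
    return {"mean_auc": float(aucs.mean()), "sd_auc": float(aucs.std(ddof=1)),
            "n_sessions": n_sessions}


def auc_at_dprime(d_prime: float = 1.5, n_trials: int = 20_000, seed: int = 1) -> dict:
    """Trapezoid confidence-ROC AUC at a given memory strength, large n."""
    rng = np.random.default_rng(seed)
    labels = np.array([0] * (n_trials // 2) + [1] * (n_trials // 2))
    codes, _ = simulate_recognition_behavior(
        labels, BehaviorParams(d_prime=d_prime), rng
    )
    from .behavior_analysis import ConfusionCounts

    old = np.bincount(codes[labels == 0] - 31, minlength=6)
    new = np.bincount(codes[labels == 1] - 31, minlength=6)
    auc = auc_trapezoid(roc_points(ConfusionCounts(old=old, new=new)))
    return {"auc": float(auc), "n_trials": n_trials}
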