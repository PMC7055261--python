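"""Firing rates, PSTH, VS/MS screening, and sorting-quality metrics."""

import numpy as np
import pytest
from scipy import stats

from newold.core_model import RECOGNITION, TrialRecord
from newold.neuron_analysis import (
    AnalysisWindow,
    SelectionConfig,
    UnitSelectionResult,
    classify_units_population,
    compute_snr,
    isi_violation_fraction,
    isolation_distance,
    psth,
    select_ms_bootstrap,
    select_vs_anova,
    trial_rates,
)
from newold.synthetic_session import NeuronSpec, simulate_spike_train

CATS = ["animals", "houses", "landscapes", "mobility", "phones"]


def _trials(n, gap=3.0, cats=None, labels=None):
    out = []
    for i in range(n):
        t0 = i * gap
        out.append(
            TrialRecord(
                phase=RECOGNITION, start_time=t0, stop_time=t0 + 1.0,
                delay1_time=t0 + 1.5, response_time=t0 + 2.0,
                delay2_time=t0 + 2.5, response_value=35,
                category_name=cats[i] if cats else CATS[i % 5],
                stim_category=0, stimulus_id=f"s{i}",
                new_old_label=labels[i] if labels else i % 2,
            )
        )
    return out


def _spikes_for_rates(trials, rates, window=AnalysisWindow()):
    """Place exactly `rates[i]` spikes inside trial i's analysis window."""
    spikes = []
    for t, r in zip(trials, rates):
        lo = t.start_time + window.offset_s
        spikes.extend(lo + 0.001 + k * (window.length_s / (r + 1)) for k in range(int(r)))
    return np.sort(np.array(spikes))


class TestTrialRates:
    def test_count_over_width(self):
        trials = _trials(1)
        rates = trial_rates(np.array([0.25, 0.5, 1.0]), trials)
        assert rates[0] == pytest.approx(3.0)

    def test_right_edge_excluded_half_open(self):
        trials = _trials(1)
        assert trial_rates(np.array([1.2]), trials)[0] == 0.0
        assert trial_rates(np.array([0.2]), trials)[0] == 1.0

    def test_no_spikes_zero_rate(self):
        assert trial_rates(np.array([]), _trials(3)).tolist() == [0.0, 0.0, 0.0]


class TestPsth:
    def test_flat_curve_for_homogeneous_unit(self, rng):
        trials = _trials(400, gap=4.0)
        spikes = simulate_spike_train(NeuronSpec(baseline_hz=5.0), trials, rng)
        _, rate, edges = psth(spikes, trials, bin_s=0.25, range_s=(0.0, 2.0))
        assert np.all(np.abs(rate - 5.0) < 1.5)

    def test_single_spike_per_trial_single_column(self):
        trials = _trials(10)
        spikes = np.sort(np.array([t.start_time + 0.35 for t in trials]))
        mat, rate, edges = psth(spikes, trials, bin_s=0.1, range_s=(0.0, 1.0))
        nonzero = np.nonzero(mat.sum(axis=0))[0]
        assert len(nonzero) == 1
        assert edges[nonzero[0]] == pytest.approx(0.3)

    def test_conservation_within_range(self, rng):
        trials = _trials(50)
        spikes = simulate_spike_train(NeuronSpec(baseline_hz=8.0), trials, rng)
        mat, _, edges = psth(spikes, trials, bin_s=0.1, range_s=(-0.5, 2.0))
        total = sum(
            np.sum((spikes - t.start_time >= -0.5) & (spikes - t.start_time < 2.0))
            for t in trials
        )
        assert mat.sum() == total


def _anova_oracle(groups):
    """Brute-force one-way ANOVA from explicit sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return f, float(stats.f.sf(f, df_b, df_w))


class TestVsAnova:
    def test_all_rates_equal_gives_p_one(self):
        trials = _trials(20)
        spikes = _spikes_for_rates(trials, [4] * 20)
        assert select_vs_anova(spikes, trials) == 1.0

    def test_matches_sums_of_squares_oracle_hand_data(self):
        per_cat = {c: v for c, v in zip(CATS, [(1, 2, 3), (2, 3, 4), (3, 4, 5),
                                               (4, 5, 6), (5, 6, 7)])}
        cats = [c for c in CATS for _ in range(3)]
        rates = [per_cat[c][i % 3] for i, c in enumerate(
            [c for c in CATS for _ in range(3)]
        )]
        trials = _trials(15, cats=cats)
        spikes = _spikes_for_rates(trials, rates)
        groups = [np.array(per_cat[c], dtype=float) for c in CATS]
        _, p_oracle = _anova_oracle(groups)
        assert select_vs_anova(spikes, trials) == pytest.approx(p_oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        trials = _trials(30)
        rates = rng.integers(0, 12, 30)
        spikes = _spikes_for_rates(trials, rates)
        cats = np.array([t.category_name for t in trials])
        groups = [rates[cats == c].astype(float) for c in sorted(set(cats))]
        _, p_oracle = _anova_oracle(groups)
        assert select_vs_anova(spikes, trials) == pytest.approx(p_oracle, abs=1e-10)

    def test_power_to_detect_gain_three_vs_unit(self):
        detected = 0
        n_seeds = 30
        trials = _trials(100)
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            spec = NeuronSpec(kind="VS", baseline_hz=5.0, category_gain=3.0,
                              pref_category="houses")
            spikes = simulate_spike_train(spec, trials, rng)
            detected += select_vs_anova(spikes, trials) < 0.05
        assert detected >= 0.9 * n_seeds

    def test_fewer_than_five_categories_rejected(self):
        trials = _trials(20, cats=["houses"] * 20)
        with pytest.raises(ValueError, match="5 category"):
            select_vs_anova(_spikes_for_rates(trials, [3] * 20), trials)


class TestMsBootstrap:
    def test_identical_conditions_give_p_one(self):
        trials = _trials(20)
        # same rate everywhere: observed difference exactly zero
        spikes = _spikes_for_rates(trials, [5] * 20)
        p = select_ms_bootstrap(spikes, trials, SelectionConfig(seed=0))
        assert p == 1.0

    def test_deterministic_given_seed(self, rng):
        trials = _trials(40)
        spikes = np.sort(rng.uniform(0, 120, 400))
        cfg = SelectionConfig(seed=33)
        assert select_ms_bootstrap(spikes, trials, cfg) == select_ms_bootstrap(
            spikes, trials, cfg
        )

    def test_power_on_strongly_tuned_unit(self):
        trials = _trials(100)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            spec = NeuronSpec(kind="MS", baseline_hz=1.0, memory_gain=10.0,
                              pref_condition="new")
            spikes = simulate_spike_train(spec, trials, rng)
            p = select_ms_bootstrap(spikes, trials, SelectionConfig(seed=seed))
            hits += p <= 0.05
        assert hits >= 0.95 * n_seeds

    def test_empty_condition_rejected(self):
        trials = _trials(10, labels=[1] * 10)
        with pytest.raises(ValueError):
            select_ms_bootstrap(np.array([0.5, 1.0]), trials)

    def test_p_value_never_zero(self, rng):
        trials = _trials(30)
        spec = NeuronSpec(kind="MS", baseline_hz=2.0, memory_gain=50.0)
        spikes = simulate_spike_train(spec, trials, rng)
        p = select_ms_bootstrap(spikes, trials, SelectionConfig(n_boot=100, seed=0))
        assert p >= 1 / 101


class TestPopulation:
    def test_thresholding(self):
        results = [
            UnitSelectionResult(0, p_vs=0.01, p_ms=0.2, label="VS"),
            UnitSelectionResult(1, p_vs=0.01, p_ms=0.01, label="dual"),
            UnitSelectionResult(2, p_vs=1.0, p_ms=1.0, label="none"),
        ]
        pop = classify_units_population(results)
        # the dual unit is counted in n_vs, n_ms, and n_dual
        assert (pop.n_vs, pop.n_ms, pop.n_dual) == (2, 1, 1)
        assert pop.n_dual <= min(pop.n_vs, pop.n_ms)
        assert pop.prop_vs == pytest.approx(2 / 3)

    def test_all_null_gives_zero_proportions(self):
        results = [
            UnitSelectionResult(i, p_vs=1.0, p_ms=1.0, label="none") for i in range(5)
        ]
        pop = classify_units_population(results)
        assert pop.n_vs == pop.n_ms == pop.n_dual == 0


class TestQcMetrics:
    def test_hand_counted_isi_fraction(self):
        frac, ok = isi_violation_fraction(np.array([0.0, 0.001, 0.010, 0.020]))
        assert frac == pytest.approx(1 / 3)
        assert not ok

    def test_clean_train_passes(self):
        frac, ok = isi_violation_fraction(np.arange(1000) * 0.010)
        assert frac == 0.0 and ok

    def test_exactly_three_percent_fails_strict(self):
        # 1000 spikes -> 999 ISIs; build a train whose violation fraction can
        # bracket 3% exactly on 1000 ISIs
        isis = np.full(1000, 0.010)
        isis[:30] = 0.001  # 30/1000 = exactly 3%
        st = np.concatenate([[0.0], np.cumsum(isis)])
        frac, ok = isi_violation_fraction(st)
        assert frac == pytest.approx(0.03)
        assert not ok  # "<3%" is strict

    def test_fewer_than_two_spikes_passes_vacuously(self):
        assert isi_violation_fraction(np.array([1.0])) == (0.0, True)

    def test_qc_monotone_under_added_violation(self, rng):
        st = np.sort(rng.uniform(0, 100, 300))
        frac0, ok0 = isi_violation_fraction(st)
        worse = np.sort(np.append(st, st[10] + 0.001))
        frac1, ok1 = isi_violation_fraction(worse)
        assert frac1 >= frac0
        assert not (not ok0 and ok1)

    def test_snr_definition_and_homogeneity(self):
        w = np.zeros(256)
        w[100] = 100.0
        assert compute_snr(w, 5.0) == pytest.approx(20.0)
        assert compute_snr(3 * w, 5.0) == pytest.approx(60.0)
        assert compute_snr(np.zeros(256), 5.0) == 0.0
        with pytest.raises(ValueError):
            compute_snr(w, 0.0)


class TestIsolationDistance:
    def test_monotone_in_separation(self, rng):
        cluster = rng.normal(0, 1, (100, 3))
        vals = []
        for sep in (2.0, 5.0, 10.0):
            other = rng.normal(0, 1, (300, 3)) + sep
            vals.append(isolation_distance(cluster, other))
        assert vals[0] < vals[1] < vals[2]

    def test_same_distribution_matches_chi_square_rank(self, rng):
        # outside spikes drawn from the cluster's own Gaussian: the n-th
        # closest squared Mahalanobis distance sits near the chi-square
        # quantile of rank n/m
        n, m, d = 500, 2000, 3
        cluster = rng.normal(0, 1, (n, d))
        other = rng.normal(0, 1, (m, d))
        val = isolation_distance(cluster, other)
        expected = stats.chi2.ppf(n / m, df=d)
        assert val == pytest.approx(expected, rel=0.2)

    def test_singular_covariance_undefined(self, rng):
        cluster = np.column_stack([rng.normal(0, 1, 50), np.ones(50)])
        other = rng.normal(0, 1, (100, 2))
        assert isolation_distance(cluster, other) is None

    def test_too_few_outside_points_undefined(self, rng):
        cluster = rng.normal(0, 1, (50, 3))
        other = rng.normal(0, 1, (10, 3))
        assert isolation_distance(cluster, other) is None


def test_plot_raster_psth_smoke(tmp_path, rng):
    import matplotlib

    matplotlib.use("Agg")
    from newold.neuron_analysis import plot_raster_psth

    trials = _trials(10)
    spikes = simulate_spike_train(NeuronSpec(baseline_hz=8.0), trials, rng)
    fig = plot_raster_psth(spikes, trials)
    fig.savefig(tmp_path / "raster.png")
    assert (tmp_path / "raster.png").stat().st_size > 0
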