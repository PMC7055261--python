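"""Generator: behavior model, timeline rendering, spike trains, waveforms."""

import numpy as np
import pytest
from scipy.stats import norm

from newold.behavior_analysis import mann_whitney_auc
from newold.core_model import LEARNING, RECOGNITION, TrialRecord
from newold.synthetic_session import (
    BehaviorParams,
    GeneratorConfig,
    NeuronSpec,
    TaskTimingConfig,
    build_trial_timeline,
    generate_session,
    load_generator_configs,
    schedule_trials,
    simulate_recognition_behavior,
    simulate_spike_train,
    synth_waveform,
)


def _labels(n_old=50, n_new=50):
    return np.array([0] * n_old + [1] * n_new)


class TestRecognitionBehavior:
    def test_no_signal_gives_chance_auc(self, rng):
        labels = _labels(10_000, 10_000)
        codes, _ = simulate_recognition_behavior(
            labels, BehaviorParams(d_prime=0.0), rng
        )
        auc = mann_whitney_auc(labels, codes)
        assert abs(auc - 0.5) < 0.02

    def test_infinite_separation_saturates_scale(self, rng):
        labels = _labels()
        codes, _ = simulate_recognition_behavior(
            labels, BehaviorParams(d_prime=50.0), rng
        )
        assert np.all(codes[labels == 0] == 36)

    def test_auc_matches_equal_variance_closed_form(self, rng):
        # equal-variance signal detection: continuous-strength AUC is
        # Phi(d'/sqrt(2)); the 6-level response ROC has a closed-form
        # trapezoid AUC slightly below it (discretization loss)
        d = 1.5
        params = BehaviorParams(d_prime=d)
        labels = _labels(10_000, 10_000)
        codes, _ = simulate_recognition_behavior(labels, params, rng)
        c = np.asarray(params.criteria)
        fa = np.concatenate([[0], (1 - norm.cdf(c))[::-1], [1]])
        hit = np.concatenate([[0], (1 - norm.cdf(c - d))[::-1], [1]])
        discrete_expected = np.trapezoid(hit, fa)
        assert discrete_expected == pytest.approx(norm.cdf(d / np.sqrt(2)), abs=0.01)
        assert mann_whitney_auc(labels, codes) == pytest.approx(
            discrete_expected, abs=0.008
        )

    def test_nonincreasing_criteria_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(criteria=(0.0, 0.5, 0.5, 1.0, 1.5))

    def test_rts_positive_and_bounded(self, rng):
        _, rts = simulate_recognition_behavior(_labels(), BehaviorParams(), rng)
        assert np.all(rts > 0)


def _draft(phase, code):
    return TrialRecord(
        phase=phase,
        start_time=0, stop_time=0, delay1_time=0, response_time=0, delay2_time=0,
        response_value=code, category_name="houses", stim_category=0,
        stimulus_id="s", new_old_label=0 if phase == RECOGNITION else None,
    )


class TestTimeline:
    def test_learning_only_toy_stream(self):
        timing = TaskTimingConfig()
        trials = schedule_trials(
            [_draft(LEARNING, 21), _draft(LEARNING, 20)], [1.0, 1.0], timing
        )
        events, tags = build_trial_timeline(trials, 1, timing)
        assert [e.code for e in events] == [55, 1, 2, 3, 21, 6, 1, 2, 3, 20, 6, 66]
        assert all(t.xid == 80 for t in tags)

    @pytest.mark.parametrize("variant,learn_id,recog_id", [(1, 80, 81), (2, 83, 84), (3, 88, 89)])
    def test_variant_sets_block_ids(self, variant, learn_id, recog_id):
        timing = TaskTimingConfig()
        trials = schedule_trials(
            [_draft(LEARNING, 20), _draft(RECOGNITION, 35)], [1.0, 1.0], timing
        )
        events, tags = build_trial_timeline(trials, variant, timing)
        xids = [t.xid for t in tags]
        assert xids[1] == learn_id and xids[6] == recog_id

    def test_empty_trial_list(self):
        events, tags = build_trial_timeline([], 1, TaskTimingConfig())
        assert [e.code for e in events] == [55, 66]
        assert len(tags) == 2

    def test_illegal_response_code_for_phase(self):
        timing = TaskTimingConfig()
        trials = schedule_trials([_draft(LEARNING, 35)], [1.0], timing)
        with pytest.raises(ValueError):
            build_trial_timeline(trials, 1, timing)

    def test_event_times_strictly_increasing(self, default_session):
        times = [e.time_s for e in default_session.events]
        assert np.all(np.diff(times) > 0)


def _window_trials(n, start_gap=3.0):
    return [
        TrialRecord(
            phase=RECOGNITION, start_time=i * start_gap,
            stop_time=i * start_gap + 1.0, delay1_time=i * start_gap + 1.5,
            response_time=i * start_gap + 2.0, delay2_time=i * start_gap + 2.5,
            response_value=35, category_name="houses", stim_category=0,
            stimulus_id=f"s{i}", new_old_label=i % 2,
        )
        for i in range(n)
    ]


class TestSpikeTrain:
    def test_untuned_rate_matches_baseline(self, rng):
        trials = _window_trials(100)
        spikes = simulate_spike_train(NeuronSpec(baseline_hz=5.0), trials, rng)
        counts = [
            np.sum((spikes >= t.start_time) & (spikes < t.start_time + 1.0))
            for t in trials
        ]
        se = np.sqrt(5.0 / len(trials))
        assert abs(np.mean(counts) - 5.0) < 3 * se

    def test_fano_factor_near_poisson(self, rng):
        trials = _window_trials(300)
        spikes = simulate_spike_train(NeuronSpec(baseline_hz=5.0), trials, rng)
        counts = np.array(
            [
                np.sum((spikes >= t.start_time) & (spikes < t.start_time + 1.0))
                for t in trials
            ]
        )
        fano = counts.var(ddof=1) / counts.mean()
        assert 0.7 < fano < 1.3  # refractory deletion biases slightly low

    def test_unit_gain_is_noop(self):
        trials = _window_trials(20)
        a = simulate_spike_train(
            NeuronSpec(kind="VS", category_gain=1.0, pref_category="houses"),
            trials, np.random.default_rng(7),
        )
        b = simulate_spike_train(NeuronSpec(), trials, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_near_zero_baseline_gives_empty_train(self, rng):
        trials = _window_trials(10)
        spikes = simulate_spike_train(NeuronSpec(baseline_hz=1e-9), trials, rng)
        assert len(spikes) == 0

    def test_gain_elevates_rate_in_window_only(self, rng):
        trials = _window_trials(200)
        spec = NeuronSpec(kind="VS", baseline_hz=5.0, category_gain=3.0,
                          pref_category="houses")
        spikes = simulate_spike_train(spec, trials, rng)
        in_win = sum(
            np.sum((spikes >= t.start_time + 0.2) & (spikes < t.start_time + 1.2))
            for t in trials
        ) / len(trials)
        assert in_win > 10.0  # ~15 Hz expected vs 5 Hz baseline

    def test_refractory_period_enforced(self, rng):
        trials = _window_trials(100)
        spikes = simulate_spike_train(
            NeuronSpec(baseline_hz=50.0, refractory_s=0.003), trials, rng
        )
        assert np.min(np.diff(spikes)) >= 0.003


class TestWaveform:
    def test_noiseless_template_peak_equals_amplitude(self, rng):
        w = synth_waveform(100.0, 0.0, rng)
        assert len(w) == 256
        assert np.max(np.abs(w)) == pytest.approx(100.0)

    def test_snr_definition_recovered(self, rng):
        from newold.neuron_analysis import compute_snr

        w = synth_waveform(100.0, 5.0, rng)
        assert compute_snr(w, 5.0) == pytest.approx(20.0, rel=0.15)

    def test_same_seed_identical(self):
        a = synth_waveform(80.0, 5.0, np.random.default_rng(3))
        b = synth_waveform(80.0, 5.0, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestGenerateSession:
    def test_session_structure(self, default_session):
        s = default_session
        assert len(s.trials) == 200
        assert len(s.learning_trials()) == 100
        recog = s.recognition_trials()
        assert len(recog) == 100
        assert sum(t.new_old_label == 1 for t in recog) == 50
        assert sum(t.new_old_label == 0 for t in recog) == 50
        assert len({t.category_name for t in s.trials}) == 5
        assert len(s.events) == len(s.tags)

    def test_category_balance(self, default_session):
        recog = default_session.recognition_trials()
        for cat in {t.category_name for t in recog}:
            old = sum(
                t.category_name == cat and t.new_old_label == 0 for t in recog
            )
            new = sum(
                t.category_name == cat and t.new_old_label == 1 for t in recog
            )
            assert (old, new) == (10, 10)

    def test_old_images_repeat_encoding_images(self, default_session):
        enc_ids = {t.stimulus_id for t in default_session.learning_trials()}
        for t in default_session.recognition_trials():
            if t.new_old_label == 0:
                assert t.stimulus_id in enc_ids
            else:
                assert t.stimulus_id not in enc_ids

    def test_same_seed_fully_deterministic(self):
        a = generate_session(GeneratorConfig(seed=42))
        b = generate_session(GeneratorConfig(seed=42))
        assert a.trials == b.trials
        assert a.events == b.events
        for ua, ub in zip(a.units, b.units):
            assert np.array_equal(ua.spike_times, ub.spike_times)
            assert np.array_equal(ua.waveform_mean_encoding, ub.waveform_mean_encoding)
        assert all(
            np.array_equal(a.stimuli[k], b.stimuli[k]) for k in a.stimuli
        )

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(frac_vs=0.8, frac_ms=0.5)

    def test_config_file_loading(self, tmp_path):
        cfg_file = tmp_path / "sessions.ini"
        cfg_file.write_text(
            "[sessA]\nsession_id = T05_session_1\nvariant = 2\nseed = 9\n"
            "n_units = 4\nd_prime = 1.0\nsubject_id = T05\n"
        )
        (cfg,) = load_generator_configs(cfg_file)
        assert cfg.session_id == "T05_session_1"
        assert cfg.variant == 2 and cfg.n_units == 4
        assert cfg.behavior.d_prime == 1.0
        s = generate_session(cfg)
        assert s.subject.subject_id == "T05"
        assert {t.xid for t in s.tags} == {83, 84}
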