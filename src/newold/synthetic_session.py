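"""Synthetic new/old recognition-memory sessions.

Generates complete sessions — task timeline, behavior, spike trains,
waveforms, quality metrics — so that every downstream stage (serialization,
event parsing, behavioral ROC, unit screening) can be exercised end to end
without any recorded data.

The generative choices, in brief:

* Behavior follows equal-variance Gaussian signal detection: memory strength
  is N(d', 1) for old items and N(0, 1) for new items, and five strictly
  increasing criteria carve the strength axis into the six confidence
  responses (codes 31-36).  An optional old-item standard deviation != 1
  produces the asymmetric (zROC slope < 1) curves typical of declarative
  memory.
* Spike trains are piecewise-constant-rate Poisson processes: baseline rate
  everywhere, multiplied by a gain inside the response window of trials that
  match the unit's preference (visual category for VS units, new/old status
  for MS units).  Spikes violating an absolute refractory period are deleted.
* Waveforms are a fixed biphasic template (difference of two Gaussians,
  256 samples at 100 kHz) scaled to a target peak amplitude plus white noise.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_model import (
    CODE_MAPS,
    LEARNING,
    RECOGNITION,
    TTL_END_EXPERIMENT,
    TTL_END_TRIAL,
    TTL_QUESTION_ON,
    TTL_START_EXPERIMENT,
    TTL_STIM_OFF,
    TTL_STIM_ON,
    ElectrodeRecord,
    EventMarker,
    ExperimentTag,
    SessionBundle,
    SubjectMeta,
    TrialRecord,
    UnitRecord,
)

__all__ = [
    "CATEGORY_POOL",
    "TaskTimingConfig",
    "BehaviorParams",
    "NeuronSpec",
    "GeneratorConfig",
    "simulate_recognition_behavior",
    "build_trial_timeline",
    "simulate_spike_train",
    "synth_waveform",
    "generate_session",
    "load_generator_configs",
]

# Visual categories used across task variants; each session draws five.
CATEGORY_POOL = [
    "houses", "landscapes", "mobility", "phones", "animals", "fruits",
    "kids", "military", "space", "cars", "food", "people", "spatial",
]

MTL_AREAS = [
    ("Left Hippocampus", (-25.0, -20.0, -14.0)),
    ("Right Hippocampus", (26.0, -20.0, -14.0)),
    ("Left Amygdala", (-22.0, -4.0, -18.0)),
    ("Right Amygdala", (23.0, -4.0, -18.0)),
]

WAVEFORM_N_SAMPLES = 256
WAVEFORM_RATE_HZ = 100_000.0


@dataclass
class TaskTimingConfig:
    """Trial pacing.  The task itself does not pin these durations down, so
    they are explicit defaults: 1 s stimulus, 0.5 s delay to the question
    screen, 0.5 s from response to end-of-trial, 1 s inter-trial interval."""

    stim_duration_s: float = 1.0
    delay_stim_to_question_s: float = 0.5
    post_response_s: float = 0.5
    max_rt_s: float = 10.0
    iti_s: float = 1.0
    n_encoding: int = 100
    n_recognition: int = 100
    n_categories: int = 5
    category_names: Tuple[str, ...] = tuple(CATEGORY_POOL[:5])

    def __post_init__(self):
        for name in (
            "stim_duration_s",
            "delay_stim_to_question_s",
            "post_response_s",
            "iti_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.category_names) != self.n_categories:
            raise ValueError("category_names length must equal n_categories")


def _default_criteria(d_prime: float = 1.5) -> Tuple[float, ...]:
    # Symmetric about the midpoint between the new/old strength means, with
    # 0.6-SD spacing: closed-form analysis of the 6-point trapezoid ROC shows
    # this spacing minimizes the information lost by discretizing strength
    # onto the 6-level confidence scale (residual AUC bias ~0.009 at d'=1.5).
    mid = d_prime / 2.0
    return tuple(mid + o for o in (-1.2, -0.6, 0.0, 0.6, 1.2))


@dataclass
class BehaviorParams:
    """Signal-detection behavior model.

    ``d_prime`` separates old from new memory-strength distributions;
    ``criteria`` are five increasing cutpoints mapping strength to the six
    confidence responses; ``old_sd`` != 1 gives an unequal-variance model.
    ``p_animal_correct`` governs the encoding-phase animal judgment.
    Reaction times are lognormal (median ~1 s by default).
    """

    d_prime: float = 1.5
    criteria: Optional[Tuple[float, ...]] = None
    old_sd: float = 1.0
    p_animal_correct: float = 0.95
    rt_lognorm_mu: float = 0.0
    rt_lognorm_sigma: float = 0.35

    def __post_init__(self):
        if self.criteria is None:
            # symmetric about the midpoint between the two strength means
            self.criteria = _default_criteria(self.d_prime)
        crit = np.asarray(self.criteria, dtype=float)
        if len(crit) != 5 or not np.all(np.diff(crit) > 0):
            raise ValueError("criteria must be 5 strictly increasing cutpoints")
        if not 0.0 <= self.p_animal_correct <= 1.0:
            raise ValueError("p_animal_correct must be in [0, 1]")
        if self.old_sd <= 0:
            raise ValueError("old_sd must be > 0")


@dataclass
class NeuronSpec:
    """Tuning of one simulated unit.

    ``kind`` is none (untuned), VS (category-tuned), MS (new/old-tuned) or
    dual (both).  Gains are multiplicative on the baseline rate inside the
    response window [onset + latency, onset + latency + duration)."""

    kind: str = "none"
    baseline_hz: float = 5.0
    category_gain: float = 3.0
    pref_category: Optional[str] = None
    memory_gain: float = 3.0
    pref_condition: str = "new"
    latency_s: float = 0.2
    resp_duration_s: float = 1.0
    refractory_s: float = 0.003

    def __post_init__(self):
        if self.kind not in ("none", "VS", "MS", "dual"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if self.baseline_hz <= 0:
            raise ValueError("baseline_hz must be > 0")
        if self.kind in ("VS", "dual") and self.category_gain < 1:
            raise ValueError("category_gain must be >= 1 for VS/dual units")
        if self.kind in ("MS", "dual") and self.memory_gain < 1:
            raise ValueError("memory_gain must be >= 1 for MS/dual units")
        if self.pref_condition not in ("new", "old"):
            raise ValueError("pref_condition must be 'new' or 'old'")


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic session."""

    session_id: str = "C01_session_1"
    variant: int = 1
    seed: int = 0
    n_units: int = 20
    frac_vs: float = 0.2
    frac_ms: float = 0.1
    frac_dual: float = 0.0
    baseline_hz: float = 5.0
    category_gain: float = 3.0
    memory_gain: float = 3.0
    subject_id: str = "C01"
    subject_age: int = 40
    subject_sex: str = "F"
    image_size: int = 16
    timing: TaskTimingConfig = field(default_factory=TaskTimingConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self):
        if min(self.frac_vs, self.frac_ms, self.frac_dual) < 0:
            raise ValueError("unit-kind fractions must be >= 0")
        if self.frac_vs + self.frac_ms + self.frac_dual > 1.0 + 1e-12:
            raise ValueError("unit-kind fractions must sum to <= 1")
        if self.variant not in (1, 2, 3):
            raise ValueError("variant must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def simulate_recognition_behavior(
    labels: Sequence[int],
    params: BehaviorParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate confidence responses (codes 31..36) and RTs for one block.

    ``labels`` follow the trials-table convention: 0 = old, 1 = new.  Memory
    strength is drawn from N(d', old_sd) for old items and N(0, 1) for new
    items; the response is 31 plus the number of criteria the strength
    exceeds, so high strength maps to "old, confident" (36).
    """
    labels = np.asarray(labels, dtype=int)
    strength = np.where(
        labels == 0,
        rng.normal(params.d_prime, params.old_sd, size=len(labels)),
        rng.normal(0.0, 1.0, size=len(labels)),
    )
    crit = np.asarray(params.criteria, dtype=float)
    codes = 31 + np.searchsorted(crit, strength)
    rts = rng.lognormal(params.rt_lognorm_mu, params.rt_lognorm_sigma, len(labels))
    return codes.astype(int), np.minimum(rts, 10.0)


def _simulate_learning_behavior(
    categories: Sequence[str],
    params: BehaviorParams,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Animal/no-animal responses (20/21) for the encoding block."""
    truth_yes = np.array([c == "animals" for c in categories])
    correct = rng.random(len(truth_yes)) < params.p_animal_correct
    answer_yes = truth_yes == correct
    codes = np.where(answer_yes, 20, 21)
    rts = rng.lognormal(params.rt_lognorm_mu, params.rt_lognorm_sigma, len(codes))
    return codes.astype(int), np.minimum(rts, 10.0)


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------


def schedule_trials(
    drafts: List[TrialRecord],
    rts: Sequence[float],
    timing: TaskTimingConfig,
    t0: float = 1.0,
) -> List[TrialRecord]:
    """Assign onset/offset/question/response/end times sequentially from t0."""
    t = t0
    out = []
    for d, rt in zip(drafts, rts):
        start = t
        stop = start + timing.stim_duration_s
        delay1 = stop + timing.delay_stim_to_question_s
        response = delay1 + min(float(rt), timing.max_rt_s)
        delay2 = response + timing.post_response_s
        out.append(
            replace(
                d,
                start_time=start,
                stop_time=stop,
                delay1_time=delay1,
                response_time=response,
                delay2_time=delay2,
            )
        )
        t = delay2 + timing.iti_s
    return out


def build_trial_timeline(
    trials: List[TrialRecord],
    variant: int,
    timing: TaskTimingConfig,
) -> Tuple[List[EventMarker], List[ExperimentTag]]:
    """Render trials into the TTL event stream and paired experiment-id tags.

    The stream is ``55`` then, per trial, ``1, 2, 3, response, 6`` at the
    trial's own times, then ``66``.  Tags carry the variant's learning id for
    learning-block entries and the recognition id for recognition entries and
    always match the event stream in length and order.
    """
    learn_id, recog_id = CODE_MAPS.pair_for_variant(variant)
    seen_recognition = False
    events: List[EventMarker] = [EventMarker(0.0, TTL_START_EXPERIMENT)]
    xids: List[int] = [learn_id if trials and trials[0].phase == LEARNING else recog_id]
    if not trials:
        xids = [learn_id]
    for t in trials:
        if t.phase == LEARNING and seen_recognition:
            raise ValueError("learning trial after recognition block began")
        if t.phase == RECOGNITION:
            seen_recognition = True
        if t.response_value not in CODE_MAPS.response_codes(t.phase):
            raise ValueError(
                f"response code {t.response_value} illegal for phase {t.phase}"
            )
        xid = learn_id if t.phase == LEARNING else recog_id
        for time_s, code in (
            (t.start_time, TTL_STIM_ON),
            (t.stop_time, TTL_STIM_OFF),
            (t.delay1_time, TTL_QUESTION_ON),
            (t.response_time, t.response_value),
            (t.delay2_time, TTL_END_TRIAL),
        ):
            events.append(EventMarker(time_s, code))
            xids.append(xid)
    t_end = (trials[-1].delay2_time + timing.iti_s) if trials else timing.iti_s
    events.append(EventMarker(t_end, TTL_END_EXPERIMENT))
    xids.append(xids[-1])
    tags = [ExperimentTag(e.time_s, x) for e, x in zip(events, xids)]
    return events, tags


# ---------------------------------------------------------------------------
# Spike trains and waveforms
# ---------------------------------------------------------------------------


def _response_windows(spec: NeuronSpec, trials: List[TrialRecord]) -> list:
    """(t_lo, t_hi, gain) windows in which the unit's rate is elevated."""
    wins = []
    for t in trials:
        gain = 1.0
        if spec.kind in ("VS", "dual") and t.category_name == spec.pref_category:
            gain *= spec.category_gain
        if (
            spec.kind in ("MS", "dual")
            and t.phase == RECOGNITION
            and t.new_old_label == (1 if spec.pref_condition == "new" else 0)
        ):
            gain *= spec.memory_gain
        if gain > 1.0:
            lo = t.start_time + spec.latency_s
            wins.append((lo, lo + spec.resp_duration_s, gain))
    return wins


def simulate_spike_train(
    spec: NeuronSpec,
    trials: List[TrialRecord],
    rng: np.random.Generator,
    t_end: Optional[float] = None,
) -> np.ndarray:
    """Sample a sorted spike train for one unit over the whole session.

    Piecewise-constant-rate Poisson process by thinning: candidates are drawn
    homogeneously at the maximum rate and kept with probability
    rate(t)/rate_max.  Spikes closer than the refractory period to the
    previously kept spike are then deleted.
    """
    if t_end is None:
        t_end = (trials[-1].delay2_time + 1.0) if trials else 1.0
    wins = _response_windows(spec, trials)
    max_gain = max([g for _, _, g in wins], default=1.0)
    rate_max = spec.baseline_hz * max_gain
    if rate_max <= 0 or t_end <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n))
    gains = np.ones(n)
    for lo, hi, g in wins:
        i0, i1 = np.searchsorted(cand, [lo, hi])
        gains[i0:i1] *= g
    keep = rng.random(n) < (spec.baseline_hz * gains) / rate_max
    spikes = cand[keep]
    if spec.refractory_s > 0 and len(spikes) > 1:
        kept = [spikes[0]]
        for t in spikes[1:]:
            if t - kept[-1] >= spec.refractory_s:
                kept.append(t)
        spikes = np.asarray(kept)
    return spikes


def _waveform_template(n_samples: int = WAVEFORM_N_SAMPLES) -> np.ndarray:
    """Unit-peak biphasic template: difference of two Gaussians."""
    t = np.arange(n_samples, dtype=float)
    pos = np.exp(-0.5 * ((t - 0.38 * n_samples) / (0.035 * n_samples)) ** 2)
    neg = np.exp(-0.5 * ((t - 0.55 * n_samples) / (0.08 * n_samples)) ** 2)
    w = pos - 0.45 * neg
    return w / np.max(np.abs(w))


def synth_waveform(
    amplitude_uv: float,
    noise_sd_uv: float,
    rng: np.random.Generator,
    n_samples: int = WAVEFORM_N_SAMPLES,
) -> np.ndarray:
    """Biphasic mean waveform (microvolts) with peak ``amplitude_uv`` plus
    white noise of sd ``noise_sd_uv``; 256 samples at 100 kHz by default."""
    if amplitude_uv <= 0:
        raise ValueError("amplitude_uv must be > 0")
    w = amplitude_uv * _waveform_template(n_samples)
    if noise_sd_uv > 0:
        w = w + rng.normal(0.0, noise_sd_uv, size=n_samples)
    return w


# ---------------------------------------------------------------------------
# Full session
# ---------------------------------------------------------------------------


def _category_image(cat_index: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Small placeholder image with a category-specific mean intensity."""
    base = 30 + 40 * cat_index
    img = base + rng.integers(0, 30, size=(size, size))
    return img.astype(np.uint8)


def _unit_kinds(cfg: GeneratorConfig) -> List[str]:
    n = cfg.n_units
    n_vs = int(round(cfg.frac_vs * n))
    n_ms = int(round(cfg.frac_ms * n))
    n_dual = int(round(cfg.frac_dual * n))
    kinds = ["VS"] * n_vs + ["MS"] * n_ms + ["dual"] * n_dual
    kinds += ["none"] * (n - len(kinds))
    return kinds[:n]


def _make_electrodes(rng: np.random.Generator) -> List[ElectrodeRecord]:
    """Four MTL bundles of eight microwires each, with jittered MNI coords."""
    out = []
    eid = 0
    for area, (x, y, z) in MTL_AREAS:
        gname = "microwires-" + area.replace(" ", "-")
        for ch in range(8):
            out.append(
                ElectrodeRecord(
                    id=eid,
                    location=area,
                    x=float(x + rng.normal(0, 0.5)),
                    y=float(y + rng.normal(0, 0.5)),
                    z=float(z + rng.normal(0, 0.5)),
                    filtering="300-3000Hz",
                    orig_channel=eid + 1,
                    group_name=gname,
                    device_name="Neuralynx-Atlas",
                )
            )
            eid += 1
    return out


def generate_session(cfg: GeneratorConfig) -> SessionBundle:
    """Generate one complete, internally consistent session.

    The encoding block shows 100 images, 20 per category; the recognition
    block shows 50 of them again ("old", label 0) plus 50 new images
    (label 1), 10 old + 10 new per category, in shuffled order.  Everything
    downstream — responses, event streams, units, electrodes, stimuli — is
    derived deterministically from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    timing = cfg.timing
    cats = list(timing.category_names)
    n_per_cat = timing.n_encoding // len(cats)

    # --- stimuli -----------------------------------------------------------
    enc_cats = [c for c in cats for _ in range(n_per_cat)]
    order = rng.permutation(timing.n_encoding)
    enc_cats = [enc_cats[i] for i in order]
    enc_ids = [f"learn_{i + 1:03d}" for i in range(timing.n_encoding)]
    stimuli: Dict[str, np.ndarray] = {
        sid: _category_image(cats.index(c), cfg.image_size, rng)
        for sid, c in zip(enc_ids, enc_cats)
    }

    # old subset: 10 per category from encoding, after a seeded shuffle
    n_old_per_cat = timing.n_recognition // (2 * len(cats))
    old_ids: List[str] = []
    for c in cats:
        pool = [sid for sid, cc in zip(enc_ids, enc_cats) if cc == c]
        pick = rng.permutation(len(pool))[:n_old_per_cat]
        old_ids.extend(pool[i] for i in pick)
    new_ids, new_cats = [], []
    for c in cats:
        for k in range(n_old_per_cat):
            sid = f"recog_new_{c}_{k + 1:02d}"
            new_ids.append(sid)
            new_cats.append(c)
            stimuli[sid] = _category_image(cats.index(c), cfg.image_size, rng)

    recog_ids = old_ids + new_ids
    recog_cats = [enc_cats[enc_ids.index(s)] for s in old_ids] + new_cats
    recog_labels = [0] * len(old_ids) + [1] * len(new_ids)
    perm = rng.permutation(len(recog_ids))
    recog_ids = [recog_ids[i] for i in perm]
    recog_cats = [recog_cats[i] for i in perm]
    recog_labels = [recog_labels[i] for i in perm]

    # --- behavior ----------------------------------------------------------
    learn_codes, learn_rts = _simulate_learning_behavior(enc_cats, cfg.behavior, rng)
    recog_codes, recog_rts = simulate_recognition_behavior(
        recog_labels, cfg.behavior, rng
    )

    def draft(phase, code, cat, sid, label):
        return TrialRecord(
            phase=phase,
            start_time=0.0,
            stop_time=0.0,
            delay1_time=0.0,
            response_time=0.0,
            delay2_time=0.0,
            response_value=int(code),
            category_name=cat,
            stim_category=cats.index(cat),
            stimulus_id=sid,
            new_old_label=label,
        )

    drafts = [
        draft(LEARNING, c, cat, sid, None)
        for c, cat, sid in zip(learn_codes, enc_cats, enc_ids)
    ] + [
        draft(RECOGNITION, c, cat, sid, lab)
        for c, cat, sid, lab in zip(recog_codes, recog_cats, recog_ids, recog_labels)
    ]
    rts = np.concatenate([learn_rts, recog_rts])
    trials = schedule_trials(drafts, rts, timing)
    events, tags = build_trial_timeline(trials, cfg.variant, timing)
    t_end = events[-1].time_s

    # --- units -------------------------------------------------------------
    electrodes = _make_electrodes(rng)
    units: List[UnitRecord] = []
    for i, kind in enumerate(_unit_kinds(cfg)):
        spec = NeuronSpec(
            kind=kind,
            baseline_hz=cfg.baseline_hz,
            category_gain=cfg.category_gain,
            pref_category=cats[int(rng.integers(len(cats)))],
            memory_gain=cfg.memory_gain,
            pref_condition="new" if rng.random() < 0.5 else "old",
        )
        spikes = simulate_spike_train(spec, trials, rng, t_end=t_end)
        amp = float(rng.uniform(60.0, 150.0))
        noise_sd = float(rng.uniform(4.0, 9.0))
        wf_enc = synth_waveform(amp, noise_sd, rng)
        wf_rec = synth_waveform(amp, noise_sd, rng)
        snr = float(np.max(np.abs(wf_enc)) / noise_sd)
        # feature-space separation for an isolation-distance style metric
        sep = float(rng.uniform(4.0, 10.0))
        from .neuron_analysis import isolation_distance

        cluster = rng.normal(0.0, 1.0, size=(80, 3))
        others = rng.normal(0.0, 1.0, size=(200, 3)) + sep / np.sqrt(3)
        isol = isolation_distance(cluster, others)
        units.append(
            UnitRecord(
                unit_id=i,
                electrode_index=int(rng.integers(len(electrodes))),
                spike_times=spikes,
                waveform_mean_encoding=wf_enc,
                waveform_mean_recognition=wf_rec,
                snr=snr,
                isol_dist=float(isol) if isol is not None else np.nan,
                orig_cluster_id=1000 + i,
            )
        )

    subject = SubjectMeta(
        subject_id=cfg.subject_id,
        age=cfg.subject_age,
        sex=cfg.subject_sex,
        description="synthetic subject",
    )
    return SessionBundle(
        session_id=cfg.session_id,
        variant=cfg.variant,
        subject=subject,
        electrodes=electrodes,
        units=units,
        events=events,
        tags=tags,
        trials=trials,
        stimuli=stimuli,
    )


# ---------------------------------------------------------------------------
# Declarative session configuration files
# ---------------------------------------------------------------------------


def load_generator_configs(path) -> List[GeneratorConfig]:
    """Read an INI-style session registry into GeneratorConfig objects.

    Each ``[section]`` describes one session; keys mirror GeneratorConfig
    fields (session_id, variant, seed, n_units, frac_vs, frac_ms, frac_dual,
    baseline_hz, category_gain, memory_gain, d_prime, subject_id, ...).
    """
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    out = []
    for section in parser.sections():
        sec = parser[section]
        behavior = BehaviorParams(
            d_prime=sec.getfloat("d_prime", 1.5),
            old_sd=sec.getfloat("old_sd", 1.0),
            p_animal_correct=sec.getfloat("p_animal_correct", 0.95),
        )
        cfg = GeneratorConfig(
            session_id=sec.get("session_id", section),
            variant=sec.getint("variant", 1),
            seed=sec.getint("seed", 0),
            n_units=sec.getint("n_units", 20),
            frac_vs=sec.getfloat("frac_vs", 0.2),
            frac_ms=sec.getfloat("frac_ms", 0.1),
            frac_dual=sec.getfloat("frac_dual", 0.0),
            baseline_hz=sec.getfloat("baseline_hz", 5.0),
            category_gain=sec.getfloat("category_gain", 3.0),
            memory_gain=sec.getfloat("memory_gain", 3.0),
            subject_id=sec.get("subject_id", "C01"),
            subject_age=sec.getint("subject_age", 40),
            subject_sex=sec.get("subject_sex", "F"),
            behavior=behavior,
        )
        out.append(cfg)
    return out
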