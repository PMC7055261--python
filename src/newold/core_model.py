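"""In-memory data model for new/old recognition-memory sessions.

A session of the task has two blocks: an encoding ("learning") block in which
the subject views 100 novel images and answers "is this an animal?", and a
recognition block in which 50 of those images return interleaved with 50 new
ones and the subject answers "have you seen this image before?" on a 1-6
confidence scale.  Everything the downstream stages need — event-marker
streams, per-trial timing, sorted units with spike times and waveforms,
electrode metadata — lives in a :class:`SessionBundle`.

Times are seconds (float) relative to the start of the experiment throughout;
calendar time belongs to the serialization layer only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "CODE_MAPS",
    "CodeMaps",
    "EventMarker",
    "ExperimentTag",
    "TrialRecord",
    "UnitRecord",
    "ElectrodeRecord",
    "SubjectMeta",
    "SessionBundle",
    "RaggedPair",
    "build_ragged",
    "slice_ragged",
    "validate_session",
]

LEARNING = "learning"
RECOGNITION = "recognition"

# TTL event-marker codes used by the task
TTL_START_EXPERIMENT = 55
TTL_STIM_ON = 1
TTL_STIM_OFF = 2
TTL_QUESTION_ON = 3
TTL_RESP_ANIMAL_YES = 20
TTL_RESP_ANIMAL_NO = 21
TTL_END_TRIAL = 6
TTL_END_EXPERIMENT = 66

LEARNING_RESPONSE_CODES = (20, 21)
RECOGNITION_RESPONSE_CODES = (31, 32, 33, 34, 35, 36)


@dataclass(frozen=True)
class CodeMaps:
    """Code tables for TTL event markers and block (experiment) IDs.

    ``ttl_codes`` maps each marker to its meaning; ``experiment_ids`` maps
    each block label to its phase.  A session uses exactly one of the
    ``variant_pairs`` (learning id, recognition id) so that repeated runs of
    the task by one subject can be told apart.
    """

    ttl_codes: Dict[int, str] = field(
        default_factory=lambda: {
            55: "start of experiment",
            1: "stimulus onset",
            2: "stimulus offset",
            3: "question screen onset",
            20: "response: yes, this is an animal",
            21: "response: no, this is not an animal",
            31: "response: new, confident",
            32: "response: new, probably",
            33: "response: new, guess",
            34: "response: old, guess",
            35: "response: old, probably",
            36: "response: old, confident",
            6: "end of trial",
            66: "end of experiment",
        }
    )
    experiment_ids: Dict[int, str] = field(
        default_factory=lambda: {
            80: LEARNING,
            83: LEARNING,
            88: LEARNING,
            81: RECOGNITION,
            84: RECOGNITION,
            89: RECOGNITION,
        }
    )
    variant_pairs: frozenset = frozenset({(80, 81), (83, 84), (88, 89)})

    def phase_of_xid(self, xid: int) -> str:
        try:
            return self.experiment_ids[xid]
        except KeyError:
            raise KeyError(f"unknown experiment id {xid}") from None

    def pair_for_variant(self, variant: int) -> tuple:
        pairs = {1: (80, 81), 2: (83, 84), 3: (88, 89)}
        if variant not in pairs:
            raise ValueError(f"task variant must be 1, 2 or 3, got {variant}")
        return pairs[variant]

    def response_codes(self, phase: str) -> tuple:
        return (
            LEARNING_RESPONSE_CODES
            if phase == LEARNING
            else RECOGNITION_RESPONSE_CODES
        )


CODE_MAPS = CodeMaps()


@dataclass(frozen=True)
class EventMarker:
    """One TTL pulse: a marker code at a time (seconds from experiment start)."""

    time_s: float
    code: int


@dataclass(frozen=True)
class ExperimentTag:
    """Block label paired 1:1 with an event marker (same stream length/order)."""

    time_s: float
    xid: int


@dataclass
class TrialRecord:
    """One trial of either phase.

    Timing fields follow the trials-table convention: ``start_time`` is
    stimulus onset, ``stop_time`` stimulus offset, ``delay1_time`` question
    screen onset, ``response_time`` the button press, ``delay2_time`` the end
    of the trial.  ``new_old_label`` is 0 (old) or 1 (new) and exists only for
    recognition trials.
    """

    phase: str
    start_time: float
    stop_time: float
    delay1_time: float
    response_time: float
    delay2_time: float
    response_value: int
    category_name: str
    stim_category: int
    stimulus_id: str
    new_old_label: Optional[int] = None

    def is_recognition(self) -> bool:
        return self.phase == RECOGNITION


@dataclass
class UnitRecord:
    """One sorted putative single neuron.

    ``spike_times`` are sorted seconds from experiment start.  The two mean
    waveforms (encoding / recognition phase) are microvolt vectors sampled at
    ``waveform_rate_hz`` (100 kHz).  ``snr`` and ``isol_dist`` are the spike
    sorting quality metrics stored in the units table; ``orig_cluster_id``
    links back to the sorter's cluster numbering.
    """

    unit_id: int
    electrode_index: int
    spike_times: np.ndarray
    waveform_mean_encoding: np.ndarray
    waveform_mean_recognition: np.ndarray
    snr: float
    isol_dist: float
    orig_cluster_id: int
    waveform_rate_hz: float = 100_000.0

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.waveform_mean_encoding = np.asarray(
            self.waveform_mean_encoding, dtype=float
        )
        self.waveform_mean_recognition = np.asarray(
            self.waveform_mean_recognition, dtype=float
        )


@dataclass
class ElectrodeRecord:
    """One microwire: brain-area label, MNI coordinates (mm), filter string."""

    id: int
    location: str
    x: float
    y: float
    z: float
    filtering: str
    orig_channel: int
    group_name: str
    device_name: str


@dataclass
class SubjectMeta:
    """Subject metadata; the id prefix encodes the recording site
    (H = Huntington Memorial, C = Cedars-Sinai, T = Toronto Western)."""

    subject_id: str
    age: int
    sex: str
    species: str = "Homo sapiens"
    description: str = ""


@dataclass
class SessionBundle:
    """Everything belonging to one recorded session."""

    session_id: str
    variant: int
    subject: SubjectMeta
    electrodes: List[ElectrodeRecord]
    units: List[UnitRecord]
    events: List[EventMarker]
    tags: List[ExperimentTag]
    trials: List[TrialRecord]
    stimuli: Dict[str, np.ndarray] = field(default_factory=dict)
    session_start_year: int = 2019
    session_start_month: int = 1

    def recognition_trials(self) -> List[TrialRecord]:
        return [t for t in self.trials if t.phase == RECOGNITION]

    def learning_trials(self) -> List[TrialRecord]:
        return [t for t in self.trials if t.phase == LEARNING]


# ---------------------------------------------------------------------------
# Ragged-array utilities (spike_times / spike_times_index semantics)
# ---------------------------------------------------------------------------


@dataclass
class RaggedPair:
    """Flat concatenated values plus a cumulative end-index vector.

    ``index[i]`` is the total element count through row ``i``, so row ``i``
    occupies ``data[index[i-1]:index[i]]`` (with ``index[-1] := 0``).  The
    same numbers support the 1-based inclusive slice
    ``data(index(i)+1 : index(i+1))`` used from MATLAB: the stored values are
    language-neutral end counts, only the slicing idiom differs.
    """

    data: np.ndarray
    index: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.index = np.asarray(self.index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.index)


def build_ragged(per_unit_lists: Sequence[Sequence[float]]) -> RaggedPair:
    """Concatenate per-unit vectors into a flat array + cumulative end index."""
    lengths = np.array([len(v) for v in per_unit_lists], dtype=np.int64)
    index = np.cumsum(lengths)
    if len(per_unit_lists):
        data = np.concatenate([np.asarray(v, dtype=float) for v in per_unit_lists])
    else:
        data = np.empty(0, dtype=float)
    return RaggedPair(data=data, index=index)


def slice_ragged(r: RaggedPair, unit_i: int) -> np.ndarray:
    """Extract unit ``unit_i``'s vector (0-based) from a ragged pair."""
    n = len(r.index)
    if not 0 <= unit_i < n:
        raise IndexError(f"unit index {unit_i} out of range for {n} units")
    lo = 0 if unit_i == 0 else int(r.index[unit_i - 1])
    hi = int(r.index[unit_i])
    return r.data[lo:hi]


# ---------------------------------------------------------------------------
# Session validation
# ---------------------------------------------------------------------------


def _check_trial(t: TrialRecord, i: int, cm: CodeMaps) -> List[str]:
    out = []
    if not (
        t.start_time < t.stop_time <= t.delay1_time <= t.response_time <= t.delay2_time
    ):
        out.append(
            f"trial {i}: time ordering violated "
            f"(start<stop<=delay1<=response<=delay2 required)"
        )
    if t.phase not in (LEARNING, RECOGNITION):
        out.append(f"trial {i}: unknown phase {t.phase!r}")
        return out
    if t.response_value not in cm.response_codes(t.phase):
        out.append(
            f"trial {i}: response code {t.response_value} illegal for {t.phase}"
        )
    if t.phase == RECOGNITION:
        if t.new_old_label not in (0, 1):
            out.append(f"trial {i}: recognition trial lacks a 0/1 new/old label")
    elif t.new_old_label is not None:
        out.append(f"trial {i}: learning trial carries a new/old label")
    return out


def _check_event_grammar(events: List[EventMarker], cm: CodeMaps) -> List[str]:
    out = []
    codes = [e.code for e in events]
    for i, e in enumerate(events):
        if e.code not in cm.ttl_codes:
            out.append(f"event {i}: unknown TTL code {e.code}")
        if e.time_s < 0:
            out.append(f"event {i}: negative timestamp {e.time_s}")
    if not codes:
        out.append("event stream empty")
        return out
    if codes[0] != TTL_START_EXPERIMENT:
        out.append(f"event stream does not start with {TTL_START_EXPERIMENT}")
    if codes[-1] != TTL_END_EXPERIMENT:
        out.append(f"event stream does not end with {TTL_END_EXPERIMENT}")
    # per-trial grammar: 1, 2, 3, response, 6 repeated between the terminals
    body = [c for c in codes if c not in (TTL_START_EXPERIMENT, TTL_END_EXPERIMENT)]
    resp = set(LEARNING_RESPONSE_CODES) | set(RECOGNITION_RESPONSE_CODES)
    k = 0
    trial_no = 0
    while k < len(body):
        chunk = body[k : k + 5]
        ok = (
            len(chunk) == 5
            and chunk[0] == TTL_STIM_ON
            and chunk[1] == TTL_STIM_OFF
            and chunk[2] == TTL_QUESTION_ON
            and chunk[3] in resp
            and chunk[4] == TTL_END_TRIAL
        )
        if not ok:
            out.append(f"trial {trial_no}: event sequence violates 1,2,3,response,6")
            break
        k += 5
        trial_no += 1
    return out


def validate_session(s: SessionBundle, cm: CodeMaps = CODE_MAPS) -> List[str]:
    """Check every invariant of the bundle; return violations (empty = valid).

    Violations are returned rather than raised so that a reader can report
    all problems of a defective file at once.
    """
    out: List[str] = []

    if s.variant not in (1, 2, 3):
        out.append(f"variant {s.variant} not in 1..3")
    if not s.subject.subject_id or s.subject.subject_id[0] not in "HCT":
        out.append(
            f"subject id {s.subject.subject_id!r} lacks a site prefix (H/C/T)"
        )

    elec_ids = [e.id for e in s.electrodes]
    if len(set(elec_ids)) != len(elec_ids):
        out.append("electrode ids not unique")
    for u in s.units:
        if not 0 <= u.electrode_index < len(s.electrodes):
            out.append(f"unit {u.unit_id}: electrode index {u.electrode_index} invalid")
        st = u.spike_times
        if len(st) > 1 and not np.all(np.diff(st) > 0):
            out.append(f"unit {u.unit_id}: spike times not strictly increasing")
        if len(u.waveform_mean_encoding) != len(u.waveform_mean_recognition):
            out.append(f"unit {u.unit_id}: waveform vectors differ in length")
        if u.snr < 0:
            out.append(f"unit {u.unit_id}: negative SNR")

    if len(s.events) != len(s.tags):
        out.append(
            f"events ({len(s.events)}) and experiment_ids ({len(s.tags)}) "
            "streams differ in length"
        )
    for i, tag in enumerate(s.tags):
        if tag.xid not in cm.experiment_ids:
            out.append(f"tag {i}: unknown experiment id {tag.xid}")

    if s.variant in (1, 2, 3) and s.tags:
        want = set(cm.pair_for_variant(s.variant))
        got = {t.xid for t in s.tags}
        if not got <= want:
            out.append(f"experiment ids {sorted(got - want)} do not match variant")

    for i, t in enumerate(s.trials):
        out.extend(_check_trial(t, i, cm))

    out.extend(_check_event_grammar(s.events, cm))

    n_recog = len(s.recognition_trials())
    recog_stim = [t.stimulus_id for t in s.trials if t.phase == RECOGNITION]
    if len(set(recog_stim)) != n_recog:
        out.append("recognition stimulus ids not unique across recognition trials")

    return out
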