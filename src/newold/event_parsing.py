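"""Reconstruct the trials table from raw TTL events + experiment-id tags.

This is the alignment stage of the pipeline: the acquisition system stores
only two parallel streams (event markers and block labels), and every
per-trial quantity — stimulus onset/offset, question onset, response code and
time, end of trial — must be recovered from the marker grammar
``1, 2, 3, response, 6`` repeated within each block.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

from .core_model import (
    CODE_MAPS,
    LEARNING,
    LEARNING_RESPONSE_CODES,
    RECOGNITION,
    RECOGNITION_RESPONSE_CODES,
    TTL_END_EXPERIMENT,
    TTL_END_TRIAL,
    TTL_QUESTION_ON,
    TTL_START_EXPERIMENT,
    TTL_STIM_OFF,
    TTL_STIM_ON,
    CodeMaps,
    EventMarker,
    ExperimentTag,
    TrialRecord,
)

__all__ = [
    "split_blocks",
    "decode_response",
    "parse_block_to_trials",
    "parse_timeline",
    "ParseError",
]


class ParseError(ValueError):
    """Raised when the event stream violates the task grammar."""


def split_blocks(
    events: Sequence[EventMarker],
    tags: Sequence[ExperimentTag],
    cm: CodeMaps = CODE_MAPS,
) -> Tuple[List[EventMarker], List[EventMarker]]:
    """Partition events into (learning, recognition) by their block label.

    The tag stream must use exactly one legal (learning, recognition)
    variant pair; mixed pairs indicate a corrupted session.
    """
    if len(events) != len(tags):
        raise ParseError(
            f"events ({len(events)}) and tags ({len(tags)}) differ in length"
        )
    unknown = sorted({t.xid for t in tags} - set(cm.experiment_ids))
    if unknown:
        raise ParseError(f"unknown experiment ids in tag stream: {unknown}")
    xids = {t.xid for t in tags}
    learn_ids = {x for x in xids if cm.experiment_ids[x] == LEARNING}
    recog_ids = {x for x in xids if cm.experiment_ids[x] == RECOGNITION}
    if len(learn_ids) > 1 or len(recog_ids) > 1:
        raise ParseError(f"multiple block ids within one phase: {sorted(xids)}")
    if learn_ids and recog_ids:
        pair = (next(iter(learn_ids)), next(iter(recog_ids)))
        if pair not in cm.variant_pairs:
            raise ParseError(
                f"experiment ids {sorted(xids)} are not a legal variant pair"
            )
    learning = [e for e, t in zip(events, tags) if cm.experiment_ids[t.xid] == LEARNING]
    recognition = [
        e for e, t in zip(events, tags) if cm.experiment_ids[t.xid] == RECOGNITION
    ]
    return learning, recognition


def decode_response(code: int, phase: str) -> Tuple[str, Optional[str]]:
    """Translate a response TTL to its meaning.

    Learning: 20 -> ("yes-animal", None), 21 -> ("no-animal", None).
    Recognition: 31..36 -> (judgment, confidence) where the judgment is
    "old" iff code >= 34 and confidence runs guess/probably/confident
    outward from the middle of the scale.
    """
    if phase == LEARNING:
        if code == 20:
            return "yes-animal", None
        if code == 21:
            return "no-animal", None
        raise ValueError(f"code {code} is not a learning response")
    if phase == RECOGNITION:
        if code not in RECOGNITION_RESPONSE_CODES:
            raise ValueError(f"code {code} is not a recognition response")
        judgment = "old" if code >= 34 else "new"
        confidence = {31: "confident", 32: "probably", 33: "guess",
                      34: "guess", 35: "probably", 36: "confident"}[code]
        return judgment, confidence
    raise ValueError(f"unknown phase {phase!r}")


def parse_block_to_trials(
    block_events: Sequence[EventMarker],
    phase: str,
    ground_truth_labels: Optional[Sequence[int]] = None,
) -> List[TrialRecord]:
    """Parse one block's events into TrialRecords.

    Consumes the stream in strict ``1, 2, 3, response, 6`` groups; any
    missing, duplicated, or leftover marker raises :class:`ParseError`
    naming the trial ordinal and what was expected.  Ground-truth new/old
    labels are not carried in the TTL stream, so recognition trials are
    joined to ``ground_truth_labels`` by trial order.
    """
    resp_codes = set(CODE_MAPS.response_codes(phase))
    events = [
        e
        for e in block_events
        if e.code not in (TTL_START_EXPERIMENT, TTL_END_EXPERIMENT)
    ]
    if len(events) % 5 != 0:
        raise ParseError(
            f"{phase} block has {len(events)} events, not a multiple of 5"
        )
    n_trials = len(events) // 5
    if phase == RECOGNITION:
        if ground_truth_labels is None:
            raise ParseError("recognition block requires ground-truth labels")
        if len(ground_truth_labels) != n_trials:
            raise ParseError(
                f"{n_trials} recognition trials but "
                f"{len(ground_truth_labels)} ground-truth labels"
            )
    trials = []
    for i in range(n_trials):
        chunk = events[5 * i : 5 * i + 5]
        expected = [TTL_STIM_ON, TTL_STIM_OFF, TTL_QUESTION_ON, None, TTL_END_TRIAL]
        for pos, (ev, want) in enumerate(zip(chunk, expected)):
            if want is None:
                if ev.code not in resp_codes:
                    raise ParseError(
                        f"trial {i}: expected a {phase} response code, "
                        f"found {ev.code}"
                    )
            elif ev.code != want:
                raise ParseError(
                    f"trial {i}: expected code {want} at position {pos}, "
                    f"found {ev.code}"
                )
        trials.append(
            TrialRecord(
                phase=phase,
                start_time=chunk[0].time_s,
                stop_time=chunk[1].time_s,
                delay1_time=chunk[2].time_s,
                response_time=chunk[3].time_s,
                delay2_time=chunk[4].time_s,
                response_value=chunk[3].code,
                category_name="",
                stim_category=-1,
                stimulus_id="",
                new_old_label=(
                    int(ground_truth_labels[i]) if phase == RECOGNITION else None
                ),
            )
        )
    return trials


def parse_timeline(
    events: Sequence[EventMarker],
    tags: Sequence[ExperimentTag],
    recognition_labels: Optional[Sequence[int]] = None,
) -> List[TrialRecord]:
    """Full parse: split blocks, then parse each; learning trials first."""
    learning, recognition = split_blocks(events, tags)
    out = parse_block_to_trials(learning, LEARNING)
    out += parse_block_to_trials(recognition, RECOGNITION, recognition_labels)
    return out
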