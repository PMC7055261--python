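"""Serialization of sessions to NWB:N-style HDF5 files, and reading them back.

The on-disk layout follows the NWB:N 2.x organisation used for human
single-neuron recordings: top-level groups ``acquisition`` (events +
experiment_ids streams), ``general`` (devices, extracellular_ephys with the
electrodes table, subject), ``intervals/trials`` (one row per trial),
``stimulus/presentation`` (one group per image), and ``units`` (a
column-based table whose ``spike_times`` column is a ragged array delimited
by ``spike_times_index``).  Column names are kept file-exact
(``new_old_labels_recog``, ``stimCategory``, ``origClusterID``, ``IsolDist``)
even where the in-memory model uses different names.

Event codes are written as text annotations with integer-parseable payloads
(the dialect of the released dataset, whose exporter stringifies the code
column) but are read tolerantly whether stored as text or integers.

Implemented directly on h5py; files carry ``neurodata_type`` attributes so
their intent is readable by NWB-aware tooling.
"""

from __future__ import annotations

from typing import Dict, List

import h5py
import numpy as np

from .core_model import (
    ElectrodeRecord,
    EventMarker,
    ExperimentTag,
    RaggedPair,
    SessionBundle,
    SubjectMeta,
    TrialRecord,
    UnitRecord,
    build_ragged,
    slice_ragged,
    validate_session,
)

__all__ = ["write_session_nwb", "read_session_nwb", "SessionLoadError"]

_STR = h5py.string_dtype(encoding="utf-8")

_VARIANT_OF_LEARN_ID = {80: 1, 83: 2, 88: 3}

_EVENTS_DESCRIPTION = (
    "TTL markers. 55=start of experiment; 1=stimulus onset; 2=stimulus "
    "offset; 3=question screen onset; 20/21=learning response "
    "(yes/no animal); 31-36=recognition response (31 new confident, "
    "32 new probably, 33 new guess, 34 old guess, 35 old probably, "
    "36 old confident); 6=end of trial; 66=end of experiment."
)

_XIDS_DESCRIPTION = (
    "Experiment ids labeling each event's block: 80/83/88=learning phase, "
    "81/84/89=recognition phase."
)


class SessionLoadError(IOError):
    """A required group or dataset is missing or unreadable."""


def _str_ds(group: h5py.Group, name: str, values) -> h5py.Dataset:
    return group.create_dataset(name, data=np.array(values, dtype=object), dtype=_STR)


def _set_type(obj, neurodata_type: str) -> None:
    obj.attrs["neurodata_type"] = neurodata_type
    obj.attrs["namespace"] = "core"


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_session_nwb(session: SessionBundle, path) -> None:
    """Write one session to ``path`` in the NWB-style layout.

    Refuses to write a session that fails :func:`validate_session`.  The
    ``session_start_time`` day is forced to the first of the month, a
    de-identification convention for patient data.
    """
    violations = validate_session(session)
    if violations:
        raise ValueError(
            "refusing to write invalid session: " + "; ".join(violations[:5])
        )

    with h5py.File(path, "w") as f:
        f.attrs["nwb_version"] = "2.2.5"
        _str_ds(f, "identifier", [session.session_id])
        _str_ds(f, "session_description", ["new/old recognition memory task"])
        start = (
            f"{session.session_start_year:04d}-"
            f"{session.session_start_month:02d}-01T00:00:00"
        )
        _str_ds(f, "session_start_time", [start])

        # --- acquisition ---------------------------------------------------
        acq = f.create_group("acquisition")
        ev = acq.create_group("events")
        _set_type(ev, "AnnotationSeries")
        ev.attrs["description"] = _EVENTS_DESCRIPTION
        _str_ds(ev, "data", [str(e.code) for e in session.events])
        ts = ev.create_dataset(
            "timestamps", data=np.array([e.time_s for e in session.events])
        )
        ts.attrs["unit"] = "seconds"

        xg = acq.create_group("experiment_ids")
        _set_type(xg, "TimeSeries")
        xg.attrs["description"] = _XIDS_DESCRIPTION
        xg.create_dataset(
            "data", data=np.array([t.xid for t in session.tags], dtype=np.float64)
        )
        xts = xg.create_dataset(
            "timestamps", data=np.array([t.time_s for t in session.tags])
        )
        xts.attrs["unit"] = "seconds"

        # --- general -------------------------------------------------------
        gen = f.create_group("general")
        _str_ds(gen, "session_id", [session.session_id])
        devices = gen.create_group("devices")
        for dev in sorted({e.device_name for e in session.electrodes}):
            d = devices.create_group(dev)
            _set_type(d, "Device")

        ee = gen.create_group("extracellular_ephys")
        for gname in sorted({e.group_name for e in session.electrodes}):
            grp = ee.create_group(gname)
            _set_type(grp, "ElectrodeGroup")
            first = next(e for e in session.electrodes if e.group_name == gname)
            grp.attrs["description"] = "microwires"
            grp.attrs["location"] = first.location
            grp["device"] = devices[first.device_name]  # hard link

        et = ee.create_group("electrodes")
        _set_type(et, "DynamicTable")
        et.create_dataset(
            "id", data=np.array([e.id for e in session.electrodes], dtype=np.int64)
        )
        _str_ds(et, "location", [e.location for e in session.electrodes])
        for col in ("x", "y", "z"):
            et.create_dataset(
                col, data=np.array([getattr(e, col) for e in session.electrodes])
            )
        _str_ds(et, "filtering", [e.filtering for e in session.electrodes])
        et.create_dataset(
            "origChannel",
            data=np.array([e.orig_channel for e in session.electrodes], dtype=np.int64),
        )
        _str_ds(et, "group_name", [e.group_name for e in session.electrodes])
        _str_ds(et, "device_name", [e.device_name for e in session.electrodes])

        subj = gen.create_group("subject")
        _set_type(subj, "Subject")
        _str_ds(subj, "subject_id", [session.subject.subject_id])
        subj.create_dataset("age", data=np.array([session.subject.age]))
        _str_ds(subj, "sex", [session.subject.sex])
        _str_ds(subj, "species", [session.subject.species])
        _str_ds(subj, "description", [session.subject.description])

        # --- intervals/trials ---------------------------------------------
        iv = f.create_group("intervals")
        tr = iv.create_group("trials")
        _set_type(tr, "TimeIntervals")
        trials = session.trials
        tr.create_dataset("id", data=np.arange(len(trials), dtype=np.int64))
        for col in (
            "start_time",
            "stop_time",
            "delay1_time",
            "response_time",
            "delay2_time",
        ):
            tr.create_dataset(
                col, data=np.array([getattr(t, col) for t in trials])
            )
        _str_ds(
            tr,
            "new_old_labels_recog",
            ["NA" if t.new_old_label is None else str(t.new_old_label) for t in trials],
        )
        tr.create_dataset(
            "response_value",
            data=np.array([t.response_value for t in trials], dtype=np.int64),
        )
        _str_ds(tr, "category_name", [t.category_name for t in trials])
        tr.create_dataset(
            "stimCategory",
            data=np.array([t.stim_category for t in trials], dtype=np.int64),
        )
        _str_ds(tr, "stim_phase", [t.phase for t in trials])
        _str_ds(tr, "stimulus_id", [t.stimulus_id for t in trials])

        # --- stimulus ------------------------------------------------------
        stim = f.create_group("stimulus")
        pres = stim.create_group("presentation")
        learn_i = recog_i = 0
        for t in trials:
            if t.phase == "learning":
                learn_i += 1
                name = f"stimuli_learn_{learn_i}"
            else:
                recog_i += 1
                name = f"stimuli_recog_{recog_i}"
            g = pres.create_group(name)
            _set_type(g, "OpticalSeries")
            g.attrs["stimulus_id"] = t.stimulus_id
            img = session.stimuli.get(t.stimulus_id)
            if img is not None:
                g.create_dataset("data", data=img)

        # --- units ---------------------------------------------------------
        un = f.create_group("units")
        _set_type(un, "Units")
        units = session.units
        un.create_dataset(
            "id", data=np.array([u.unit_id for u in units], dtype=np.int64)
        )
        ragged = build_ragged([u.spike_times for u in units])
        st = un.create_dataset("spike_times", data=ragged.data)
        st.attrs["unit"] = "seconds"
        un.create_dataset("spike_times_index", data=ragged.index)
        n_wf = len(units[0].waveform_mean_encoding) if units else 0
        for col, attr in (
            ("waveform_mean_encoding", "waveform_mean_encoding"),
            ("waveform_mean_recognition", "waveform_mean_recognition"),
        ):
            arr = np.vstack([getattr(u, attr) for u in units]) if units else np.empty(
                (0, n_wf)
            )
            ds = un.create_dataset(col, data=arr)
            ds.attrs["unit"] = "microvolts"
            ds.attrs["sampling_rate"] = (
                units[0].waveform_rate_hz if units else 100_000.0
            )
        un.create_dataset(
            "origClusterID",
            data=np.array([u.orig_cluster_id for u in units], dtype=np.int64),
        )
        un.create_dataset("SNR", data=np.array([u.snr for u in units]))
        un.create_dataset("IsolDist", data=np.array([u.isol_dist for u in units]))
        un.create_dataset(
            "electrodes",
            data=np.array([u.electrode_index for u in units], dtype=np.int64),
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _decode(x):
    return x.decode() if isinstance(x, bytes) else x


def _read_str_col(group: h5py.Group, name: str) -> List[str]:
    return [_decode(v) for v in group[name][()]]


def _require(f: h5py.File, path: str) -> h5py.Group:
    if path not in f:
        raise SessionLoadError(f"required group {path!r} missing from file")
    return f[path]


def _codes_as_int(raw) -> np.ndarray:
    """Event codes may be stored as integers, floats, or numeric text."""
    out = []
    for v in raw:
        v = _decode(v)
        out.append(int(float(v)) if isinstance(v, str) else int(round(float(v))))
    return np.array(out, dtype=int)


def read_session_nwb(path) -> SessionBundle:
    """Read an NWB-style session file back into a :class:`SessionBundle`.

    Tolerant where released files vary (text vs integer event codes, absent
    stimulus group); loud where structure is required (units, trials,
    events), raising :class:`SessionLoadError` naming the missing group.
    """
    with h5py.File(path, "r") as f:
        ev = _require(f, "acquisition/events")
        codes = _codes_as_int(ev["data"][()])
        times = np.asarray(ev["timestamps"][()], dtype=float)
        events = [EventMarker(float(t), int(c)) for t, c in zip(times, codes)]

        xg = _require(f, "acquisition/experiment_ids")
        xids = _codes_as_int(xg["data"][()])
        xtimes = np.asarray(xg["timestamps"][()], dtype=float)
        tags = [ExperimentTag(float(t), int(x)) for t, x in zip(xtimes, xids)]

        tr = _require(f, "intervals/trials")
        n = len(tr["start_time"])
        labels_raw = _read_str_col(tr, "new_old_labels_recog")
        phases = _read_str_col(tr, "stim_phase")
        cats = _read_str_col(tr, "category_name")
        stim_ids = (
            _read_str_col(tr, "stimulus_id") if "stimulus_id" in tr else [""] * n
        )
        trials = []
        for i in range(n):
            lab = labels_raw[i]
            trials.append(
                TrialRecord(
                    phase=phases[i],
                    start_time=float(tr["start_time"][i]),
                    stop_time=float(tr["stop_time"][i]),
                    delay1_time=float(tr["delay1_time"][i]),
                    response_time=float(tr["response_time"][i]),
                    delay2_time=float(tr["delay2_time"][i]),
                    response_value=int(round(float(tr["response_value"][i]))),
                    category_name=cats[i],
                    stim_category=int(round(float(tr["stimCategory"][i]))),
                    stimulus_id=stim_ids[i],
                    new_old_label=None if lab == "NA" else int(float(lab)),
                )
            )

        un = _require(f, "units")
        ragged = RaggedPair(
            data=un["spike_times"][()], index=un["spike_times_index"][()]
        )
        wf_enc = np.asarray(un["waveform_mean_encoding"][()])
        wf_rec = np.asarray(un["waveform_mean_recognition"][()])
        rate = float(
            un["waveform_mean_encoding"].attrs.get("sampling_rate", 100_000.0)
        )
        ids = un["id"][()]
        units = [
            UnitRecord(
                unit_id=int(ids[i]),
                electrode_index=int(un["electrodes"][i]),
                spike_times=slice_ragged(ragged, i),
                waveform_mean_encoding=wf_enc[i],
                waveform_mean_recognition=wf_rec[i],
                snr=float(un["SNR"][i]),
                isol_dist=float(un["IsolDist"][i]),
                orig_cluster_id=int(un["origClusterID"][i]),
                waveform_rate_hz=rate,
            )
            for i in range(len(ids))
        ]

        et = _require(f, "general/extracellular_ephys/electrodes")
        locs = _read_str_col(et, "location")
        filts = _read_str_col(et, "filtering")
        gnames = _read_str_col(et, "group_name")
        dnames = _read_str_col(et, "device_name")
        electrodes = [
            ElectrodeRecord(
                id=int(et["id"][i]),
                location=locs[i],
                x=float(et["x"][i]),
                y=float(et["y"][i]),
                z=float(et["z"][i]),
                filtering=filts[i],
                orig_channel=int(et["origChannel"][i]),
                group_name=gnames[i],
                device_name=dnames[i],
            )
            for i in range(len(et["id"]))
        ]

        sg = _require(f, "general/subject")
        subject = SubjectMeta(
            subject_id=_decode(sg["subject_id"][0]),
            age=int(sg["age"][0]),
            sex=_decode(sg["sex"][0]),
            species=_decode(sg["species"][0]),
            description=_decode(sg["description"][0]),
        )

        stimuli: Dict[str, np.ndarray] = {}
        if "stimulus/presentation" in f:
            for name, g in f["stimulus/presentation"].items():
                sid = g.attrs.get("stimulus_id", name)
                if "data" in g:
                    stimuli[_decode(sid)] = np.asarray(g["data"][()])

        session_id = (
            _decode(f["general/session_id"][0])
            if "general/session_id" in f
            else _decode(f["identifier"][0])
        )
        start = _decode(f["session_start_time"][0]) if "session_start_time" in f else ""
        year, month = 2019, 1
        if len(start) >= 7:
            try:
                year, month = int(start[:4]), int(start[5:7])
            except ValueError:
                pass

        learn_ids = {x for x in xids if x in _VARIANT_OF_LEARN_ID}
        variant = _VARIANT_OF_LEARN_ID[next(iter(learn_ids))] if learn_ids else 1

        return SessionBundle(
            session_id=session_id,
            variant=variant,
            subject=subject,
            electrodes=electrodes,
            units=units,
            events=events,
            tags=tags,
            trials=trials,
            stimuli=stimuli,
            session_start_year=year,
            session_start_month=month,
        )
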