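"""Serialization: EDF export, event tables, and session logs.

The EDF writer emits plain 16-bit EDF (one data record per second, physical
units microvolts).  It exists because the package must round-trip its
synthetic sessions through the standard exchange format; reading is done
with mne's independent EDF reader (see preproc.read_edf).
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from datetime import datetime
from pathlib import Path

import numpy as np

from .synthgen import (
    CUE_S,
    FEEDBACK_MAX_S,
    REST_S,
    ContinuousRecording,
    SynthConfig,
    TrialInfo,
    TrialSchedule,
)

__all__ = [
    "write_edf",
    "write_event_table",
    "schedule_to_events",
    "schedule_from_events",
    "export_session",
    "import_session",
]


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(recording: ContinuousRecording, path) -> None:
    """Write a continuous recording as 16-bit EDF, 1-s data records.

    Requires an integer sampling rate; the last partial second is
    zero-padded.  Physical range is set per channel from the data.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    x = recording.samples
    n_ch, n = x.shape
    n_rec = int(np.ceil(n / fs))
    pad = n_rec * fs - n
    if pad:
        x = np.hstack([x, np.zeros((n_ch, pad))])

    pmin = x.min(axis=1)
    pmax = x.max(axis=1)
    same = pmax - pmin < 1e-9
    pmax[same] = pmin[same] + 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        start = datetime(2000, 1, 1)
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_pad(start.strftime("%d.%m.%y"), 8))
        fh.write(_pad(start.strftime("%H.%M.%S"), 8))
        fh.write(_pad(str(256 * (1 + n_ch)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for name in recording.channel_names:
            fh.write(_pad(name, 16))
        for _ in range(n_ch):
            fh.write(_pad("EEG", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in pmin:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for v in pmax:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(fs), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))

        scale = (pmax - pmin) / (dmax - dmin)
        digital = np.round((x - pmin[:, None]) / scale[:, None] + dmin).astype("<i2")
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def schedule_to_events(schedule: TrialSchedule) -> list[tuple[float, str, str]]:
    events = []
    for tr in schedule:
        events.append((tr.rest_onset, "rest", tr.label))
        events.append((tr.cue_onset, f"cue_{tr.label}", tr.label))
        events.append((tr.feedback_onset, "feedback", tr.label))
    return events


def write_event_table(schedule: TrialSchedule, path) -> None:
    """Delimited text: time_s, code, label — one row per landmark."""
    with open(path, "w") as fh:
        fh.write("time_s\tcode\tlabel\n")
        for t, code, label in schedule_to_events(schedule):
            fh.write(f"{t:.6f}\t{code}\t{label}\n")


def schedule_from_events(events: list[tuple[float, str]]) -> TrialSchedule:
    """Rebuild a trial schedule from rest/cue/feedback markers."""
    trials = []
    rest = None
    cue = None
    k = 0
    for t, code in events:
        code = code.split("\t")[0]
        if code == "rest":
            rest = t
        elif code.startswith("cue_"):
            cue = (t, code.removeprefix("cue_"))
        elif code == "feedback":
            if rest is None or cue is None:
                raise ValueError("feedback marker without preceding rest/cue")
            trials.append(
                TrialInfo(
                    run=0, trial=k, label=cue[1],
                    rest_onset=rest, cue_onset=cue[0],
                    feedback_onset=t, feedback_deadline=t + FEEDBACK_MAX_S,
                )
            )
            k += 1
            rest = cue = None
    return TrialSchedule(trials)


# -- session export ---------------------------------------------------------

_SESSION_VERSION = 1


def export_session(result, out_dir) -> None:
    """Write a SessionResult as plain-text files (lossless round-trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "trials.tsv", "w") as fh:
        fh.write("run\ttrial\tlabel\tresult\tduration_s\tcalibration\n")
        for o in result.all_outcomes():
            fh.write(
                f"{o.run}\t{o.trial}\t{o.label}\t{o.result}"
                f"\t{o.feedback_duration:.6f}\t{int(o.calibration)}\n"
            )
    with open(out / "summary.tsv", "w") as fh:
        fh.write("run\tpvc\n")
        for r, p in enumerate(result.run_pvc):
            fh.write(f"{r}\t{'NA' if p is None else f'{p:.6f}'}\n")
        sp = result.session_pvc
        fh.write(f"session\t{'NA' if sp is None else f'{sp:.6f}'}\n")
    meta = {
        "version": _SESSION_VERSION,
        "decoder_kind": result.decoder_kind,
        "config": asdict(result.config),
        "snapshots": result.snapshots,
        "trajectories": [
            [[o.trial, o.trajectory] for o in run] for run in result.outcomes
        ],
    }
    with open(out / "session.json", "w") as fh:
        json.dump(meta, fh)


def import_session(in_dir):
    """Inverse of export_session."""
    from .closed_loop import SessionResult, TrialOutcome  # local: avoid cycle

    src = Path(in_dir)
    for fname in ("trials.tsv", "summary.tsv", "session.json"):
        if not (src / fname).exists():
            raise FileNotFoundError(f"session export is missing {fname}")
    with open(src / "session.json") as fh:
        meta = json.load(fh)
    if meta.get("version") != _SESSION_VERSION:
        raise ValueError("unsupported session export version")
    cfg_d = meta["config"]
    cfg_d["env_bounds"] = tuple(cfg_d["env_bounds"])
    config = SynthConfig(**cfg_d)
    traj = {}
    for run in meta["trajectories"]:
        for trial, t in run:
            traj[trial] = [tuple(p) for p in t]

    outcomes: dict[int, list[TrialOutcome]] = {}
    with open(src / "trials.tsv") as fh:
        header = fh.readline()
        for line in fh:
            run_s, trial_s, label, res, dur, cal = line.split("\t")
            o = TrialOutcome(
                label=label,
                result=res,
                feedback_duration=float(dur),
                trajectory=traj.get(int(trial_s), []),
                calibration=bool(int(cal)),
                run=int(run_s),
                trial=int(trial_s),
            )
            outcomes.setdefault(o.run, []).append(o)
    per_run = [outcomes.get(r, []) for r in range(config.n_runs)]

    run_pvc, session_pvc = [], None
    with open(src / "summary.tsv") as fh:
        fh.readline()
        for line in fh:
            key, val = line.split("\t")
            v = None if val.strip() == "NA" else float(val)
            if key == "session":
                session_pvc = v
            else:
                run_pvc.append(v)
    return SessionResult(
        meta["decoder_kind"], per_run, run_pvc, session_pvc, meta["snapshots"], config
    )
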