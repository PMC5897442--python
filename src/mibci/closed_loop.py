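"""The online cursor-control paradigm.

One-dimensional cursor on a normalized screen: position 0 is the center,
+1 the right target, -1 the left target.  Every 0.1-s control block the
decoder maps the trailing signal window to a normalized control value; the
cursor integrates position += gain * control * dt and the trial ends at a
boundary crossing (hit on the cued side, miss on the other) or at the 6-s
feedback cap (abort).  The velocity gain is set so a sustained control value
of +1 crosses the center-to-target distance in 3 s.

Calibration rules mirror the paradigm: CSP pipelines freeze the cursor for
the whole first run (training data) and batch-retrain after every run on the
trailing 50 trials (25 before run 2); the Laplacian pipeline freezes only the
first trial of each run to calibrate its adaptive normalizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import montage as mt
from .decoders import (
    CSPPipeline,
    LapPipeline,
    NormalizerState,
    normalizer_apply,
    normalizer_update,
    retrain_batch,
)
from .preproc import bandpass, epoch
from .synthgen import (
    FEEDBACK_MAX_S,
    ContinuousRecording,
    SynthConfig,
    TrialInfo,
    generate_session,
)

__all__ = [
    "CursorState",
    "TrialOutcome",
    "SessionResult",
    "PVCUndefinedError",
    "run_trial",
    "run_session",
    "pvc",
    "switch_over_schedule",
    "simulate_group",
    "BLOCK_S",
    "CURSOR_GAIN",
    "DECODER_KINDS",
]

BLOCK_S = 0.1          # control-loop block length (s)
CURSOR_GAIN = 1.0 / 3  # unit control crosses half-screen (distance 1) in 3 s
DECODER_KINDS = ("LAP/S", "CSP/L", "CSP/S")


class PVCUndefinedError(ValueError):
    """Raised when PVC is requested but no valid (hit/miss) outcomes exist."""


@dataclass
class CursorState:
    position: float = 0.0
    time_in_feedback: float = 0.0

    def step(self, control: float, dt: float = BLOCK_S, gain: float = CURSOR_GAIN) -> None:
        self.position = float(np.clip(self.position + gain * control * dt, -1.0, 1.0))
        self.time_in_feedback += dt

    @property
    def at_boundary(self) -> bool:
        # small tolerance so exact analytic crossing times are not missed to
        # float accumulation over control blocks
        return abs(self.position) >= 1.0 - 1e-9


@dataclass
class TrialOutcome:
    label: str
    result: str                 # hit | miss | abort
    feedback_duration: float
    trajectory: list = field(default_factory=list)  # (t_in_feedback, position)
    calibration: bool = False
    run: int = 0
    trial: int = 0


@dataclass
class SessionResult:
    decoder_kind: str
    outcomes: list[list[TrialOutcome]]      # per run
    run_pvc: list
    session_pvc: float | None
    snapshots: list                         # per-run decoder state dicts
    config: SynthConfig

    def all_outcomes(self) -> list[TrialOutcome]:
        return [o for run in self.outcomes for o in run]


def pvc(outcomes: list[TrialOutcome]) -> float:
    """Percent Valid Correct: hits / (hits + misses); aborts and calibration
    trials excluded.  Raises PVCUndefinedError when no valid outcome exists."""
    valid = [o for o in outcomes if not o.calibration and o.result in ("hit", "miss")]
    if not valid:
        raise PVCUndefinedError("no valid (hit/miss) outcomes")
    hits = sum(o.result == "hit" for o in valid)
    return hits / len(valid)


def run_trial(
    stream: ContinuousRecording,
    decoder,
    spec: TrialInfo,
    window_s: float,
    frozen: bool = False,
    calibration: bool = False,
) -> TrialOutcome:
    """Stream one trial's feedback period through the decoder.

    `decoder` is a callable mapping a trailing (channels, time) window ending
    at the current block boundary to a normalized control value.  With
    `frozen` the control value is still computed (the normalizer may adapt)
    but the cursor does not move.
    """
    fs = stream.sampling_rate
    n_blocks = int(round(FEEDBACK_MAX_S / BLOCK_S))
    if (spec.feedback_onset + FEEDBACK_MAX_S) * fs > stream.samples.shape[1] + 1e-6:
        raise ValueError(f"trial {spec.trial}: stream does not cover the feedback period")
    cursor = CursorState()
    traj = [(0.0, 0.0)]
    result = "abort"
    duration = FEEDBACK_MAX_S
    for k in range(1, n_blocks + 1):
        t = spec.feedback_onset + k * BLOCK_S
        window = stream.segment(t - window_s, t)
        control = decoder(window)
        if frozen:
            continue
        cursor.step(control)
        traj.append((round(k * BLOCK_S, 10), cursor.position))
        if cursor.at_boundary:
            duration = k * BLOCK_S
            hit_right = cursor.position > 0
            result = "hit" if (hit_right == (spec.label == "right")) else "miss"
            break
    if frozen:
        traj = []
    return TrialOutcome(
        label=spec.label,
        result=result,
        feedback_duration=duration,
        trajectory=traj,
        calibration=calibration,
        run=spec.run,
        trial=spec.trial,
    )


def run_session(
    config: SynthConfig,
    layout: mt.ElectrodeLayout,
    decoder_kind: str,
    seed: int | None = None,
) -> SessionResult:
    """Simulate one full closed-loop session with the given decoding pipeline.

    The recording is generated on the pipeline's own montage subset of
    `layout`.  Deterministic given (config, seed, decoder_kind).
    """
    if decoder_kind not in DECODER_KINDS:
        raise ValueError(f"unknown decoder kind {decoder_kind!r}")
    if seed is not None:
        config = replace(config, seed=seed)

    channels = (
        mt.large_montage(layout) if decoder_kind == "CSP/L" else mt.small_montage(layout)
    )
    sub = layout.subset(channels)
    recording, schedule = generate_session(config, sub)

    if decoder_kind in ("CSP/L", "CSP/S"):
        return _run_csp_session(config, recording, schedule, channels, decoder_kind)
    return _run_lap_session(config, recording, schedule, sub, decoder_kind)


def _run_csp_session(config, recording, schedule, channels, kind) -> SessionResult:
    filtered = bandpass(recording, causal=True)
    epochs = epoch(filtered, schedule)  # training pool, causally filtered
    pipeline = CSPPipeline(channels)
    outcomes: list[list[TrialOutcome]] = []
    snapshots = []
    for r in range(config.n_runs):
        if r == 0:
            # calibration run: cursor frozen, imagery still performed
            run_out = [
                run_trial(filtered, lambda w: 0.0, tr, pipeline.window_s,
                          frozen=True, calibration=True)
                for tr in schedule if tr.run == 0
            ]
        else:
            history = [ep for ep in epochs if ep.run < r]
            pipeline = retrain_batch(history, run_index=r + 1, pipeline=pipeline)
            run_out = [
                run_trial(filtered, pipeline.control, tr, pipeline.window_s)
                for tr in schedule if tr.run == r
            ]
        outcomes.append(run_out)
        snapshots.append(pipeline.snapshot())
    return _finish(kind, outcomes, snapshots, config)


def _run_lap_session(config, recording, schedule, sub_layout, kind) -> SessionResult:
    pipeline = LapPipeline(sub_layout)
    state = NormalizerState(block_s=BLOCK_S)
    fs = recording.sampling_rate
    names = recording.channel_names

    def decoder(window, adapt=True):
        raw = pipeline.control_raw(window, names, fs)
        z = normalizer_apply(state, raw)
        if adapt:
            normalizer_update(state, raw)
        return z

    outcomes: list[list[TrialOutcome]] = []
    snapshots = []
    for r in range(config.n_runs):
        run_out = []
        for j, tr in enumerate([t for t in schedule if t.run == r]):
            first = j == 0
            run_out.append(
                run_trial(recording, decoder, tr, pipeline.window_s,
                          frozen=first, calibration=first)
            )
        outcomes.append(run_out)
        snapshots.append(state.to_dict())
    return _finish(kind, outcomes, snapshots, config)


def _finish(kind, outcomes, snapshots, config) -> SessionResult:
    run_pvc = []
    for run_out in outcomes:
        try:
            run_pvc.append(pvc(run_out))
        except PVCUndefinedError:
            run_pvc.append(None)
    try:
        session_pvc = pvc([o for run in outcomes for o in run])
    except PVCUndefinedError:
        session_pvc = None
    return SessionResult(kind, outcomes, run_pvc, session_pvc, snapshots, config)


def switch_over_schedule(group: str) -> list[str]:
    """Per-session decoder kinds for the three experimental groups."""
    schedules = {
        "G1": ["LAP/S"] * 3 + ["CSP/L"] * 2,
        "G2": ["CSP/L"] * 3 + ["LAP/S"] * 2,
        "G3": ["CSP/S"] * 5,
    }
    if group not in schedules:
        raise ValueError(f"unknown group {group!r} (expected G1, G2 or G3)")
    return schedules[group]


def simulate_group(
    group: str,
    config: SynthConfig,
    layout: mt.ElectrodeLayout,
    learning_rate: float = 0.0,
) -> list[SessionResult]:
    """Run a group's five-session switch-over protocol.

    `learning_rate` optionally drifts erd_depth upward per session to emulate
    a subject acquiring imagery skill (default off: the simulated subject
    does not learn).
    """
    results = []
    for s, kind in enumerate(switch_over_schedule(group)):
        cfg = replace(
            config,
            erd_depth=float(min(config.erd_depth + s * learning_rate, 1.0)),
            seed=config.seed + s,
        )
        results.append(run_session(cfg, layout, kind))
    return results
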