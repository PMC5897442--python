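"""Filtering, epoching, band power, and artifact-trial rejection.

Conventions: half-open, 0-based sample indexing; landmark seconds are floored
to samples.  Offline filtering is zero-phase (forward-backward Butterworth);
the closed-loop path uses the causal variant of the same filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthgen import ContinuousRecording, TrialSchedule

__all__ = [
    "TrialEpoch",
    "RejectionReport",
    "bandpass",
    "epoch",
    "band_power",
    "rest_baseline_spectrum",
    "spectral_deviation_db",
    "reject_artifact_trials",
    "read_edf",
    "read_event_table",
    "write_rejection_report",
]

CONTROL_BAND = (8.0, 26.0)
ARTIFACT_BAND = (7.0, 35.0)
ARTIFACT_DB = 35.0
MIN_FEEDBACK_S = 2.0


@dataclass
class TrialEpoch:
    """One trial's samples with trial-relative timing landmarks."""

    samples: np.ndarray          # (channels, time), from rest onset
    sampling_rate: float
    channel_names: list[str]
    label: str                   # 'left' | 'right'
    rest_onset: float = 0.0      # trial-relative seconds
    cue_onset: float = 3.0
    feedback_onset: float = 6.0
    feedback_end: float = 12.0   # actual end (may be < deadline after a hit/miss)
    outcome: str = "none"        # hit | miss | abort | none
    run: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        if not (self.rest_onset <= self.cue_onset <= self.feedback_onset <= self.feedback_end):
            raise ValueError("landmarks must be ordered")
        if self.feedback_end - self.feedback_onset > 6.0 + 1e-9:
            raise ValueError("feedback period exceeds the 6-s cap")

    @property
    def feedback_duration(self) -> float:
        return self.feedback_end - self.feedback_onset

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Trial-relative [t0, t1) samples."""
        i0 = int(t0 * self.sampling_rate)
        i1 = int(t1 * self.sampling_rate)
        if i0 < 0 or i1 > self.samples.shape[1]:
            raise ValueError(f"window [{t0}, {t1}) outside epoch")
        return self.samples[:, i0:i1]


@dataclass
class RejectionReport:
    kept: list[int]
    rejected: list[int]
    reasons: dict = field(default_factory=dict)       # trial -> reason
    deviation_db: dict = field(default_factory=dict)  # trial -> max |dB|

    def __post_init__(self) -> None:
        if set(self.kept) & set(self.rejected):
            raise ValueError("kept and rejected must be disjoint")


def bandpass(
    recording: ContinuousRecording,
    low: float = CONTROL_BAND[0],
    high: float = CONTROL_BAND[1],
    order: int = 4,
    causal: bool = False,
) -> ContinuousRecording:
    """Butterworth band-pass; zero-phase offline, causal for the online path."""
    nyq = recording.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"invalid band ({low}, {high}) for fs={recording.sampling_rate}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    if causal:
        out = sps.sosfilt(sos, recording.samples, axis=1)
    else:
        out = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(
        out, recording.sampling_rate, list(recording.channel_names), list(recording.markers)
    )


def epoch(recording: ContinuousRecording, schedule: TrialSchedule) -> list[TrialEpoch]:
    """Cut one epoch per scheduled trial, rest onset to feedback deadline."""
    epochs = []
    n = recording.samples.shape[1]
    fs = recording.sampling_rate
    for tr in schedule:
        i0 = int(tr.rest_onset * fs)
        i1 = int(tr.feedback_deadline * fs)
        if i0 < 0 or i1 > n:
            raise ValueError(f"trial {tr.trial}: landmarks outside recording")
        epochs.append(
            TrialEpoch(
                samples=recording.samples[:, i0:i1],
                sampling_rate=fs,
                channel_names=list(recording.channel_names),
                label=tr.label,
                rest_onset=0.0,
                cue_onset=tr.cue_onset - tr.rest_onset,
                feedback_onset=tr.feedback_onset - tr.rest_onset,
                feedback_end=tr.feedback_deadline - tr.rest_onset,
                run=tr.run,
                trial=tr.trial,
            )
        )
    return epochs


def band_power(
    segment: np.ndarray, sampling_rate: float, band: tuple = CONTROL_BAND
) -> np.ndarray:
    """Welch average power within `band`, per channel (Hann, 50% overlap)."""
    segment = np.atleast_2d(segment)
    min_len = int(2 * sampling_rate / band[0])  # two cycles of the low edge
    if segment.shape[1] < min_len:
        raise ValueError(
            f"segment of {segment.shape[1]} samples too short for band {band}"
        )
    nperseg = min(segment.shape[1], int(2 * sampling_rate))
    f, p = sps.welch(segment, fs=sampling_rate, nperseg=nperseg, axis=1)
    m = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[:, m], f[m], axis=1)


def _welch_1hz(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD at 1-Hz resolution, Hann window, 50% overlap."""
    nper = min(x.shape[-1], int(fs))
    return sps.welch(x, fs=fs, nperseg=nper, axis=-1)


def rest_baseline_spectrum(epochs: list[TrialEpoch]) -> tuple[np.ndarray, np.ndarray]:
    """Median rest-period (0-3 s) PSD across trials, per channel.

    The median is robust to the very artifacts the rejection rule targets.
    Returns (freqs, psd[channels, freqs]).
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    psds = []
    for ep in epochs:
        f, p = _welch_1hz(ep.window(ep.rest_onset, ep.cue_onset), ep.sampling_rate)
        psds.append(p)
    return f, np.median(np.asarray(psds), axis=0)


def spectral_deviation_db(
    ep: TrialEpoch,
    baseline: tuple[np.ndarray, np.ndarray],
    band: tuple = ARTIFACT_BAND,
) -> float:
    """Max |10 log10(feedback PSD / baseline PSD)| over channel-frequency bins."""
    f_base, p_base = baseline
    f, p = _welch_1hz(ep.window(ep.feedback_onset, ep.feedback_end), ep.sampling_rate)
    if len(f) != len(f_base) or not np.allclose(f, f_base):
        # interpolate onto baseline grid (short feedback → coarser grid)
        p = np.array([np.interp(f_base, f, row) for row in p])
    m = (f_base >= band[0]) & (f_base <= band[1])
    with np.errstate(divide="ignore"):
        dev = 10.0 * np.log10(p[:, m] / p_base[:, m])
    return float(np.max(np.abs(dev)))


def reject_artifact_trials(
    epochs: list[TrialEpoch],
    baseline: tuple[np.ndarray, np.ndarray] | None = None,
    deviation_db: float = ARTIFACT_DB,
    min_feedback_s: float = MIN_FEEDBACK_S,
) -> RejectionReport:
    """Reject trials whose feedback spectrum deviates from rest baseline by
    more than +-35 dB in any 7-35 Hz channel-frequency bin, or whose feedback
    lasted under 2 s.  The test is per-bin (the stricter reading)."""
    if baseline is None:
        baseline = rest_baseline_spectrum(epochs)
    kept, rejected, reasons, devs = [], [], {}, {}
    for i, ep in enumerate(epochs):
        if ep.feedback_duration < min_feedback_s:
            rejected.append(i)
            reasons[i] = "short_feedback"
            continue
        d = spectral_deviation_db(ep, baseline)
        devs[i] = d
        if d > deviation_db:
            rejected.append(i)
            reasons[i] = "spectral_deviation"
        else:
            kept.append(i)
    return RejectionReport(kept, rejected, reasons, devs)


def read_edf(path) -> ContinuousRecording:
    """Read a continuous EDF recording (annotations become markers)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    markers = sorted(
        (float(a["onset"]), str(a["description"])) for a in raw.annotations
    )
    return ContinuousRecording(samples, raw.info["sfreq"], list(raw.ch_names), markers)


def read_event_table(path) -> list[tuple[float, str]]:
    """Delimited event table: header 'time_s<TAB>code', one event per row."""
    events = []
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["time_s", "code"]:
            raise ValueError("event table must have header 'time_s code'")
        for line in fh:
            t, code = line.split("\t")[:2]
            events.append((float(t), code.strip()))
    return events


def write_rejection_report(report: RejectionReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("trial\tkept\treason\tdeviation_db\n")
        for i in sorted([*report.kept, *report.rejected]):
            kept = i in report.kept
            reason = report.reasons.get(i, "")
            dev = report.deviation_db.get(i, float("nan"))
            fh.write(f"{i}\t{int(kept)}\t{reason}\t{dev:.3f}\n")
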