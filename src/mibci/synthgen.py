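"""Seeded synthetic EEG session generator.

Emulates the closed-loop motor-imagery paradigm's recordings: two
sensorimotor-rhythm sources (mu ~10 Hz + beta ~20 Hz) at the C3 and C4
positions whose amplitude is attenuated contralateral to the imagined hand
during cue and feedback (event-related desynchronization), an optional
occipital alpha distractor, Gaussian volume-conduction mixing to the scalp
channels, and spatially smoothed 1/f background noise.

Trial anatomy (seconds, trial-relative): rest 0-3, cue 3-6, feedback onset 6,
feedback deadline 12 (6-s cap), 1-s post-feedback gap; 13 s per trial slot.
A session is 10 runs x 25 trials by default, targets block-randomized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .montage import ElectrodeLayout

__all__ = [
    "SynthConfig",
    "TrialInfo",
    "TrialSchedule",
    "ContinuousRecording",
    "make_target_sequence",
    "generate_session",
    "inject_artifacts",
    "REST_S",
    "CUE_S",
    "FEEDBACK_MAX_S",
    "POST_FEEDBACK_S",
    "TRIAL_SLOT_S",
]

REST_S = 3.0
CUE_S = 3.0
FEEDBACK_MAX_S = 6.0
POST_FEEDBACK_S = 1.0
TRIAL_SLOT_S = REST_S + CUE_S + FEEDBACK_MAX_S + POST_FEEDBACK_S  # 13 s

# fixed source positions on the unit-head disc (layout-independent)
_SRC_POS = {"C3": (-0.4, 0.0), "C4": (0.4, 0.0), "Oz": (0.0, -0.8)}


@dataclass
class SynthConfig:
    """Generator parameters; defaults are the simulated study conditions."""

    sampling_rate: float = 250.0  # Hz; 1000 supported
    erd_depth: float = 0.5       # fractional contralateral amplitude attenuation
    mu_freq: float = 10.0        # Hz
    beta_freq: float = 20.0      # Hz
    beta_rel_amp: float = 0.5    # beta amplitude relative to mu
    snr: float = 1.0             # 8-26 Hz rhythm/noise power ratio at source electrode
    mixing_sigma: float = 0.25   # Gaussian gain spread, layout units
    artifact_rate: float = 0.0   # artifacts per run
    artifact_db: float = 40.0    # injected spectral deviation magnitude (dB)
    n_runs: int = 10
    trials_per_run: int = 25
    seed: int = 0
    # secondary knobs
    env_sigma: float = 0.3            # log-amplitude diffusion per sqrt(s)
    env_bounds: tuple = (0.5, 2.0)    # reflecting bounds on envelope amplitude
    distractor: bool = True           # occipital alpha source
    distractor_amp: float = 1.0       # relative to sensorimotor source amplitude
    noise_spatial_sigma: float = 0.15
    session_gain_jitter: float = 0.0  # sd of per-session multiplicative gain
    source_amp_uv: float = 10.0       # base source amplitude (microvolt scale)

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.sampling_rate <= 2 * self.beta_freq:
            raise ValueError("sampling_rate must exceed 2 x beta_freq")
        if self.trials_per_run < 1 or self.n_runs < 1:
            raise ValueError("n_runs and trials_per_run must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass
class TrialInfo:
    run: int            # 0-based
    trial: int          # 0-based within session
    label: str          # 'left' | 'right'
    rest_onset: float   # absolute seconds
    cue_onset: float
    feedback_onset: float
    feedback_deadline: float
    calibration: bool = False


@dataclass
class TrialSchedule:
    trials: list[TrialInfo]

    def __post_init__(self) -> None:
        for t in self.trials:
            if not (t.rest_onset < t.cue_onset < t.feedback_onset < t.feedback_deadline):
                raise ValueError(f"trial {t.trial}: landmarks out of order")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i) -> TrialInfo:
        return self.trials[i]

    def labels(self) -> list[str]:
        return [t.label for t in self.trials]

    def for_runs(self, runs) -> "TrialSchedule":
        runs = set(runs)
        return TrialSchedule([t for t in self.trials if t.run in runs])


@dataclass
class ContinuousRecording:
    """Multichannel time series in microvolts with event markers."""

    samples: np.ndarray          # (channels, time)
    sampling_rate: float
    channel_names: list[str]
    markers: list = field(default_factory=list)  # (time_s, code) pairs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_names):
            raise ValueError("samples must be (n_channels, n_times)")
        times = [t for t, _ in self.markers]
        if times != sorted(times):
            raise ValueError("markers must be time-sorted")
        if times and (times[0] < 0 or times[-1] > self.duration):
            raise ValueError("markers must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples in [t0, t1), half-open, landmarks floored to samples."""
        i0 = int(t0 * self.sampling_rate)
        i1 = int(t1 * self.sampling_rate)
        if i0 < 0 or i1 > self.samples.shape[1]:
            raise ValueError(f"segment [{t0}, {t1}) outside recording")
        return self.samples[:, i0:i1]

    def pick(self, names: list[str]) -> "ContinuousRecording":
        idx = [self.channel_names.index(n) for n in names]
        return ContinuousRecording(
            self.samples[idx], self.sampling_rate, list(names), list(self.markers)
        )


def make_target_sequence(n_trials: int, seed: int) -> list[str]:
    """Block-randomized left/right targets: shuffled (L,R) pairs, roughly equal."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for _ in range(n_trials // 2):
        block = ["left", "right"]
        rng.shuffle(block)
        labels.extend(block)
    if n_trials % 2:
        labels.append(["left", "right"][rng.integers(2)])
    return labels


def make_schedule(config: SynthConfig, seed: int | None = None) -> TrialSchedule:
    """Session schedule: fixed 13-s trial slots, block-randomized targets per run."""
    ss = np.random.SeedSequence([config.seed if seed is None else seed, 101])
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_runs)]
    trials = []
    k = 0
    for run in range(config.n_runs):
        labels = make_target_sequence(config.trials_per_run, run_seeds[run])
        for j, lab in enumerate(labels):
            t0 = k * TRIAL_SLOT_S
            trials.append(
                TrialInfo(
                    run=run,
                    trial=k,
                    label=lab,
                    rest_onset=t0,
                    cue_onset=t0 + REST_S,
                    feedback_onset=t0 + REST_S + CUE_S,
                    feedback_deadline=t0 + REST_S + CUE_S + FEEDBACK_MAX_S,
                )
            )
            k += 1
    return TrialSchedule(trials)


def _reflected_walk(rng, n: int, step_sd: float, lo: float, hi: float) -> np.ndarray:
    """Random walk reflected into [lo, hi] (triangle-wave folding)."""
    x = np.cumsum(rng.normal(0.0, step_sd, n))
    x += rng.uniform(lo, hi)
    span = hi - lo
    u = np.mod(x - lo, 2 * span)
    return lo + np.where(u < span, u, 2 * span - u)


def _source_waveform(rng, cfg: SynthConfig, n: int) -> np.ndarray:
    """Amplitude-modulated mu+beta sinusoid pair with log-normal envelope."""
    fs = cfg.sampling_rate
    t = np.arange(n) / fs
    lo, hi = np.log(cfg.env_bounds[0]), np.log(cfg.env_bounds[1])
    env = np.exp(_reflected_walk(rng, n, cfg.env_sigma / np.sqrt(fs), lo, hi))
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    wave = np.sin(2 * np.pi * cfg.mu_freq * t + ph1)
    wave += cfg.beta_rel_amp * np.sin(2 * np.pi * cfg.beta_freq * t + ph2)
    return env * wave


def _erd_gate(schedule: TrialSchedule, side: str, cfg: SynthConfig, n: int) -> np.ndarray:
    """Per-sample amplitude gate for the source on `side` ('C3'|'C4').

    Imagining the right hand attenuates the left-hemisphere (C3) source and
    vice versa, from cue onset through the feedback deadline.
    """
    gate = np.ones(n)
    attn_label = "right" if side == "C3" else "left"
    fs = cfg.sampling_rate
    for tr in schedule:
        if tr.label == attn_label:
            i0 = int(tr.cue_onset * fs)
            i1 = min(int(tr.feedback_deadline * fs), n)
            gate[i0:i1] = 1.0 - cfg.erd_depth
    return gate


def _pink_noise(rng, n_ch: int, n: int, fs: float) -> np.ndarray:
    """Per-channel 1/f (power) noise, unit variance per channel."""
    from scipy.fft import irfft, next_fast_len, rfft

    nfft = next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    scale = np.ones_like(freqs, dtype=np.float32)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz], dtype=np.float32)
    scale[0] = scale[1] if nfft > 1 else 1.0
    white = rng.standard_normal((n_ch, nfft), dtype=np.float32)
    spec = rfft(white, axis=1)
    spec *= scale[None, :]
    out = irfft(spec, nfft, axis=1)[:, :n]  # float32; upcast deferred to caller
    out /= out.std(axis=1, keepdims=True)
    return out


def _band_power_welch(x: np.ndarray, fs: float, band: tuple) -> float:
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), int(2 * fs)))
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


def generate_session(
    config: SynthConfig, layout: ElectrodeLayout
) -> tuple[ContinuousRecording, TrialSchedule]:
    """Simulate one continuous session for the channels of `layout`.

    Channel signal = sum over sources of Gaussian-gain-mixed rhythm waveforms
    plus spatially smoothed 1/f noise scaled so that the 8-26 Hz rhythm/noise
    power ratio at the C3 electrode equals ``config.snr``.
    """
    fs = config.sampling_rate
    schedule = make_schedule(config)
    n = int(round(config.n_trials * TRIAL_SLOT_S * fs))

    ss = np.random.SeedSequence([config.seed, 202])
    r_env3, r_env4, r_dist, r_noise, r_jit = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    sources, positions = [], []
    s3 = _source_waveform(r_env3, config, n) * _erd_gate(schedule, "C3", config, n)
    s4 = _source_waveform(r_env4, config, n) * _erd_gate(schedule, "C4", config, n)
    sources += [s3, s4]
    positions += [_SRC_POS["C3"], _SRC_POS["C4"]]
    if config.distractor:
        # occipital alpha, no task modulation
        dist_cfg = replace(config, beta_rel_amp=0.0)
        sd = _source_waveform(r_dist, dist_cfg, n) * config.distractor_amp
        sources.append(sd)
        positions.append(_SRC_POS["Oz"])

    # Gaussian volume-conduction gains: channels x sources
    pos = layout.positions
    gains = np.empty((len(layout), len(sources)))
    for j, sp in enumerate(positions):
        d2 = np.sum((pos - np.asarray(sp)) ** 2, axis=1)
        gains[:, j] = np.exp(-d2 / (2 * config.mixing_sigma**2))
    if config.session_gain_jitter > 0:
        gains *= np.exp(r_jit.normal(0, config.session_gain_jitter, gains.shape[0]))[:, None]

    rhythm = config.source_amp_uv * (gains @ np.asarray(sources))
    del sources

    noise = _pink_noise(r_noise, len(layout), n, fs)
    # spatial smoothing across channels, unit-row-norm to keep channel variance
    dch = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
    K = np.exp(-(dch**2) / (2 * config.noise_spatial_sigma**2))
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    noise = K.astype(np.float32) @ noise

    # calibrate noise amplitude: in-band rhythm/noise power ratio at C3 = snr
    try:
        i_c3 = layout.index("C3")
    except KeyError:
        i_c3 = 0
    probe = slice(0, min(n, int(120 * fs)))
    p_sig = _band_power_welch(rhythm[i_c3, probe], fs, (8.0, 26.0))
    p_noi = _band_power_welch(noise[i_c3, probe], fs, (8.0, 26.0))
    noise *= np.sqrt(p_sig / (config.snr * p_noi))

    samples = rhythm + noise
    del rhythm, noise

    markers = []
    for tr in schedule:
        markers.append((tr.rest_onset, "rest"))
        markers.append((tr.cue_onset, f"cue_{tr.label}"))
        markers.append((tr.feedback_onset, "feedback"))
    rec = ContinuousRecording(samples, fs, list(layout.names), markers)
    return rec, schedule


def inject_artifacts(
    recording: ContinuousRecording,
    schedule: TrialSchedule,
    config: SynthConfig,
) -> tuple[ContinuousRecording, list[int]]:
    """Add broadband bursts to the feedback period of randomly chosen trials.

    Burst amplitude is set per channel so the feedback-vs-rest-baseline Welch
    spectral deviation in 7-35 Hz exceeds ``config.artifact_db``.  Returns the
    modified recording and the ground-truth affected trial indices.
    """
    n_affected = int(round(config.artifact_rate * config.n_runs))
    if n_affected == 0:
        return recording, []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    idx = sorted(rng.choice(len(schedule), size=min(n_affected, len(schedule)), replace=False))

    fs = recording.sampling_rate
    # per-channel baseline: median rest-period PSD, max over 7-35 Hz
    rest_psds = []
    for tr in schedule:
        seg = recording.segment(tr.rest_onset, tr.cue_onset)
        f, p = sps.welch(seg, fs=fs, nperseg=int(fs), axis=1)
        rest_psds.append(p)
    base = np.median(np.asarray(rest_psds), axis=0)  # channels x freqs
    band = (f >= 7) & (f <= 35)
    b_max = base[:, band].max(axis=1)  # strongest baseline bin per channel

    samples = recording.samples.copy()
    # white-noise one-sided PSD = sigma^2 / (fs/2); +6 dB headroom over target
    target_psd = b_max * 10 ** ((config.artifact_db + 6.0) / 10.0)
    sigma = np.sqrt(target_psd * fs / 2.0)
    for i in idx:
        tr = schedule[i]
        i0 = int(tr.feedback_onset * fs)
        i1 = min(int(tr.feedback_deadline * fs), samples.shape[1])
        burst = rng.standard_normal((samples.shape[0], i1 - i0)) * sigma[:, None]
        burst *= sps.windows.tukey(i1 - i0, 0.1)[None, :]
        samples[:, i0:i1] += burst
    rec = ContinuousRecording(
        samples, fs, list(recording.channel_names), list(recording.markers)
    )
    return rec, [int(i) for i in idx]
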