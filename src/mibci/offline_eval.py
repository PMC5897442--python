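"""Offline evaluation suite.

Per-electrode r-squared topography of class discriminability, repeated
stratified cross-validation of the CSP+LDA decoder, CSP forward-model
spatial patterns, and run-by-run spatial-filter coefficient tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.model_selection import StratifiedKFold

from .decoders import CSPModel, class_covariance, csp_features, fit_csp, fit_lda
from .montage import ElectrodeLayout, large_laplacian_matrix
from .preproc import CONTROL_BAND, TrialEpoch, band_power

__all__ = [
    "RSquaredMap",
    "CVResult",
    "WeightTrace",
    "r_squared_map",
    "group_average_rsq",
    "cross_validate_csp",
    "spatial_patterns",
    "weight_variation",
    "write_rsq_map",
    "write_weight_trace",
]


@dataclass
class RSquaredMap:
    """Squared point-biserial correlation of band power with class, per electrode."""

    values: np.ndarray
    channel_names: list[str]
    band: tuple
    n_trials: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("r-squared values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def argmax_channel(self) -> str:
        return self.channel_names[int(np.argmax(self.values))]


@dataclass
class CVResult:
    accuracies: np.ndarray  # (repeats * folds,)
    folds: int
    repeats: int
    segment_s: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sem(self) -> float:
        a = np.asarray(self.accuracies)
        return float(a.std(ddof=1) / np.sqrt(len(a)))


@dataclass
class WeightTrace:
    values: np.ndarray  # per-run normalized coefficient at one electrode
    electrode: str
    dispersion: float   # std across runs


def r_squared_map(
    epochs: list[TrialEpoch],
    layout: ElectrodeLayout,
    band: tuple = CONTROL_BAND,
    log_power: bool = True,
) -> RSquaredMap:
    """r-squared topography from artifact-free trials.

    Each trial's feedback-period samples are large-Laplacian re-referenced,
    reduced to per-channel band power (log-transformed by default, a
    variance-stabilizing choice), and correlated with the binary class label.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    labels = np.array([ep.label for ep in epochs])
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    names = epochs[0].channel_names
    lap = large_laplacian_matrix(layout, names)
    powers = []
    for ep in epochs:
        seg = lap.weights @ ep.window(ep.feedback_onset, ep.feedback_end)
        powers.append(band_power(seg, ep.sampling_rate, band))
    p = np.asarray(powers)
    if log_power:
        p = np.log(np.maximum(p, 1e-300))
    y = (labels == "right").astype(float)
    y = y - y.mean()
    p = p - p.mean(axis=0)
    denom = np.sqrt((p**2).sum(axis=0) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (p.T @ y) / denom
    r = np.nan_to_num(r)
    return RSquaredMap(r**2, list(names), band, len(epochs))


def group_average_rsq(maps: list[RSquaredMap]) -> RSquaredMap:
    """Element-wise mean over subjects/sessions; trial counts are summed."""
    if not maps:
        raise ValueError("need at least one map")
    names = maps[0].channel_names
    for m in maps[1:]:
        if m.channel_names != names:
            raise ValueError("maps must share an identical channel set")
    vals = np.mean([m.values for m in maps], axis=0)
    return RSquaredMap(vals, list(names), maps[0].band, sum(m.n_trials for m in maps))


def _bandpass_epochs(epochs: list[TrialEpoch], low: float, high: float) -> list[TrialEpoch]:
    fs = epochs[0].sampling_rate
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    out = []
    for ep in epochs:
        filt = sps.sosfiltfilt(sos, ep.samples, axis=1)
        out.append(
            TrialEpoch(
                filt, fs, list(ep.channel_names), ep.label,
                ep.rest_onset, ep.cue_onset, ep.feedback_onset, ep.feedback_end,
                ep.outcome, ep.run, ep.trial,
            )
        )
    return out


def cross_validate_csp(
    epochs: list[TrialEpoch],
    folds: int = 5,
    repeats: int = 5,
    segment_s: float = 2.0,
    seed: int = 0,
    n_pairs: int = 3,
    assume_filtered: bool = False,
) -> CVResult:
    """Repeated stratified K-fold CV of the CSP+LDA decoder.

    CSP and LDA are fit on training folds only (no leakage); features come
    from the `segment_s` window right after cursor onset.  Epochs are
    zero-phase band-pass filtered to 8-26 Hz unless `assume_filtered`.
    """
    labels = np.array([ep.label for ep in epochs])
    counts = {c: int((labels == c).sum()) for c in set(labels.tolist())}
    if len(counts) < 2 or min(counts.values()) < folds:
        raise ValueError(f"need >= {folds} trials per class, got {counts}")
    if not assume_filtered:
        epochs = _bandpass_epochs(epochs, *CONTROL_BAND)
    segs = [
        (ep.feedback_onset, ep.feedback_onset + segment_s) for ep in epochs
    ]
    accs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(len(epochs)), labels):
            train = [epochs[i] for i in train_idx]
            cl = class_covariance(
                [ep for ep in train if ep.label == "left"],
                segment=None,
            )
            cr = class_covariance(
                [ep for ep in train if ep.label == "right"],
                segment=None,
            )
            csp = fit_csp(cl, cr, n_pairs, epochs[0].channel_names)
            feats_tr = np.array(
                [csp_features(epochs[i].window(*segs[i]), csp) for i in train_idx]
            )
            lda = fit_lda(feats_tr, labels[train_idx].tolist())
            correct = 0
            for i in test_idx:
                d = lda.decision(csp_features(epochs[i].window(*segs[i]), csp))
                pred = "right" if d > 0 else "left"
                correct += pred == labels[i]
            accs.append(correct / len(test_idx))
    return CVResult(np.asarray(accs), folds, repeats, segment_s)


def spatial_patterns(model: CSPModel) -> np.ndarray:
    """Column-normalized forward-model patterns A = (S_l + S_r) W^T."""
    a = np.asarray(model.patterns, float)
    norms = np.linalg.norm(a, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return a / norms


def weight_variation(
    models: list[CSPModel], electrode: str
) -> WeightTrace:
    """Run-by-run top-filter coefficient at one electrode, sign-aligned.

    CSP filters are sign-ambiguous, so each run's top filter is flipped to
    maximize correlation with the first run's before unit-normalization.
    The dispersion statistic is the standard deviation across runs.
    """
    if len(models) < 2:
        raise ValueError("need at least two run models")
    ref = None
    vals = []
    for m in models:
        if electrode not in m.channel_names:
            raise ValueError(f"electrode {electrode!r} absent from model montage")
        w = np.asarray(m.filters[0], float)
        w = w / np.linalg.norm(w)
        if ref is None:
            ref = w
        elif float(w @ ref) < 0:
            w = -w
        vals.append(w[m.channel_names.index(electrode)])
    vals = np.asarray(vals)
    return WeightTrace(vals, electrode, float(vals.std()))


def write_rsq_map(m: RSquaredMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tr_squared\n")
        for name, v in zip(m.channel_names, m.values):
            fh.write(f"{name}\t{v:.6f}\n")


def write_weight_trace(tr: WeightTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# electrode {tr.electrode}, dispersion {tr.dispersion:.6f}\n")
        fh.write("run\tcoefficient\n")
        for i, v in enumerate(tr.values):
            fh.write(f"{i}\t{v:.6f}\n")
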