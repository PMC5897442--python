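"""Trainable decoder cores for the three online pipelines.

CSP/L and CSP/S: 8-26 Hz Butterworth band-pass, common-spatial-pattern
filters from the generalized eigendecomposition of class covariances, log
variance of a 2-s sliding window as features, LDA with normalized output.

LAP/S: large-Laplacian C3/C4 derivations, Burg autoregressive alpha-beta
(8-26 Hz) band power, a fixed linear map (log-power difference C4-C3), and
an adaptive zero-mean/unit-variance output normalizer.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from statsmodels.regression.linear_model import burg as _burg

from .montage import LAPLACIAN_STENCILS, ElectrodeLayout, build_laplacian
from .preproc import TrialEpoch

__all__ = [
    "CSPModel",
    "LDAModel",
    "NormalizerState",
    "ARSpectrumConfig",
    "class_covariance",
    "fit_csp",
    "csp_features",
    "fit_lda",
    "ar_band_power",
    "lap_control_signal",
    "normalizer_update",
    "normalizer_apply",
    "retrain_batch",
    "CSPPipeline",
    "LapPipeline",
]

_VAR_EPS = 1e-12
TRAIN_SEGMENT_S = 2.0  # post-cursor-onset segment used to fit CSP+LDA


@dataclass
class ARSpectrumConfig:
    order: int = 16
    window_s: float = 0.5
    band: tuple = (8.0, 26.0)


@dataclass
class CSPModel:
    filters: np.ndarray       # (2*n_pairs, channels), rows are spatial filters
    patterns: np.ndarray      # (channels, 2*n_pairs), forward model columns
    eigenvalues: np.ndarray   # descending, in (0, 1)
    n_pairs: int
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.filters.shape[0] != 2 * self.n_pairs:
            raise ValueError("components must equal 2 * n_pairs")
        ev = np.asarray(self.eigenvalues)
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    def to_dict(self) -> dict:
        return {
            "kind": "csp",
            "version": 1,
            "filters": self.filters.tolist(),
            "patterns": self.patterns.tolist(),
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "n_pairs": self.n_pairs,
            "channel_names": list(self.channel_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CSPModel":
        if d.get("kind") != "csp" or d.get("version") != 1:
            raise ValueError("unsupported CSP model container version")
        return cls(
            np.asarray(d["filters"]),
            np.asarray(d["patterns"]),
            np.asarray(d["eigenvalues"]),
            int(d["n_pairs"]),
            list(d["channel_names"]),
        )


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    out_scale: float = 1.0   # training decision values have unit variance
    out_offset: float = 0.0

    def decision(self, x: np.ndarray) -> float:
        return float(self.weights @ np.asarray(x) + self.bias)

    def normalized(self, x: np.ndarray) -> float:
        """Decision value scaled to unit training variance; positive => right."""
        return (self.decision(x) - self.out_offset) * self.out_scale

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "version": 1,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "out_scale": self.out_scale,
            "out_offset": self.out_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        if d.get("kind") != "lda" or d.get("version") != 1:
            raise ValueError("unsupported LDA model container version")
        return cls(np.asarray(d["weights"]), float(d["bias"]),
                   float(d["out_scale"]), float(d["out_offset"]))


def class_covariance(
    epochs: list[TrialEpoch],
    segment: tuple[float, float] | None = None,
    shrinkage: float = 0.05,
) -> np.ndarray:
    """Mean trace-normalized per-trial covariance with diagonal loading.

    Each trial's spatial covariance is normalized to unit trace, averaged,
    then regularized as (1-lam)*S + lam*(trace(S)/n)*I.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    covs = []
    for ep in epochs:
        if segment is None:
            seg = (ep.feedback_onset, ep.feedback_onset + TRAIN_SEGMENT_S)
        else:
            seg = segment
        x = ep.window(*seg)
        x = x - x.mean(axis=1, keepdims=True)
        c = x @ x.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError(f"trial {ep.trial}: degenerate (zero-power) segment")
        covs.append(c / tr)
    s = np.mean(covs, axis=0)
    n = s.shape[0]
    s = (1.0 - shrinkage) * s + shrinkage * (np.trace(s) / n) * np.eye(n)
    try:
        sla.cholesky(s)
    except sla.LinAlgError:
        raise ValueError("class covariance rank-deficient after loading") from None
    return s


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Make each filter's largest-|weight| element positive (reproducibility)."""
    out = w.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_csp(
    cov_left: np.ndarray,
    cov_right: np.ndarray,
    n_pairs: int = 3,
    channel_names: list[str] | None = None,
) -> CSPModel:
    """CSP filters from the generalized eigenproblem S_left w = lam (S_left+S_right) w.

    Retains `n_pairs` filters from each end of the eigenvalue spectrum
    (largest: left-class variance maximized; smallest: right-class).  Filters
    satisfy W (S_left+S_right) W^T = I on the retained components; patterns
    are A = (S_left+S_right) W^T.
    """
    cov_left = np.asarray(cov_left, float)
    cov_right = np.asarray(cov_right, float)
    if cov_left.shape != cov_right.shape or cov_left.shape[0] != cov_left.shape[1]:
        raise ValueError("covariances must be square and same size")
    comp = cov_left + cov_right
    for m in (cov_left, cov_right):
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariances must be symmetric")
    try:
        evals, evecs = sla.eigh(cov_left, comp)  # ascending
    except sla.LinAlgError:
        raise ValueError("covariances must be positive definite") from None
    if 2 * n_pairs > len(evals):
        raise ValueError("n_pairs too large for channel count")
    order = np.argsort(evals)[::-1]
    keep = np.concatenate([order[:n_pairs], order[-n_pairs:]])
    w = evecs[:, keep].T  # rows are filters; w_i^T comp w_i = 1
    w = _fix_signs(w)
    ev = evals[keep]
    patterns = comp @ w.T
    names = channel_names if channel_names is not None else [
        f"ch{i}" for i in range(cov_left.shape[0])
    ]
    return CSPModel(w, patterns, ev, n_pairs, list(names))


def csp_features(window: np.ndarray, model: CSPModel, eps: float = _VAR_EPS) -> np.ndarray:
    """Log variance of each CSP-projected component over the window."""
    proj = model.filters @ np.atleast_2d(window)
    v = proj.var(axis=1)
    return np.log(np.maximum(v, eps))


def fit_lda(
    features: np.ndarray, labels: list[str], shrinkage: float = 0.05
) -> LDAModel:
    """Pooled-covariance LDA: w ~ S^-1 (mu_right - mu_left), midpoint bias,
    output scaled to unit variance on the training decisions."""
    x = np.asarray(features, float)
    y = np.asarray(labels)
    classes = set(y.tolist())
    if classes != {"left", "right"}:
        raise ValueError(f"need both classes, got {sorted(classes)}")
    xl, xr = x[y == "left"], x[y == "right"]
    mul, mur = xl.mean(axis=0), xr.mean(axis=0)
    resid = np.vstack([xl - mul, xr - mur])
    pooled = resid.T @ resid / max(len(x) - 2, 1)
    n = pooled.shape[0]
    pooled = (1 - shrinkage) * pooled + shrinkage * (np.trace(pooled) / n) * np.eye(n)
    w = sla.solve(pooled, mur - mul, assume_a="pos")
    bias = -float(w @ (mul + mur) / 2.0)
    d = x @ w + bias
    sd = float(d.std())
    return LDAModel(w, bias, out_scale=1.0 / sd if sd > 0 else 1.0, out_offset=0.0)


def _ar_psd(ar: np.ndarray, sigma2: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided AR spectral density at `freqs`."""
    k = np.arange(1, len(ar) + 1)
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 - z @ ar) ** 2
    return 2.0 * sigma2 / fs / denom


def ar_band_power(
    window: np.ndarray, config: ARSpectrumConfig, sampling_rate: float
) -> float:
    """Burg AR spectrum of a single-channel window, integrated over the band.

    A constant (zero-variance) window yields 0.0 by convention.
    """
    x = np.asarray(window, float).ravel()
    if len(x) <= config.order:
        raise ValueError("window must be longer than the AR order")
    if np.ptp(x) == 0:
        return 0.0
    ar, sigma2 = _burg(x, order=config.order, demean=True)
    freqs = np.arange(config.band[0], config.band[1] + 1e-9, 0.25)
    psd = _ar_psd(ar, sigma2, sampling_rate, freqs)
    return float(np.trapezoid(psd, freqs))


def lap_control_signal(
    power_c3: float, power_c4: float,
    w_c3: float = 1.0, w_c4: float = 1.0,
    eps: float = _VAR_EPS,
) -> float:
    """Linear map of Laplacian-channel log band powers to a raw control value.

    Right-hand imagery desynchronizes C3, lowering its band power, so
    log(P_C4) - log(P_C3) is positive => rightward cursor drive.
    """
    if power_c3 < 0 or power_c4 < 0:
        raise ValueError("band powers must be non-negative")
    return w_c4 * np.log(max(power_c4, eps)) - w_c3 * np.log(max(power_c3, eps))


@dataclass
class NormalizerState:
    """Running zero-mean/unit-variance transform over a trailing horizon."""

    horizon_s: float = 30.0
    block_s: float = 0.1
    values: deque = field(default_factory=deque)
    var_floor: float = 1e-12

    def __post_init__(self) -> None:
        maxlen = max(int(round(self.horizon_s / self.block_s)), 2)
        self.values = deque(self.values, maxlen=maxlen)

    @property
    def count(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else 0.0

    @property
    def variance(self) -> float:
        return float(np.var(self.values)) if len(self.values) >= 2 else 0.0

    def to_dict(self) -> dict:
        return {
            "kind": "normalizer",
            "version": 1,
            "horizon_s": self.horizon_s,
            "block_s": self.block_s,
            "values": list(self.values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizerState":
        if d.get("kind") != "normalizer" or d.get("version") != 1:
            raise ValueError("unsupported normalizer container version")
        return cls(float(d["horizon_s"]), float(d["block_s"]), deque(d["values"]))


def normalizer_update(state: NormalizerState, value: float) -> NormalizerState:
    state.values.append(float(value))
    return state


def normalizer_apply(state: NormalizerState, value: float) -> float:
    """(value - mean) / sqrt(variance); unit-variance fallback when degenerate."""
    if state.count == 0:
        return 0.0
    var = state.variance
    if var < state.var_floor:
        return 0.0
    return (float(value) - state.mean) / np.sqrt(var)


class CSPPipeline:
    """CSP + LDA decoder over a fixed montage (large or small).

    Operates on causally band-pass-filtered signals; features are the log
    variances of the 2-s trailing window projected through the CSP filters.
    """

    def __init__(
        self,
        channel_names: list[str],
        n_pairs: int = 3,
        window_s: float = 2.0,
        shrinkage: float = 0.05,
        lda_shrinkage: float = 0.05,
    ) -> None:
        self.channel_names = list(channel_names)
        self.n_pairs = n_pairs
        self.window_s = window_s
        self.shrinkage = shrinkage
        self.lda_shrinkage = lda_shrinkage
        self.csp: CSPModel | None = None
        self.lda: LDAModel | None = None

    @property
    def is_fitted(self) -> bool:
        return self.csp is not None

    def fit(self, epochs: list[TrialEpoch]) -> "CSPPipeline":
        """Fit CSP and LDA on the 2-s post-cursor-onset segments."""
        left = [ep for ep in epochs if ep.label == "left"]
        right = [ep for ep in epochs if ep.label == "right"]
        if not left or not right:
            raise ValueError("training epochs must contain both classes")
        cl = class_covariance(left, shrinkage=self.shrinkage)
        cr = class_covariance(right, shrinkage=self.shrinkage)
        self.csp = fit_csp(cl, cr, self.n_pairs, self.channel_names)
        feats = np.array([
            csp_features(
                ep.window(ep.feedback_onset, ep.feedback_onset + TRAIN_SEGMENT_S),
                self.csp,
            )
            for ep in epochs
        ])
        self.lda = fit_lda(feats, [ep.label for ep in epochs], self.lda_shrinkage)
        return self

    def control(self, window: np.ndarray) -> float:
        """Normalized control value from a trailing window; positive => right."""
        if not self.is_fitted:
            raise RuntimeError("pipeline not fitted")
        return self.lda.normalized(csp_features(window, self.csp))

    def snapshot(self) -> dict:
        return {
            "kind": "csp_pipeline",
            "version": 1,
            "channel_names": self.channel_names,
            "n_pairs": self.n_pairs,
            "csp": self.csp.to_dict() if self.csp else None,
            "lda": self.lda.to_dict() if self.lda else None,
        }

    @classmethod
    def from_snapshot(cls, d: dict) -> "CSPPipeline":
        if d.get("kind") != "csp_pipeline" or d.get("version") != 1:
            raise ValueError("unsupported pipeline container version")
        p = cls(d["channel_names"], n_pairs=int(d["n_pairs"]))
        if d["csp"]:
            p.csp = CSPModel.from_dict(d["csp"])
            p.lda = LDAModel.from_dict(d["lda"])
        return p


class LapPipeline:
    """Large-Laplacian C3/C4 + Burg AR band power + fixed linear map.

    The raw control value is the C4-C3 log band-power difference; the
    adaptive normalizer turning it into a z-valued velocity command lives in
    the closed-loop layer (it is session state, not a trained model).
    """

    def __init__(
        self,
        layout: ElectrodeLayout,
        ar_config: ARSpectrumConfig | None = None,
        weights: tuple[float, float] = (1.0, 1.0),
    ) -> None:
        self.ar_config = ar_config or ARSpectrumConfig()
        self.weights = weights
        self.lap_c3 = build_laplacian(layout, "C3", LAPLACIAN_STENCILS["C3"])
        self.lap_c4 = build_laplacian(layout, "C4", LAPLACIAN_STENCILS["C4"])
        self.window_s = self.ar_config.window_s

    def control_raw(self, window: np.ndarray, channel_names: list[str],
                    sampling_rate: float) -> float:
        """Raw (un-normalized) control value from a trailing window."""
        c3 = self.lap_c3.apply(window, channel_names)[0]
        c4 = self.lap_c4.apply(window, channel_names)[0]
        p3 = ar_band_power(c3, self.ar_config, sampling_rate)
        p4 = ar_band_power(c4, self.ar_config, sampling_rate)
        return lap_control_signal(p3, p4, *self.weights)


def retrain_batch(
    history: list[TrialEpoch], run_index: int, pipeline: CSPPipeline
) -> CSPPipeline:
    """Batch-mode adaptation before run `run_index` (1-based).

    Before run 2 the decoder is trained on run 1 only (25 trials); before run
    r >= 3 on runs r-2 and r-1 (50 trials).
    """
    if run_index < 2:
        raise ValueError("retraining is defined from run 2 onward")
    upcoming = run_index - 1  # 0-based
    runs = {upcoming - 1} if upcoming == 1 else {upcoming - 2, upcoming - 1}
    train = [ep for ep in history if ep.run in runs]
    if not train:
        raise ValueError(f"no history for runs {sorted(runs)}")
    fresh = CSPPipeline(
        pipeline.channel_names,
        n_pairs=pipeline.n_pairs,
        window_s=pipeline.window_s,
        shrinkage=pipeline.shrinkage,
        lda_shrinkage=pipeline.lda_shrinkage,
    )
    return fresh.fit(train)
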