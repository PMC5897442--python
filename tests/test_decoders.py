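import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mibci.decoders import (
    ARSpectrumConfig,
    CSPModel,
    CSPPipeline,
    LDAModel,
    NormalizerState,
    ar_band_power,
    class_covariance,
    csp_features,
    fit_csp,
    fit_lda,
    lap_control_signal,
    normalizer_apply,
    normalizer_update,
    retrain_batch,
)
from mibci.preproc import TrialEpoch, epoch


def _epoch_from(x, fs=250.0, label="left", run=0, trial=0):
    names = [f"ch{i}" for i in range(x.shape[0])]
    dur = x.shape[1] / fs
    return TrialEpoch(x, fs, names, label, 0.0, 0.0, 0.0, min(dur, 6.0),
                      run=run, trial=trial)


def _random_spd(rng, n):
    a = rng.normal(size=(n, n))
    return a @ a.T + n * np.eye(n)


class TestClassCovariance:
    def test_single_epoch_trace_normalized(self, rng):
        x = rng.normal(size=(4, 500))
        ep = _epoch_from(x)
        c = class_covariance([ep], segment=(0.0, 2.0), shrinkage=0.0)
        assert np.trace(c) == pytest.approx(1.0)
        xc = x - x.mean(1, keepdims=True)
        raw = xc @ xc.T
        assert np.allclose(c, raw / np.trace(raw))

    def test_full_shrinkage_gives_scaled_identity(self, rng):
        ep = _epoch_from(rng.normal(size=(4, 500)))
        c = class_covariance([ep], segment=(0.0, 2.0), shrinkage=1.0)
        assert np.allclose(c, np.eye(4) / 4)

    def test_two_epochs_average(self, rng):
        e1 = _epoch_from(rng.normal(size=(3, 500)))
        e2 = _epoch_from(rng.normal(size=(3, 500)) * 3)
        c12 = class_covariance([e1, e2], segment=(0.0, 2.0), shrinkage=0.0)
        c1 = class_covariance([e1], segment=(0.0, 2.0), shrinkage=0.0)
        c2 = class_covariance([e2], segment=(0.0, 2.0), shrinkage=0.0)
        assert np.allclose(c12, (c1 + c2) / 2)

    def test_degenerate_segment_rejected(self):
        ep = _epoch_from(np.zeros((3, 500)))
        with pytest.raises(ValueError):
            class_covariance([ep], segment=(0.0, 2.0))


def _brute_force_top_filter(cov_l, cov_r, n_grid=200_000):
    """Rayleigh-quotient maximization over a fine angular grid (2-D only)."""
    ang = np.linspace(0, np.pi, n_grid, endpoint=False)
    w = np.c_[np.cos(ang), np.sin(ang)]
    num = np.einsum("ij,jk,ik->i", w, cov_l, w)
    den = np.einsum("ij,jk,ik->i", w, cov_l + cov_r, w)
    q = num / den
    return w[np.argmax(q)], q.max()


class TestFitCsp:
    def test_equal_covariances_give_half_eigenvalues(self):
        m = fit_csp(np.eye(3), np.eye(3), n_pairs=1)
        assert np.allclose(m.eigenvalues, 0.5)

    def test_diagonal_toy_matches_analytic(self):
        m = fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), n_pairs=1)
        assert m.eigenvalues[0] == pytest.approx(0.8)
        assert m.eigenvalues[1] == pytest.approx(0.2)
        top = m.filters[0] / np.linalg.norm(m.filters[0])
        assert abs(top @ [1, 0]) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_top_filter_matches_brute_force_grid(self, seed):
        """Generalized eigendecomposition vs Rayleigh-quotient grid search."""
        rng = np.random.default_rng(seed)
        cl, cr = _random_spd(rng, 2), _random_spd(rng, 2)
        m = fit_csp(cl, cr, n_pairs=1)
        w_bf, q_bf = _brute_force_top_filter(cl, cr)
        w = m.filters[0] / np.linalg.norm(m.filters[0])
        angle = np.degrees(np.arccos(np.clip(abs(w @ w_bf), 0, 1)))
        assert angle < 1.0
        assert m.eigenvalues[0] == pytest.approx(q_bf, abs=1e-6)

    def test_eigenvalue_pairing_under_class_exchange(self, rng):
        cl, cr = _random_spd(rng, 5), _random_spd(rng, 5)
        m1 = fit_csp(cl, cr, n_pairs=2)
        m2 = fit_csp(cr, cl, n_pairs=2)
        assert np.allclose(np.sort(m1.eigenvalues), np.sort(1 - m2.eigenvalues))
        assert np.all((m1.eigenvalues > 0) & (m1.eigenvalues < 1))

    def test_whitening_constraint(self, rng):
        cl, cr = _random_spd(rng, 6), _random_spd(rng, 6)
        m = fit_csp(cl, cr, n_pairs=3)
        assert np.allclose(m.filters @ (cl + cr) @ m.filters.T, np.eye(6), atol=1e-8)
        # patterns invert filters on the retained subspace
        assert np.allclose(m.filters @ m.patterns, np.eye(6), atol=1e-8)

    def test_channel_permutation_equivariance(self, rng):
        cl, cr = _random_spd(rng, 4), _random_spd(rng, 4)
        perm = [2, 0, 3, 1]
        p = np.eye(4)[perm]
        m = fit_csp(cl, cr, n_pairs=1)
        mp = fit_csp(p @ cl @ p.T, p @ cr @ p.T, n_pairs=1)
        assert np.allclose(np.abs(mp.filters), np.abs(m.filters @ p.T), atol=1e-8)

    def test_asymmetric_input_rejected(self, rng):
        bad = rng.normal(size=(3, 3))
        with pytest.raises(ValueError):
            fit_csp(bad, np.eye(3))


class TestCspFeatures:
    def test_feature_count_is_twice_pairs(self, rng):
        cl, cr = _random_spd(rng, 8), _random_spd(rng, 8)
        m = fit_csp(cl, cr, n_pairs=3)
        f = csp_features(rng.normal(size=(8, 500)), m)
        assert f.shape == (6,)

    def test_window_scaling_shifts_log_features(self, rng):
        cl, cr = _random_spd(rng, 4), _random_spd(rng, 4)
        m = fit_csp(cl, cr, n_pairs=2)
        x = rng.normal(size=(4, 500))
        c = 3.7
        assert np.allclose(csp_features(c * x, m),
                           csp_features(x, m) + 2 * np.log(c), atol=1e-9)

    def test_zero_window_floored(self, rng):
        m = fit_csp(_random_spd(rng, 4), _random_spd(rng, 4), n_pairs=2)
        f = csp_features(np.zeros((4, 500)), m)
        assert np.all(f == np.log(1e-12))


class TestFitLda:
    def test_symmetric_classes_boundary_at_zero(self, rng):
        # exactly mirrored samples: the midpoint bias must put the boundary at 0
        xl = rng.normal(-2, 1, (200, 1))
        x = np.r_[xl, -xl]
        y = ["left"] * 200 + ["right"] * 200
        m = fit_lda(x, y)
        assert m.decision([0.0]) == pytest.approx(0.0, abs=1e-9)
        assert m.decision([2.0]) > 0  # positive => right

    def test_label_flip_negates_weights(self, rng):
        x = rng.normal(size=(60, 3))
        y = ["left"] * 30 + ["right"] * 30
        m1 = fit_lda(x, y)
        m2 = fit_lda(x, [{"left": "right", "right": "left"}[l] for l in y])
        assert np.allclose(m1.weights, -m2.weights)

    def test_unit_variance_training_decisions(self, rng):
        x = rng.normal(size=(100, 4)) + np.r_[[[1, 0, 0, 0]] * 50, [[-1, 0, 0, 0]] * 50]
        y = ["right"] * 50 + ["left"] * 50
        m = fit_lda(x, y)
        d = np.array([m.normalized(row) for row in x])
        assert d.std() == pytest.approx(1.0, rel=1e-6)

    def test_duplicated_feature_matches_reduced_problem(self, rng):
        """Shrinkage keeps duplicated columns from changing decisions."""
        x = np.r_[rng.normal(-1, 1, (100, 1)), rng.normal(1, 1, (100, 1))]
        y = ["left"] * 100 + ["right"] * 100
        m1 = fit_lda(x, y, shrinkage=0.05)
        m2 = fit_lda(np.hstack([x, x]), y, shrinkage=0.05)
        d1 = np.sign([m1.decision(r) for r in x])
        d2 = np.sign([m2.decision(r) for r in np.hstack([x, x])])
        assert np.array_equal(d1, d2)

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x = np.r_[rng.normal(-1, 1, (80, 3)), rng.normal(1, 1, (80, 3))]
        y = ["left"] * 80 + ["right"] * 80
        ours = fit_lda(x, y, shrinkage=0.0)
        ref = LinearDiscriminantAnalysis().fit(x, y)
        pred_ours = ["right" if ours.decision(r) > 0 else "left" for r in x]
        assert np.mean(np.array(pred_ours) == ref.predict(x)) > 0.98

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lda(rng.normal(size=(10, 2)), ["left"] * 10)


class TestArBandPower:
    FS = 250.0
    CFG = ARSpectrumConfig()

    def _window(self, freq, rng, n=125, noise=0.05):
        t = np.arange(n) / self.FS
        return np.sin(2 * np.pi * freq * t) + noise * rng.normal(size=n)

    def test_sinusoid_power_concentrates_in_band(self, rng):
        """Cross-check against an FFT periodogram on the same window."""
        x = self._window(10.0, rng)
        in_band = ar_band_power(x, self.CFG, self.FS)
        total = ar_band_power(x, ARSpectrumConfig(band=(0.5, 124.0)), self.FS)
        assert in_band / total >= 0.8
        # FFT periodogram agrees on the concentration
        from scipy.signal import periodogram

        f, p = periodogram(x, fs=self.FS)
        m = (f >= 8) & (f <= 26)
        assert np.trapezoid(p[m], f[m]) / np.trapezoid(p, f) >= 0.8

    def test_white_noise_band_fraction(self):
        """Flat-spectrum oracle: band power ~ bandwidth / Nyquist x total."""
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(150):
            x = rng.normal(size=125)
            bp = ar_band_power(x, self.CFG, self.FS)
            tot = ar_band_power(x, ARSpectrumConfig(band=(0.0, 125.0)), self.FS)
            fracs.append(bp / tot)
        assert np.mean(fracs) == pytest.approx(18.0 / 125.0, rel=0.15)

    def test_quadratic_scaling(self, rng):
        x = self._window(12.0, rng)
        assert ar_band_power(2 * x, self.CFG, self.FS) == pytest.approx(
            4 * ar_band_power(x, self.CFG, self.FS), rel=0.05)

    def test_constant_window_gives_zero(self):
        assert ar_band_power(np.ones(125), self.CFG, self.FS) == 0.0

    def test_window_shorter_than_order_rejected(self):
        with pytest.raises(ValueError):
            ar_band_power(np.zeros(10), self.CFG, self.FS)


class TestLapControl:
    def test_equal_powers_zero(self):
        assert lap_control_signal(3.3, 3.3) == pytest.approx(0.0)

    def test_right_erd_drives_right(self):
        assert lap_control_signal(0.5, 1.0) > lap_control_signal(1.0, 1.0)
        assert lap_control_signal(0.5, 1.0) > 0

    @settings(deadline=None)
    @given(p3=st.floats(1e-6, 1e6), p4=st.floats(1e-6, 1e6))
    def test_antisymmetric_under_swap(self, p3, p4):
        assert lap_control_signal(p3, p4) == pytest.approx(
            -lap_control_signal(p4, p3), abs=1e-9)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            lap_control_signal(-1.0, 1.0)


class TestNormalizer:
    def test_stationary_stream_converges_to_z(self):
        # consecutive outputs share the trailing buffer, so the tail must be
        # several horizons long for its mean to estimate the converged level
        rng = np.random.default_rng(8)
        state = NormalizerState()
        out = []
        for v in rng.normal(5.0, 2.0, 5000):
            out.append(normalizer_apply(state, v))
            normalizer_update(state, v)
        tail = np.array(out[-1000:])
        assert abs(tail.mean()) < 0.1
        assert 0.8 <= tail.var() <= 1.25

    def test_constant_stream_returns_zero(self):
        state = NormalizerState()
        for _ in range(10):
            normalizer_update(state, 4.2)
        assert normalizer_apply(state, 4.2) == 0.0

    def test_location_invariance(self):
        rng = np.random.default_rng(9)
        stream = rng.normal(size=500)
        outs = []
        for c in (0.0, 17.3):
            state = NormalizerState()
            o = []
            for v in stream + c:
                o.append(normalizer_apply(state, v))
                normalizer_update(state, v)
            outs.append(np.array(o[-100:]))
        assert np.allclose(outs[0], outs[1], atol=1e-9)

    def test_horizon_bounds_buffer(self):
        state = NormalizerState(horizon_s=1.0, block_s=0.1)
        for v in range(100):
            normalizer_update(state, float(v))
        assert state.count == 10


@pytest.fixture(scope="module")
def history(small_layout):
    from mibci.preproc import bandpass
    from mibci.synthgen import SynthConfig, generate_session

    cfg = SynthConfig(n_runs=3, trials_per_run=25, erd_depth=0.8, snr=5.0, seed=77)
    rec, sch = generate_session(cfg, small_layout)
    return epoch(bandpass(rec, causal=True), sch)


class TestRetrainBatch:
    def test_before_run2_trains_on_25(self, history):
        pipe = CSPPipeline(history[0].channel_names)
        trained = retrain_batch([ep for ep in history if ep.run < 1], 2, pipe)
        assert trained.is_fitted
        # training pool was exactly run 1's 25 trials
        assert len([ep for ep in history if ep.run == 0]) == 25

    def test_before_run3_trains_on_50(self, history):
        pipe = CSPPipeline(history[0].channel_names)
        pool = [ep for ep in history if ep.run < 2]
        assert len(pool) == 50
        trained = retrain_batch(pool, 3, pipe)
        assert trained.is_fitted

    def test_deterministic(self, history):
        pipe = CSPPipeline(history[0].channel_names)
        m1 = retrain_batch(history, 3, pipe)
        m2 = retrain_batch(history, 3, pipe)
        assert np.array_equal(m1.csp.filters, m2.csp.filters)
        assert np.array_equal(m1.lda.weights, m2.lda.weights)

    def test_too_early_rejected(self, history):
        with pytest.raises(ValueError):
            retrain_batch(history, 1, CSPPipeline(history[0].channel_names))


class TestSerialization:
    def test_csp_pipeline_snapshot_roundtrip(self, rng):
        cl, cr = _random_spd(rng, 5), _random_spd(rng, 5)
        pipe = CSPPipeline([f"ch{i}" for i in range(5)], n_pairs=2)
        pipe.csp = fit_csp(cl, cr, 2, pipe.channel_names)
        pipe.lda = LDAModel(np.array([1.0, -1.0, 0.5, 0.0]), 0.1, 2.0, 0.0)
        back = CSPPipeline.from_snapshot(pipe.snapshot())
        assert np.allclose(back.csp.filters, pipe.csp.filters)
        assert np.allclose(back.lda.weights, pipe.lda.weights)
        assert back.csp.channel_names == pipe.csp.channel_names

    def test_version_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CSPModel.from_dict({"kind": "csp", "version": 99})

    def test_normalizer_roundtrip(self):
        s = NormalizerState()
        for v in [1.0, 2.0, 3.0]:
            normalizer_update(s, v)
        back = NormalizerState.from_dict(s.to_dict())
        assert list(back.values) == [1.0, 2.0, 3.0]
        assert back.horizon_s == s.horizon_s
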