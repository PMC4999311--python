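"""Raised-cosine basis, design construction, Bernoulli GLM fitting, STA."""

import numpy as np
import pytest

import whiskerglm as wg
from whiskerglm.glm import DesignMatrix, sigmoid
from whiskerglm.predictors import PREDICTOR_NAMES, PredictorSet


class TestBasis:
    def test_default_peaks_and_support(self, basis):
        np.testing.assert_array_equal(np.argmax(basis.functions, axis=1), [0, 1, 3, 8, 17])
        assert basis.support_ms == 75
        assert basis.functions[-1, 75] == 0.0

    def test_bounded_in_unit_interval(self, basis):
        assert basis.functions.min() >= 0.0
        assert basis.functions.max() <= 1.0 + 1e-12

    def test_single_bump(self):
        b = wg.make_basis(1, (0.0,), 20)
        assert b.functions[0, 0] == pytest.approx(1.0)
        assert np.argmax(b.functions[0]) == 0

    def test_invalid_peaks_error(self):
        with pytest.raises(ValueError):
            wg.make_basis(3, (0.0, 5.0, 3.0), 75)
        with pytest.raises(ValueError):
            wg.make_basis(2, (0.0, 80.0), 75)


def _noise_set(n, seed=0):
    rng = np.random.default_rng(seed)
    return PredictorSet(
        t_ms=np.arange(n, dtype=float),
        values=rng.standard_normal((n, 6)),
        contact=np.ones(n, dtype=bool),
    )


class TestDesign:
    def test_column_counts(self, basis):
        ps = _noise_set(5000)
        assert wg.build_design(ps, basis, "full").X.shape[1] == 31
        assert wg.build_design(ps, basis, "mechanical").X.shape[1] == 16
        assert wg.build_design(ps, basis, "kinematic").X.shape[1] == 16

    def test_impulse_convolution_identity(self, basis):
        n = 400
        vals = np.zeros((n, 6))
        t0 = 200
        vals[t0, 2] = 1.0  # impulse on M
        # other predictors need variance for whitening; fill with noise
        rng = np.random.default_rng(1)
        for j in [0, 1, 3, 4, 5]:
            vals[:, j] = rng.standard_normal(n)
        ps = PredictorSet(np.arange(n, dtype=float), vals, np.ones(n, bool))
        d = wg.build_design(ps, basis, "full")
        j = 2  # M
        sd = vals[:, 2].std()
        for l in range(5):
            col = d.X[:, 1 + j * 5 + l]
            # past the kernel ramp-in, whitening adds a constant offset
            # (col[t0-1]); above it the column is b_l(t - t0) / sd
            seg = (col[t0:t0 + 76] - col[t0 - 1]) * sd
            np.testing.assert_allclose(seg, basis.functions[l], atol=1e-9)

    def test_zero_variance_predictor_errors(self, basis):
        ps = _noise_set(1000)
        ps.values[:, 0] = 5.0
        with pytest.raises(ValueError, match="Fx"):
            wg.build_design(ps, basis, "full")


class TestFit:
    def test_sigmoid_midpoint(self):
        assert sigmoid(0.0) == pytest.approx(0.5)

    def test_intercept_only_mle_is_logit_mean_rate(self, basis):
        rng = np.random.default_rng(2)
        y = (rng.random(20000) < 0.03).astype(np.uint8)
        d = DesignMatrix(
            X=np.ones((y.size, 1)), predictor_names=(), basis=basis,
            whiten_mean=np.zeros(0), whiten_sd=np.ones(0),
            contact=np.ones(y.size, bool),
        )
        f = wg.fit(d, y, ridge=0.0)
        assert f.coef[0] == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)

    def test_zero_coefficients_predict_half(self, basis):
        ps = _noise_set(500)
        d = wg.build_design(ps, basis, "full")
        f = wg.fit(d, (np.random.default_rng(0).random(500) < 0.2).astype(np.uint8))
        f.coef[:] = 0.0
        np.testing.assert_allclose(wg.predict(f, d), 0.5)

    def test_saturated_negative_intercept(self, basis):
        ps = _noise_set(500)
        d = wg.build_design(ps, basis, "full")
        f = wg.fit(d, np.ones(500, dtype=np.uint8) * (np.arange(500) % 7 == 0))
        f.coef[:] = 0.0
        f.coef[0] = -30.0
        assert wg.predict(f, d).max() < 1e-12

    def test_basis_and_filter_space_predictions_identical(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.5, 0.3, 0.1, 0.05, 0.0]}, bias=-3.0, seed=1)
        y = wg.simulate_spikes(neuron, noise_predictors)
        d = wg.build_design(noise_predictors, basis, "full")
        f = wg.fit(d, y)
        p_basis = wg.predict(f, d)
        p_filter = wg.predict_from_filters(f, noise_predictors)
        assert np.abs(p_basis - p_filter).max() < 1e-10

    def test_filter_recovery_from_simulation(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.8, 0.5, 0.25, 0.1, 0.05],
                    "theta": [-0.4, 0.3, 0.15, -0.05, 0.02]},
            bias=np.log(0.05 / 0.95), seed=11)
        y = wg.simulate_spikes(neuron, noise_predictors)
        d = wg.build_design(noise_predictors, basis, "full")
        f = wg.fit(d, y)
        filters = f.filters()
        for name in ("M", "theta"):
            c = np.corrcoef(filters[name], neuron.filters[name])[0, 1]
            assert c > 0.9

    def test_refits_agree_from_different_inits(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.5, 0.3, 0.1, 0.0, 0.0]}, bias=-3.0, seed=2)
        y = wg.simulate_spikes(neuron, noise_predictors)
        d = wg.build_design(noise_predictors, basis, "mechanical")
        f1 = wg.fit(d, y)
        f2 = wg.fit(d, y, init=np.full(d.X.shape[1], 0.3))
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, rel=1e-6)

    def test_filter_reconstruction_is_exact_basis_expansion(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.5, 0.3, 0.1, 0.0, 0.0]}, bias=-3.0, seed=3)
        y = wg.simulate_spikes(neuron, noise_predictors)
        d = wg.build_design(noise_predictors, basis, "mechanical")
        f = wg.fit(d, y)
        alpha = f.filters()["M"]
        j = f.predictor_names.index("M")
        manual = basis.functions.T @ f.beta[:, j]
        np.testing.assert_allclose(alpha, manual, atol=1e-14)

    def test_no_spikes_errors(self, basis):
        ps = _noise_set(500)
        d = wg.build_design(ps, basis, "full")
        with pytest.raises(ValueError):
            wg.fit(d, np.zeros(500, dtype=np.uint8))

    def test_column_mismatch_errors(self, basis):
        ps = _noise_set(500)
        d_full = wg.build_design(ps, basis, "full")
        d_mech = wg.build_design(ps, basis, "mechanical")
        y = (np.arange(500) % 9 == 0).astype(np.uint8)
        f = wg.fit(d_mech, y)
        with pytest.raises(ValueError):
            wg.predict(f, d_full)


class TestCrossval:
    def test_partition_property(self, basis):
        ps = _noise_set(10_000)
        d = wg.build_design(ps, basis, "full")
        rng = np.random.default_rng(5)
        y = (rng.random(10_000) < 0.05).astype(np.uint8)
        p1, fits = wg.crossval(d, y, k=10)
        assert len(fits) == 10
        assert np.all(np.isfinite(p1))  # every bin predicted exactly once
        p2, _ = wg.crossval(d, y, k=10)
        np.testing.assert_array_equal(p1, p2)  # deterministic fold layout

    def test_out_of_fold_ll_close_to_in_sample(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.6, 0.4, 0.2, 0.1, 0.0]}, bias=np.log(0.04 / 0.96), seed=6)
        y = wg.simulate_spikes(neuron, noise_predictors).astype(float)
        d = wg.build_design(noise_predictors, basis, "full")
        p_oof, _ = wg.crossval(d, y, k=10)
        f = wg.fit(d, y)
        p_in = wg.predict(f, d)

        def ll(p):
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        assert ll(p_oof) == pytest.approx(ll(p_in), rel=0.05)


class TestSTA:
    def test_single_spike_sta_is_raw_segment(self, basis):
        ps = _noise_set(500, seed=9)
        st = wg.bin_spikes([300.0], 500.0)
        sta = wg.compute_sta(ps, st, window_ms=50)
        for j, name in enumerate(PREDICTOR_NAMES):
            np.testing.assert_allclose(sta[name][0], ps.values[250:301, j])

    def test_null_sta_for_independent_spikes(self, basis):
        ps = _noise_set(50_000, seed=10)
        rng = np.random.default_rng(12)
        st = wg.bin_spikes(np.sort(rng.uniform(100, 49_900, 800)), 50_000.0)
        sta = wg.compute_sta(ps, st, window_ms=50)
        for name in PREDICTOR_NAMES:
            mean, sem = sta[name]
            assert np.all(np.abs(mean) < 4 * sem + 1e-12)

    def test_driven_predictor_has_structured_sta(self, basis, noise_predictors):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.9, 0.5, 0.2, 0.0, 0.0]}, bias=np.log(0.03 / 0.97), seed=13)
        y = wg.simulate_spikes(neuron, noise_predictors)
        st = wg.bin_spikes(np.flatnonzero(y).astype(float), float(y.size))
        sta = wg.compute_sta(noise_predictors, st, window_ms=50)
        m_mean, m_sem = sta["M"]
        fx_mean, fx_sem = sta["Fx"]
        # center on each channel's trial mean: the AR(1) channels carry a
        # small common offset that the per-spike SEM does not account for
        m_z = np.abs((m_mean - noise_predictors.column("M").mean()) / m_sem)
        fx_z = np.abs((fx_mean - noise_predictors.column("Fx").mean()) / fx_sem)
        assert m_z.max() > 5       # strong pre-spike structure on the driver
        assert fx_z.max() < 6      # undriven channel stays null

    def test_no_spikes_errors(self):
        ps = _noise_set(500)
        st = wg.bin_spikes([], 500.0)
        with pytest.raises(ValueError):
            wg.compute_sta(ps, st, 50)
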