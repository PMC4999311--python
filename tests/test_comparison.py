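"""Comparison metrics, aggregation rules, and population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import whiskerglm as wg
from whiskerglm.comparison import ComparisonResult, UndefinedCorrelation, population_stats


class TestPearsonContact:
    def test_perfect_and_anti_correlation(self):
        x = np.sin(np.arange(500) / 10.0)
        mask = np.ones(500, dtype=bool)
        assert wg.pearson_contact(x, x, mask) == pytest.approx(1.0)
        assert wg.pearson_contact(-x + 3.0, x, mask) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 10_000))
        mask = np.ones(10_000, dtype=bool)
        # under the null, |R| < 2.58/sqrt(n) ~ 0.026 at 99% confidence
        assert abs(wg.pearson_contact(x, y, mask)) < 0.05

    def test_constant_series_raises(self):
        mask = np.ones(100, dtype=bool)
        with pytest.raises(UndefinedCorrelation):
            wg.pearson_contact(np.ones(100), np.arange(100.0), mask)

    def test_mask_restricts_bins(self):
        x = np.concatenate([np.arange(100.0), np.zeros(100)])
        y = np.concatenate([np.arange(100.0), 50 - np.arange(100.0)])
        mask = np.zeros(200, dtype=bool)
        mask[:100] = True
        assert wg.pearson_contact(x, y, mask) == pytest.approx(1.0)


class TestSubsetFullR2:
    def test_identical_predictions(self):
        p = np.random.default_rng(1).random(400)
        assert wg.subset_full_r2(p, p, np.ones(400, bool)) == pytest.approx(1.0)

    def test_is_squared_pearson(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((2, 500))
        mask = np.ones(500, bool)
        assert wg.subset_full_r2(a, b, mask) == pytest.approx(
            wg.pearson_contact(a, b, mask) ** 2)


class TestPercentError:
    @pytest.mark.parametrize("r_full, r_sub, expected",
                             [(0.5, 0.4, 20.0), (0.5, 0.5, 0.0), (0.5, 0.6, -20.0)])
    def test_hand_computed_values(self, r_full, r_sub, expected):
        assert wg.percent_error(r_full, r_sub) == pytest.approx(expected)

    def test_zero_full_raises(self):
        with pytest.raises(UndefinedCorrelation):
            wg.percent_error(0.0, 0.3)

    @given(r_full=st.floats(0.05, 1.0), r_sub=st.floats(-1.0, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sign_semantics(self, r_full, r_sub):
        pe = wg.percent_error(r_full, r_sub)
        if r_sub > r_full:
            assert pe < 0  # subset beat the full model
        elif r_sub < r_full:
            assert pe > 0


class TestAggregateBetas:
    def _fit(self, coef_scale, basis, noise_predictors, seed):
        neuron = wg.GroundTruthNeuron.from_basis(
            basis, {"M": [0.5, 0.3, 0.1, 0.0, 0.0]}, bias=-3.5, seed=seed)
        y = wg.simulate_spikes(neuron, noise_predictors)
        d = wg.build_design(noise_predictors, basis, "full")
        f = wg.fit(d, y)
        f.coef = f.coef * coef_scale
        return f

    def test_single_fit_aggregate_is_its_abs_beta(self, basis, noise_predictors):
        f = self._fit(1.0, basis, noise_predictors, 1)
        mean_abs, n = wg.aggregate_betas([f])
        assert n == 1
        np.testing.assert_allclose(mean_abs, np.abs(f.beta))

    def test_outlier_fit_excluded(self, basis, noise_predictors):
        good = self._fit(1.0, basis, noise_predictors, 2)
        bad = self._fit(1e13, basis, noise_predictors, 3)
        mean_abs, n = wg.aggregate_betas([good, bad])
        assert n == 1
        np.testing.assert_allclose(mean_abs, np.abs(good.beta))

    def test_all_excluded_errors(self, basis, noise_predictors):
        bad = self._fit(1e13, basis, noise_predictors, 4)
        with pytest.raises(ValueError):
            wg.aggregate_betas([bad])

    def test_moment_dominates_for_moment_driven_population(self, basis, passive_predictors):
        fits = []
        d = wg.build_design(passive_predictors, basis, "full")
        for s in range(4):
            neuron = wg.make_mechanics_neuron(basis, 40 + s)
            y = wg.simulate_spikes(neuron, passive_predictors)
            fits.append(wg.fit(d, y))
        mean_abs, n = wg.aggregate_betas(fits)
        assert n == 4
        j_m = fits[0].predictor_names.index("M")
        # the moment column carries the largest early-basis weight on average
        early = mean_abs[:2, :].mean(axis=0)
        assert np.argmax(early) == j_m


class TestCouplingProfile:
    def test_duplicated_signal_pair(self):
        rng = np.random.default_rng(3)
        n = 500
        vals = rng.standard_normal((n, 6))
        vals[:, 4] = vals[:, 2]  # theta duplicates M
        ps = wg.PredictorSet(np.arange(n, dtype=float), vals, np.ones(n, bool))
        prof = wg.coupling_profile(ps)
        assert prof.pair("theta", "M") == pytest.approx(1.0)

    def test_constant_pair_reported_undefined(self):
        rng = np.random.default_rng(4)
        n = 500
        vals = rng.standard_normal((n, 6))
        vals[:, 0] = 2.0
        ps = wg.PredictorSet(np.arange(n, dtype=float), vals, np.ones(n, bool))
        prof = wg.coupling_profile(ps)
        assert np.isnan(prof.pair("Fx", "M"))

    def test_too_few_contact_bins(self):
        ps = wg.PredictorSet(np.arange(50, dtype=float),
                             np.random.default_rng(5).random((50, 6)),
                             np.ones(50, bool))
        with pytest.raises(ValueError):
            wg.coupling_profile(ps)


def _result(i, rf, rm, rk, prep="anesthetized"):
    return ComparisonResult(i, rf, rm, rk, rm**2, rk**2, preparation=prep)


class TestPopulationStats:
    def test_exclusion_of_full_model_losers(self):
        results = [_result(i, 0.5 + 0.01 * i, 0.4, 0.3) for i in range(6)]
        results.append(_result(99, 0.02, 0.3, 0.25))  # full worse than both subsets
        rep = population_stats(results)
        assert rep.excluded_ids == [99]
        assert rep.n_retained == 6

    def test_identical_paired_samples_signed_rank_p_one(self):
        results = [_result(i, 0.6, 0.4, 0.4) for i in range(6)]
        rep = population_stats(results)
        assert rep.signed_rank_p_pct_err["anesthetized"] == pytest.approx(1.0)

    def test_small_groups_skip_tests(self):
        results = [_result(i, 0.6, 0.5, 0.3) for i in range(3)]
        rep = population_stats(results)
        assert rep.ranksum_p_awake_vs_anesthetized is None
        assert rep.paired_t_p_mech_vs_kin is None

    def test_below_diagonal_fraction_and_median(self):
        # r_full always above r_kin, so the exclusion rule removes nobody
        results = [_result(i, 0.31 + 0.1 * i, 0.5 + 0.02 * i, 0.3) for i in range(8)]
        rep = population_stats(results)
        assert rep.below_diagonal_fraction == 1.0
        assert rep.median_r_full == pytest.approx(np.median([r.r_full for r in results]))
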