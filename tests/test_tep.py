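import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_epochs
from tepnet.synthetic import ep_template
from tepnet.tep import (
    BayesianTEP,
    bayesian_smooth_sweep,
    compare_gmfp,
    conventional_average,
    fit_prestim_ar,
    gmfp,
    weighted_average_sweeps,
    SmoothedSweep,
)


def _ar_series(rng, coeffs, n, sd=1.0):
    q = len(coeffs)
    e = rng.standard_normal(n + 100) * sd
    v = np.zeros_like(e)
    for t in range(q, e.size):
        v[t] = np.dot(coeffs, v[t - q : t][::-1]) + e[t]
    return v[100:]


class TestFitPrestimAR:
    def test_white_noise_selects_low_order(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = fit_prestim_ar(rng.standard_normal(400), max_order=10)
            hits += m.order <= 2
        # FPE keeps the order small on order-0 truth; its intrinsic
        # overfitting probability leaves a minority of seeds above 2
        assert hits >= 80

    def test_ar2_coefficients_recovered(self, rng):
        x = _ar_series(rng, [0.5, -0.3], 5000)
        m = fit_prestim_ar(x, max_order=10)
        assert m.order >= 2
        np.testing.assert_allclose(m.coeffs[:2], [0.5, -0.3], atol=0.05)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_prestim_ar(np.full(300, 2.0), max_order=5)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fit_prestim_ar(np.zeros(30), max_order=20)

    def test_model_is_stationary(self, rng):
        x = _ar_series(rng, [0.9], 1000)
        m = fit_prestim_ar(x, max_order=5)
        roots = np.roots(np.concatenate([[1.0], -m.coeffs]))
        assert np.all(np.abs(roots) < 1.0)
        assert m.variance > 0


class TestBayesianSmoothSweep:
    def _noise_model(self, rng, sd=1.0):
        return fit_prestim_ar(_ar_series(rng, [0.6], 400, sd=sd), max_order=5)

    def test_zero_regularization_returns_input(self, rng):
        y = rng.standard_normal(80)
        sw = bayesian_smooth_sweep(y, self._noise_model(rng), reg=0.0)
        np.testing.assert_allclose(sw.waveform, y, atol=1e-8)

    def test_infinite_regularization_shrinks_to_zero(self, rng):
        y = rng.standard_normal(80) + 5.0
        sw = bayesian_smooth_sweep(y, self._noise_model(rng), reg=1e12)
        assert np.max(np.abs(sw.waveform)) < 0.05 * np.max(np.abs(y))

    def test_negative_regularization_rejected(self, rng):
        with pytest.raises(ValueError, match="nonneg"):
            bayesian_smooth_sweep(np.zeros(40), self._noise_model(rng), reg=-1.0)

    def test_smoothing_beats_raw_sweep_at_snr_1(self):
        # known smooth EP + AR(1) noise at SNR ~ 1: the filtered sweep's
        # MSE must beat the raw sweep's in nearly every seed
        post_t = np.arange(100) * 2.0
        truth = ep_template(
            post_t, peaks=((40.0, 2.0, 14.0), (100.0, -2.5, 20.0),
                           (160.0, 1.5, 28.0)),
        )
        sd = np.sqrt(np.mean(truth**2))
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            noise = self._noise_model(rng, sd=sd)
            v = _ar_series(rng, [0.6], 100, sd=sd)
            y = truth + v
            sw = bayesian_smooth_sweep(y, noise)
            wins += np.mean((sw.waveform - truth) ** 2) <= np.mean(v**2)
        assert wins >= 0.95 * n_seeds


class TestWeightedAverage:
    def test_equal_errors_reduce_to_mean(self):
        sweeps = [SmoothedSweep(np.array([1.0, 2.0]), 2.0),
                  SmoothedSweep(np.array([3.0, 4.0]), 2.0)]
        wave, w = weighted_average_sweeps(sweeps)
        np.testing.assert_allclose(wave, [2.0, 3.0])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_inverse_proportional_weights(self):
        sweeps = [SmoothedSweep(np.zeros(2), 1.0), SmoothedSweep(np.zeros(2), 3.0)]
        _, w = weighted_average_sweeps(sweeps)
        np.testing.assert_allclose(w, [0.75, 0.25])

    def test_dominant_sweep_limit(self):
        a = SmoothedSweep(np.array([5.0, 5.0]), 1e-12)
        b = SmoothedSweep(np.array([-5.0, -5.0]), 1.0)
        wave, w = weighted_average_sweeps([a, b])
        np.testing.assert_allclose(wave, a.waveform, atol=1e-6)

    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=8))
    @settings(derandomize=True, max_examples=30)
    def test_weights_always_normalized(self, errs):
        sweeps = [SmoothedSweep(np.zeros(3), e) for e in errs]
        _, w = weighted_average_sweeps(sweeps)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            weighted_average_sweeps([])


class TestConventionalAverage:
    def test_identical_trials_return_the_trial(self, rng):
        trial = rng.standard_normal((1, 2, 50))
        ep = make_epochs(np.repeat(trial, 6, axis=0), t0_index=20)
        est = conventional_average(ep)
        np.testing.assert_allclose(est.waveform, trial[0][:, 20:])

    def test_opposite_trials_cancel(self):
        data = np.stack([np.ones((2, 50)), -np.ones((2, 50))])
        ep = make_epochs(data, t0_index=10)
        np.testing.assert_allclose(conventional_average(ep).waveform, 0.0)

    def test_noise_free_embedding_ca_equals_bayes(self):
        # with zero background noise both estimators return the template
        times = np.arange(-100, 101) * 2.0
        post = times >= 0
        template = ep_template(times[post], amplitude=2.0)
        data = np.zeros((5, 2, times.size))
        data[:, :, post] = template
        # tiny dither so the AR fit has nonzero variance
        rng = np.random.default_rng(0)
        data += 1e-5 * rng.standard_normal(data.shape)
        from tepnet.containers import EpochsArray

        ep = EpochsArray(data=data, srate=500.0, times=times, labels=["a", "b"])
        ca = conventional_average(ep)
        bayes = BayesianTEP(max_ar_order=5).fit(ep).tep_
        np.testing.assert_allclose(bayes.waveform, ca.waveform, atol=1e-5)


class TestGMFP:
    def test_identical_channels_give_zero(self):
        V = np.tile(np.sin(np.arange(20.0)), (4, 1))
        np.testing.assert_allclose(gmfp(V), 0.0, atol=1e-14)

    def test_two_channel_hand_value(self):
        V = np.array([[1.0], [-1.0]])
        np.testing.assert_allclose(gmfp(V), [1.0])

    def test_direct_formula_oracle_on_random_inputs(self, rng):
        V = rng.standard_normal((6, 30))
        expected = np.array([
            np.sqrt(np.sum((V[:, t] - V[:, t].mean()) ** 2) / V.shape[0])
            for t in range(V.shape[1])
        ])
        np.testing.assert_allclose(gmfp(V), expected, atol=1e-12)

    def test_single_channel_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            out = gmfp(np.ones((1, 10)))
        np.testing.assert_array_equal(out, 0.0)

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(derandomize=True, max_examples=30)
    def test_offset_invariance_and_scaling(self, offset, scale):
        rng = np.random.default_rng(7)
        V = rng.standard_normal((5, 12))
        base = gmfp(V)
        np.testing.assert_allclose(gmfp(V + offset), base, atol=1e-9)
        np.testing.assert_allclose(gmfp(V * scale), np.abs(scale) * base,
                                   rtol=1e-9)


class TestCompareGMFP:
    def test_identical_conditions_no_significance(self, rng):
        a = np.abs(rng.standard_normal((18, 30)))
        mask, p = compare_gmfp(a, a.copy())
        assert not mask.any()
        np.testing.assert_array_equal(p, 1.0)

    def test_uniform_shift_all_significant(self, rng):
        a = np.abs(rng.standard_normal((18, 30)))
        b = a + 5.0
        mask, p = compare_gmfp(a, b, alpha=0.05)
        # exact p for 18 same-sign pairs is 2/2^18; Bonferroni over 30
        # samples leaves every sample significant
        assert mask.all()

    def test_bonferroni_mask_subset_of_uncorrected(self, rng):
        a = np.abs(rng.standard_normal((10, 40)))
        b = a + rng.standard_normal((10, 40)) * 0.5
        mask, p_corr = compare_gmfp(a, b, alpha=0.05)
        uncorrected = p_corr / 40 < 0.05
        assert np.all(~mask | uncorrected)

    def test_too_few_pairs_rejected(self, rng):
        a = np.zeros((4, 10))
        with pytest.raises(ValueError, match="5"):
            compare_gmfp(a, a)
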