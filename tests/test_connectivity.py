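import numpy as np
import pytest

from tepnet.connectivity import (
    CANONICAL_WINDOW_BOUNDARIES,
    STOK,
    aggregate_windows,
    baseline_normalize,
    ipdc,
    select_model_order_aic,
    spectral_transfer,
    stok_fit,
    windows_from_boundaries,
)
from tepnet.containers import IPDCTensor, TVMVARModel, WindowedNetwork
from tepnet.experiments import (
    stok_null_recovery,
    stok_stationary_recovery,
    stok_step_tracking,
)
from tepnet.synthetic import make_ground_truth_network, simulate_epochs


def _random_tvmvar(rng, d=3, p=2, T=20, sigma=None):
    while True:
        A = rng.uniform(-0.4, 0.4, size=(p, d, d)) / p
        coeffs = np.broadcast_to(A, (T, p, d, d)).copy()
        from tepnet.containers import companion_spectral_radius

        if companion_spectral_radius(A) < 0.95:
            break
    return TVMVARModel(
        order=p, coeffs=coeffs,
        innov_cov=np.eye(d) if sigma is None else sigma,
        srate=500.0, times=np.arange(T) * 2.0,
    )


class TestWindows:
    def test_canonical_boundaries_give_five_windows(self):
        wins = windows_from_boundaries(CANONICAL_WINDOW_BOUNDARIES)
        assert len(wins) == 5
        assert wins[0] == (12.0, 24.0) and wins[-1] == (124.0, 240.0)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            windows_from_boundaries([12, 12, 48])


class TestOrderSelection:
    def test_var3_order_recovered(self):
        times = np.arange(0, 200) * 2.0
        hits = 0
        for seed in range(10):
            m = make_ground_truth_network(
                2, 3, [(0, 1, 3, 0.4, times[0], times[-1] + 2)],
                times=times, diag=(0.4, -0.3, 0.25),
            )
            ep = simulate_epochs(m, 100, times, seed)
            hits += select_model_order_aic(ep, 6) == 3
        assert hits >= 8

    def test_white_noise_selects_minimum_order(self):
        times = np.arange(0, 150) * 2.0
        picks = []
        for seed in range(6):
            m = make_ground_truth_network(3, 1, [], times=times, diag=(0.0,))
            ep = simulate_epochs(m, 60, times, seed)
            picks.append(select_model_order_aic(ep, 5))
        assert np.median(picks) == 1

    def test_invalid_max_order_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            select_model_order_aic(small_epochs, 0)


class TestSTOK:
    def test_stationary_coefficients_recovered(self):
        assert stok_stationary_recovery(seed=0) < 0.05

    def test_step_change_tracked_within_15_samples(self):
        assert abs(stok_step_tracking(seed=0)) <= 15

    def test_null_network_within_noise_floor(self):
        assert stok_null_recovery(seed=0) < 0.05

    def test_stationary_limit_matches_pooled_ols(self):
        # time-averaged STOK coefficients vs pooled least squares
        times = np.arange(0, 300) * 2.0
        m = make_ground_truth_network(
            3, 1, [(0, 1, 1, 0.3, times[0], times[-1] + 2)], times=times
        )
        ep = simulate_epochs(m, 200, times, seed=5)
        model = STOK(p=1).fit(ep).model_
        stok_avg = model.coeffs[50:].mean(axis=0)[0]
        from tepnet.connectivity import _lagged_design

        Z, tgt = _lagged_design(ep.data, 1)
        theta, *_ = np.linalg.lstsq(Z, tgt, rcond=None)
        np.testing.assert_allclose(stok_avg, theta.T, atol=0.05)

    def test_requires_multiple_trials(self, small_epochs):
        single = small_epochs.copy(data=small_epochs.data[:1])
        with pytest.raises(ValueError, match="2 trials"):
            STOK(p=1).fit(single)

    def test_memory_decay_within_bounds(self, small_epochs):
        model = STOK(p=1).fit(small_epochs).model_
        lam = model.memory_decay_trace
        assert np.all((lam >= 0.95) & (lam <= 0.999))

    def test_innov_cov_positive_definite(self, small_epochs):
        model = stok_fit(small_epochs, p=2)
        assert np.min(np.linalg.eigvalsh(model.innov_cov)) > 0


class TestSpectralTransfer:
    def test_zero_coefficients_give_identity(self):
        model = TVMVARModel(order=1, coeffs=np.zeros((5, 1, 3, 3)),
                            innov_cov=np.eye(3), srate=500.0,
                            times=np.arange(5) * 2.0)
        st = spectral_transfer(model, np.arange(1.0, 41.0))
        np.testing.assert_allclose(
            st.B, np.broadcast_to(np.eye(3), st.B.shape), atol=1e-14
        )

    def test_scalar_ar1_closed_form(self):
        a = 0.6
        coeffs = np.full((4, 1, 1, 1), a)
        model = TVMVARModel(order=1, coeffs=coeffs, innov_cov=np.eye(1),
                            srate=500.0, times=np.arange(4) * 2.0)
        freqs = np.array([5.0, 20.0, 100.0])
        st = spectral_transfer(model, freqs)
        expected = 1 - a * np.exp(-2j * np.pi * freqs / 500.0)
        np.testing.assert_allclose(st.B[:, 0, 0, 0], expected, atol=1e-12)

    def test_direct_summation_oracle(self, rng):
        model = _random_tvmvar(rng)
        freqs = rng.uniform(1, 200, size=10)
        st = spectral_transfer(model, freqs)
        for fi in range(5):
            for t in [0, 7]:
                direct = np.eye(3, dtype=complex)
                for k in range(model.order):
                    direct -= model.coeffs[t, k] * np.exp(
                        -2j * np.pi * freqs[fi] / 500.0 * (k + 1)
                    )
                np.testing.assert_allclose(st.B[fi, t], direct, atol=1e-10)

    def test_out_of_band_frequencies_rejected(self, rng):
        model = _random_tvmvar(rng)
        with pytest.raises(ValueError):
            spectral_transfer(model, np.array([300.0]))


class TestIPDC:
    def test_zero_coupling_diagonal_one(self):
        model = TVMVARModel(order=1, coeffs=np.zeros((5, 1, 3, 3)),
                            innov_cov=4.0 * np.eye(3), srate=500.0,
                            times=np.arange(5) * 2.0)
        tensor = ipdc(spectral_transfer(model, np.arange(1.0, 41.0)),
                      model.innov_cov)
        d = 3
        diag = tensor.values[np.arange(d), np.arange(d)]
        np.testing.assert_allclose(diag, 1.0, atol=1e-12)
        off = tensor.values[~np.eye(d, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_column_normalization_under_equal_variance(self, rng):
        model = _random_tvmvar(rng, sigma=2.5 * np.eye(3))
        tensor = ipdc(spectral_transfer(model, np.arange(1.0, 41.0)),
                      model.innov_cov)
        sums = np.sum(tensor.values**2, axis=0)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)

    def test_one_way_coupling_is_directed(self):
        times = np.arange(10) * 2.0
        m = make_ground_truth_network(
            2, 1, [(0, 1, 1, 0.4, times[0], times[-1] + 2)], times=times
        )
        model = TVMVARModel(order=1, coeffs=m.coeffs, innov_cov=np.eye(2),
                            srate=500.0, times=times)
        tensor = ipdc(spectral_transfer(model, np.arange(1.0, 41.0)), np.eye(2))
        assert np.all(tensor.values[1, 0] > 0)  # 0 -> 1 present
        np.testing.assert_allclose(tensor.values[0, 1], 0.0, atol=1e-12)

    def test_singular_covariance_rejected(self, rng):
        model = _random_tvmvar(rng)
        st = spectral_transfer(model, np.arange(1.0, 11.0))
        with pytest.raises(ValueError, match="singular"):
            ipdc(st, np.ones((3, 3)))


class TestAggregateWindows:
    def _tensor(self, values, times=None, freqs=None):
        d = values.shape[0]
        return IPDCTensor(
            values=values,
            freqs=np.arange(1.0, 1.0 + values.shape[2]) if freqs is None else freqs,
            times=np.arange(values.shape[3]) * 2.0 if times is None else times,
        )

    def test_constant_tensor_gives_constant_adjacency(self):
        tensor = self._tensor(np.full((3, 3, 10, 50), 0.7))
        nets = aggregate_windows(tensor, [(0.0, 40.0), (40.0, 98.0)],
                                 band=(1.0, 10.0))
        for net in nets:
            off = net.adjacency[~np.eye(3, dtype=bool)]
            np.testing.assert_allclose(off, 0.7)
            np.testing.assert_allclose(np.diag(net.adjacency), 0.0)

    def test_half_open_window_convention_on_ramp(self):
        # values increase linearly with the sample index: the mean over
        # [a, b) includes a but not b
        T = 50
        vals = np.broadcast_to(np.arange(T, dtype=float),
                               (2, 2, 1, T)).copy()
        tensor = self._tensor(vals)
        net = aggregate_windows(tensor, [(10.0, 20.0)], band=(1.0, 1.0))[0]
        # samples at 10..18 ms = indices 5..9
        assert net.adjacency[0, 1] == pytest.approx(np.mean(np.arange(5, 10)))

    def test_empty_window_rejected_by_name(self):
        tensor = self._tensor(np.zeros((2, 2, 4, 10)))
        with pytest.raises(ValueError, match="33"):
            aggregate_windows(tensor, [(33.0, 33.5)], band=(1.0, 4.0))

    def test_frequency_grid_refinement_stability(self):
        # halving the grid spacing changes window adjacencies by < 1%
        rng = np.random.default_rng(3)
        model = _random_tvmvar(rng, T=120)
        out = {}
        for step in (1.0, 0.5):
            freqs = np.arange(1.0, 40.0 + 1e-9, step)
            tensor = ipdc(spectral_transfer(model, freqs), model.innov_cov)
            net = aggregate_windows(tensor, [(0.0, 238.0)], band=(1.0, 40.0))[0]
            out[step] = net.adjacency
        off = ~np.eye(3, dtype=bool)
        rel = np.abs(out[0.5][off] - out[1.0][off]) / np.abs(out[1.0][off])
        assert np.max(rel) < 0.01


class TestBaselineNormalize:
    def _net(self, adj, window=(12.0, 24.0)):
        return WindowedNetwork(adjacency=adj, window=window, band=(1.0, 40.0))

    def test_zero_baseline_is_identity(self, rng):
        post = [self._net(rng.random((3, 3)))]
        out = baseline_normalize(post, self._net(np.zeros((3, 3))))
        np.testing.assert_array_equal(out[0].adjacency, post[0].adjacency)

    def test_self_subtraction_gives_zero(self, rng):
        adj = rng.random((3, 3))
        out = baseline_normalize([self._net(adj)], self._net(adj.copy()))
        np.testing.assert_allclose(out[0].adjacency, 0.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimensions"):
            baseline_normalize([self._net(np.zeros((3, 3)))],
                               self._net(np.zeros((4, 4))))

    def test_stationary_null_centering(self):
        # on a stationary network, post-stimulus windows minus the
        # pre-stimulus baseline are centred on zero
        times = np.arange(-120, 121) * 2.0
        devs = []
        for seed in range(10):
            m = make_ground_truth_network(
                3, 1, [(0, 1, 1, 0.3, times[0], times[-1] + 2)], times=times
            )
            ep = simulate_epochs(m, 40, times, seed)
            model = STOK(p=1).fit(ep).model_
            tensor = ipdc(spectral_transfer(model, np.arange(1.0, 41.0)),
                          model.innov_cov)
            post = aggregate_windows(tensor, [(12.0, 240.0)], band=(1.0, 40.0))
            pre = aggregate_windows(tensor, [(-228.0, -12.0)], band=(1.0, 40.0))[0]
            norm = baseline_normalize(post, pre)[0]
            devs.append(np.mean(np.abs(norm.adjacency[~np.eye(3, dtype=bool)])))
        assert np.mean(devs) < 0.02
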