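import numpy as np
import pytest

from oracles import stationary_var_autocov
from tepnet.containers import companion_spectral_radius
from tepnet.synthetic import (
    embed_tep,
    ep_template,
    make_ground_truth_network,
    simulate_epochs,
    simulate_mocs_session,
)

TIMES = np.arange(-50, 150) * 2.0  # -100..+298 ms at 500 Hz


class TestMakeGroundTruthNetwork:
    def test_no_couplings_gives_diagonal_matrices(self):
        m = make_ground_truth_network(2, 1, [], times=TIMES)
        off = m.coeffs[:, :, ~np.eye(2, dtype=bool)]
        assert np.all(off == 0)
        assert np.all(m.coeffs[:, 0, 0, 0] == 0.5)

    def test_coupling_confined_to_window(self):
        m = make_ground_truth_network(
            3, 1, [(0, 1, 1, 0.5, 48.0, 92.0)], times=TIMES
        )
        active = (TIMES >= 48.0) & (TIMES < 92.0)
        assert np.all(m.coeffs[active, 0, 1, 0] == 0.5)
        assert np.all(m.coeffs[~active, 0, 1, 0] == 0.0)
        assert m.change_points  # the window edges are recorded

    def test_stability_enforced_at_every_configuration(self):
        m = make_ground_truth_network(
            3, 2, [(0, 1, 1, 0.4, 0.0, 100.0), (1, 2, 2, 0.3, 50.0, 200.0)],
            times=TIMES,
        )
        for t in [0, *m.change_points]:
            assert companion_spectral_radius(m.coeffs[t]) < 1.0

    def test_unstable_coupling_rejected_with_time(self):
        with pytest.raises(ValueError, match="unstable.*sample"):
            make_ground_truth_network(
                2, 1, [(0, 1, 1, 0.9, 0.0, 100.0), (1, 0, 1, 0.9, 0.0, 100.0)],
                times=TIMES,
            )

    def test_labels_resolve_channels(self):
        m = make_ground_truth_network(
            2, 1, [("O1", "O2", 1, 0.3, 0.0, 100.0)],
            times=TIMES, labels=["O1", "O2"],
        )
        assert m.coeffs[TIMES.searchsorted(10.0), 0, 1, 0] == 0.3


class TestSimulateEpochs:
    def test_seed_determinism(self):
        m = make_ground_truth_network(2, 1, [], times=TIMES)
        a = simulate_epochs(m, 5, TIMES, seed=42)
        b = simulate_epochs(m, 5, TIMES, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_shape_contract(self):
        m = make_ground_truth_network(3, 2, [], times=TIMES)
        ep = simulate_epochs(m, 7, TIMES, seed=0)
        assert ep.data.shape == (7, 3, TIMES.size)

    def test_rejects_zero_trials(self):
        m = make_ground_truth_network(2, 1, [], times=TIMES)
        with pytest.raises(ValueError, match="n_trials"):
            simulate_epochs(m, 0, TIMES, seed=0)

    def test_white_noise_covariance_matches_identity(self):
        # all-zero coefficients, identity innovations: pooled sample
        # covariance must approach I (law of large numbers)
        times = np.arange(0, 500) * 2.0
        m = make_ground_truth_network(3, 1, [], times=times, diag=(0.0,))
        ep = simulate_epochs(m, 200, times, seed=3)
        X = ep.data.transpose(1, 0, 2).reshape(3, -1)
        cov = X @ X.T / X.shape[1]
        assert np.max(np.abs(cov - np.eye(3))) < 0.1

    def test_autocovariance_matches_yule_walker(self):
        # stationary special case: simulated lag-h autocovariances converge
        # to the Lyapunov/Yule-Walker solution of the generating model
        times = np.arange(0, 300) * 2.0
        A = np.array([[[0.5, 0.2], [0.0, 0.4]]])
        m = make_ground_truth_network(
            2, 1, [(0, 1, 1, 0.0, 0, 0)], times=times, diag=(0.0,)
        )
        m.coeffs[:] = A  # fixed stationary coefficients
        ep = simulate_epochs(m, 1000, times, seed=7)
        expected = stationary_var_autocov(A, np.eye(2), max_lag=2)
        X = ep.data
        n_eff = X.shape[0] * (X.shape[2] - 2)
        for h in range(3):
            emp = np.einsum("nit,njt->ij", X[:, :, 2:], X[:, :, 2 - h : X.shape[2] - h])
            emp /= n_eff
            se = 3.0 / np.sqrt(n_eff)  # 3 standard errors at unit scale
            assert np.max(np.abs(emp - expected[h])) < se * 3

    def test_trial_noise_scaling_changes_trial_power(self):
        times = np.arange(0, 400) * 2.0
        m = make_ground_truth_network(2, 1, [], times=times, diag=(0.0,))
        ep = simulate_epochs(m, 100, times, seed=1, trial_noise_sd=1.0)
        power = ep.data.var(axis=(1, 2))
        assert power.max() / power.min() > 5  # heterogeneous sweeps


class TestEmbedTep:
    def test_zero_template_is_identity(self, small_epochs):
        out = embed_tep(small_epochs, np.zeros(int((small_epochs.times >= 0).sum())))
        np.testing.assert_array_equal(out.data, small_epochs.data)

    def test_noise_free_embedding_reproduces_template(self, small_epochs):
        quiet = small_epochs.copy(data=np.zeros_like(small_epochs.data))
        post = quiet.postim_mask()
        template = ep_template(quiet.times[post], amplitude=2.0)
        out = embed_tep(quiet, template)
        for trial in out.data:
            np.testing.assert_allclose(
                trial[:, post], np.broadcast_to(template, (3, template.size))
            )

    def test_prestimulus_untouched(self, small_epochs):
        post = small_epochs.postim_mask()
        out = embed_tep(small_epochs, np.ones(int(post.sum())), jitter_sd=0.2,
                        seed=5)
        pre = small_epochs.prestim_mask()
        np.testing.assert_array_equal(out.data[:, :, pre],
                                      small_epochs.data[:, :, pre])

    def test_template_longer_than_post_window_rejected(self, small_epochs):
        n_post = int(small_epochs.postim_mask().sum())
        with pytest.raises(ValueError, match="longer"):
            embed_tep(small_epochs, np.ones(n_post + 1))

    def test_jittered_mean_converges_to_template(self, rng):
        from conftest import make_epochs

        data = rng.standard_normal((1000, 1, 40))
        ep = make_epochs(data, t0_index=10)
        template = np.linspace(0, 3, 30)
        out = embed_tep(ep, template, jitter_sd=0.1, seed=9)
        delta = (out.data - ep.data)[:, 0, 10:]
        mean = delta.mean(axis=0)
        se = delta.std(axis=0, ddof=1) / np.sqrt(delta.shape[0])
        assert np.all(np.abs(mean - template) <= 3 * se + 1e-12)


class TestSimulateMocs:
    def test_step_function_limit(self):
        grid = np.array([60.0, 63, 66, 69, 72, 75, 78])
        r = simulate_mocs_session(69.5, 1e6, grid, 7, seed=0)
        np.testing.assert_array_equal(r.seen[grid < 69.5], 0)
        np.testing.assert_array_equal(r.seen[grid > 69.5], 7)

    def test_total_pulse_count(self):
        grid = np.arange(60.0, 79.0, 3.0)
        r = simulate_mocs_session(69.0, 0.8, grid, 7, seed=0)
        assert len(r.intensities) * r.n_pulses_per_level == 49

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            simulate_mocs_session(69.0, 0.0, [60.0, 63.0], 7, seed=0)
        with pytest.raises(ValueError, match="empty"):
            simulate_mocs_session(69.0, 1.0, [], 7, seed=0)


def test_ep_template_peaks_at_canonical_latencies():
    times = np.arange(0, 125) * 2.0
    wave = ep_template(times)
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(np.abs(wave), height=0.5)
    # overlapping atoms may shift a peak by a sample or two
    for latency in (18.0, 36.0, 70.0, 108.0, 180.0):
        assert np.min(np.abs(times[peaks] - latency)) <= 4.0
    assert len(peaks) == 5
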