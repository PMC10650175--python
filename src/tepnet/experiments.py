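"""Self-contained validation experiments on synthetic ground truth.

These routines exercise the pipeline under known generating conditions and
return scalar summaries: estimator recovery errors, tracking latencies,
estimator comparisons, type-I error rates and planted-effect detection.
They are used both by the test suite and by the reproduction script; each
is a pure function of its seed.

Problem sizes are deliberately compact (small montages, tens of trials,
epochs of a few hundred samples) so a full battery runs in minutes on one
CPU; docs/methods.md records the chosen sizes.
"""

from __future__ import annotations

import numpy as np

from ._utils import time_axis
from .connectivity import (
    STOK,
    aggregate_windows,
    ipdc,
    spectral_transfer,
    windows_from_boundaries,
)
from .containers import GroundTruthTVMVAR
from .pipeline import run_study
from .stats import contrast_edges
from .synthetic import ep_template, make_ground_truth_network, simulate_epochs
from .tep import bayesian_smooth_sweep, fit_prestim_ar, weighted_average_sweeps

__all__ = [
    "ipdc_normalization_deviation",
    "stok_stationary_recovery",
    "stok_step_tracking",
    "stok_null_recovery",
    "bayes_vs_ca",
    "null_edge_type1_rate",
    "planted_effect_study",
    "small_study_config",
]


def ipdc_normalization_deviation(n_models: int = 100, seed: int = 0) -> float:
    """Max deviation of per-source-column squared-|iPDC| sums from 1.

    Random stable VAR models with equal-variance innovations; under
    Sigma_eps = sigma^2 I the squared magnitudes must sum to 1 over targets
    for every (source, frequency, time).
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        d, p = int(rng.integers(2, 5)), int(rng.integers(1, 4))
        T = 12
        while True:
            A = rng.uniform(-0.45, 0.45, size=(p, d, d)) / p
            try:
                model = GroundTruthTVMVAR(
                    order=p, coeffs=np.broadcast_to(A, (T, p, d, d)).copy(),
                    noise_cov=np.eye(d) * float(rng.uniform(0.5, 2.0)) ** 2,
                    srate=500.0,
                )
                break
            except ValueError:
                continue
        from .containers import TVMVARModel

        tv = TVMVARModel(order=p, coeffs=model.coeffs, innov_cov=model.noise_cov,
                         srate=500.0, times=np.arange(T) * 2.0)
        freqs = rng.uniform(1.0, 200.0, size=8)
        tensor = ipdc(spectral_transfer(tv, freqs), tv.innov_cov)
        sums = np.sum(tensor.values**2, axis=0)  # over targets i -> (j, f, t)
        worst = max(worst, float(np.max(np.abs(sums - 1.0))))
    return worst


def _stationary_var1(d: int, seed: int, T: int, n_trials: int,
                     coupling: float = 0.0, step_at: int | None = None):
    """Stationary (or single-step) VAR(1) ground truth + simulated epochs."""
    times = np.arange(T) * 2.0  # 500 Hz
    spec = []
    if coupling and step_at is None:
        spec.append((0, 1, 1, coupling, times[0], times[-1] + 2.0))
    model = make_ground_truth_network(
        d, 1, spec, times=times, srate=500.0, diag=(0.5,),
    )
    if step_at is not None and coupling:
        model.coeffs[step_at:, 0, 1, 0] = coupling
    epochs = simulate_epochs(model, n_trials, times, seed)
    return model, epochs


def stok_stationary_recovery(seed: int = 0, d: int = 3, n_trials: int = 200,
                             T: int = 300) -> float:
    """Max-entry error of time-averaged STOK coefficients on a VAR(1) truth."""
    rng = np.random.default_rng(seed)
    times = np.arange(T) * 2.0
    while True:
        A = rng.uniform(-0.5, 0.5, size=(1, d, d))
        try:
            model = GroundTruthTVMVAR(
                order=1, coeffs=np.broadcast_to(A, (T, 1, d, d)).copy(),
                noise_cov=np.eye(d), srate=500.0,
            )
            break
        except ValueError:
            continue
    epochs = simulate_epochs(model, n_trials, times, seed)
    fit = STOK(p=1).fit(epochs).model_
    est = fit.coeffs[50:].mean(axis=0)  # discard filter warm-up
    return float(np.max(np.abs(est - A)))


def stok_step_tracking(seed: int = 0, step_sample: int = 150,
                       step_height: float = 0.5, n_trials: int = 200,
                       T: int = 300) -> int:
    """Latency (samples) for the tracked coupling to cross half its step.

    A 0 -> ``step_height`` step in the 1 -> 2 coupling occurs at
    ``step_sample``; returns the signed offset of the half-height crossing
    relative to the step.
    """
    model, epochs = _stationary_var1(3, seed, T, n_trials,
                                     coupling=step_height, step_at=step_sample)
    fit = STOK(p=1).fit(epochs).model_
    track = fit.coeffs[:, 0, 1, 0]
    above = np.flatnonzero(track[step_sample - 30 :] >= step_height / 2.0)
    if above.size == 0:
        return T  # never crossed
    return int(above[0] - 30)


def stok_null_recovery(seed: int = 0, d: int = 3, n_trials: int = 200,
                       T: int = 300) -> float:
    """Max time-averaged off-diagonal coefficient on an uncoupled truth."""
    model, epochs = _stationary_var1(d, seed, T, n_trials, coupling=0.0)
    fit = STOK(p=1).fit(epochs).model_
    est = fit.coeffs[50:].mean(axis=0)[0]
    off = est[~np.eye(d, dtype=bool)]
    return float(np.max(np.abs(off)))


def bayes_vs_ca(n_seeds: int = 100, n_sweeps: int = 30, n_samples: int = 120,
                seed: int = 0, ar_coeff: float = 0.6, noise_sd: float = 3.0,
                trial_noise_sd: float = 0.8) -> float:
    """Fraction of seeds where the Bayesian TEP beats conventional averaging.

    Single-channel sweeps: a known smooth evoked potential plus AR(1) noise
    whose variance varies log-normally across sweeps (heterogeneous
    reliability).  Per seed, the mean-squared error of the
    inverse-error-weighted Bayesian estimate is compared to the plain mean
    of the raw sweeps against the known truth.
    """
    base_rng = np.random.default_rng(seed)
    # post-stimulus truth on its own 500 Hz axis; canonical peak latencies
    # with widths in the smooth regime the integrated-noise prior assumes
    post_t = np.arange(n_samples) * 2.0
    peaks = ((18.0, 2.5, 10.0), (36.0, -3.5, 12.0), (70.0, 4.0, 16.0),
             (108.0, -3.0, 20.0), (180.0, 2.0, 32.0))
    truth = ep_template(post_t, peaks=peaks, amplitude=1.5)
    n_pre = n_samples
    wins = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_rng.integers(2**31))
        scales = np.exp(rng.normal(0.0, trial_noise_sd, size=n_sweeps))
        sweeps = []
        raw = np.empty((n_sweeps, n_samples))
        for k in range(n_sweeps):
            # AR(1) background spanning pre+post intervals
            e = rng.standard_normal(n_pre + n_samples + 50) * noise_sd * scales[k]
            v = np.empty_like(e)
            v[0] = e[0]
            for t in range(1, e.size):
                v[t] = ar_coeff * v[t - 1] + e[t]
            v = v[50:]
            pre, post = v[:n_pre], v[n_pre:]
            y = truth + post
            raw[k] = y
            noise = fit_prestim_ar(pre, max_order=8)
            sweeps.append(bayesian_smooth_sweep(y, noise, prior_order=2,
                                                reg="auto"))
        bayes, _ = weighted_average_sweeps(sweeps)
        mse_bayes = float(np.mean((bayes - truth) ** 2))
        mse_ca = float(np.mean((raw.mean(axis=0) - truth) ** 2))
        wins += mse_bayes <= mse_ca
    return wins / n_seeds


def small_study_config(n_subjects: int = 18, seed: int = 0,
                       planted: bool = False, trials: int = 60) -> dict:
    """A compact two-condition study config (12-channel montage).

    With ``planted=True`` the O1 condition carries an extra
    occipital -> contralateral-frontal coupling confined to the 48-92 ms
    window; otherwise the two conditions are mirror-identical (full null
    after flipping).
    """
    effect = {"O1": [["O1", "F4", 1, 0.35, 48.0, 92.0]] if planted else [],
              "O2": []}
    return {
        "study": {"subjects": n_subjects, "seed": seed},
        "montage": "small12",
        "times": {"start": -260.0, "stop": 260.0},
        "session": {"blocks": 1, "trials_per_block": trials},
        "network": {
            "order": 1,
            "diag": [0.5],
            "trial_noise_sd": 0.2,
            "couplings": [
                ["O1", "P3", 1, 0.30, 12.0, 240.0],
                ["P3", "F3", 1, 0.25, 48.0, 240.0],
            ],
            "effect_couplings": effect,
        },
        "ep": {"enabled": True, "amplitude": 0.8, "jitter_sd": 0.1},
        "tep": {"methods": ["ca"]},
        "connectivity": {"order": 1, "baseline_window": [-240.0, -12.0]},
    }


def _condensed_subject_networks(seed: int, d: int = 4, n_trials: int = 24,
                                planted: bool = False):
    """Fast epochs -> STOK -> iPDC -> windows for one synthetic session."""
    times = time_axis(-40.0, 246.0, 500.0)
    spec = [(0, 1, 1, 0.3, 12.0, 240.0)]
    if planted:
        spec.append((0, 2, 1, 0.35, 48.0, 92.0))
    model = make_ground_truth_network(d, 1, spec, times=times, srate=500.0,
                                      diag=(0.5,))
    epochs = simulate_epochs(model, n_trials, times, seed)
    fit = STOK(p=1).fit(epochs).model_
    freqs = np.arange(1.0, 41.0)
    tensor = ipdc(spectral_transfer(fit, freqs), fit.innov_cov)
    return aggregate_windows(tensor, windows_from_boundaries(), band=(1.0, 40.0))


def null_edge_type1_rate(n_seeds: int = 200, n_subjects: int = 18,
                         alpha: float = 0.001, seed: int = 0) -> float:
    """Fraction of (edge, window) cells significant on fully null studies.

    Both conditions of every synthetic study share the same generating
    network; any significant edge is a false positive.
    """
    base = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for _ in range(n_seeds):
        seeds = base.integers(2**31, size=2 * n_subjects)
        nets_a = [_condensed_subject_networks(int(seeds[i]))
                  for i in range(n_subjects)]
        nets_b = [_condensed_subject_networks(int(seeds[n_subjects + i]))
                  for i in range(n_subjects)]
        sig = contrast_edges(nets_a, nets_b, alpha=alpha)
        d = nets_a[0][0].n_nodes
        n_sig += len(sig)
        n_tests += len(nets_a[0]) * d * (d - 1)
    return n_sig / n_tests


def planted_effect_study(n_subjects: int = 18, seed: int = 0, outdir=None):
    """End-to-end study with a planted contralateral-frontal effect.

    Runs the full pipeline (epochs -> TEP -> STOK/iPDC -> graphs -> stats)
    on a compact 12-channel study in which condition O1 carries an extra
    O1 -> F4 coupling in the 48-92 ms window.  Returns the significant-edge
    table and whether the planted edge (F4 <- O1, 48-92 ms, positive sign)
    was recovered.
    """
    import tempfile

    cfg = small_study_config(n_subjects=n_subjects, seed=seed, planted=True)
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = tmp.name
    out = run_study(cfg, outdir)
    import pandas as pd

    edges = pd.read_csv(out / "stats" / "edges.csv")
    w = edges[(edges["window_start"] == 48.0) & (edges["window_end"] == 92.0)]
    hit = bool(((w["source"] == "O1") & (w["target"] == "F4")
                & (w["sign"] == 1)).any())
    return edges, hit
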