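"""Synthetic TMS-EEG study generation with known ground truth.

The generator produces everything the downstream pipeline consumes without
any recorded data: stable time-varying VAR networks with prescribed
directed couplings in prescribed time windows, multi-trial epochs driven by
those networks, an evoked-potential template embedded in the post-stimulus
interval, and Bernoulli phosphene reports from a logistic psychometric
function for the threshold-setting stage.

Every stochastic operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import numpy as np

from ._utils import as_rng, ms_to_sample, time_axis
from .containers import (
    EpochsArray,
    GroundTruthTVMVAR,
    MOCSResponses,
    SessionPlan,
    companion_spectral_radius,
)

__all__ = [
    "make_ground_truth_network",
    "simulate_epochs",
    "ep_template",
    "embed_tep",
    "simulate_mocs_session",
    "DEFAULT_EP_PEAKS",
]

#: Default evoked-potential atoms: (latency ms, amplitude µV, width ms).
#: Latencies sit near the centres of the canonical analysis windows so the
#: window logic downstream is exercised by construction.
DEFAULT_EP_PEAKS = (
    (18.0, 2.5, 5.0),
    (36.0, -3.5, 8.0),
    (70.0, 4.0, 14.0),
    (108.0, -3.0, 18.0),
    (180.0, 2.0, 30.0),
)


def make_ground_truth_network(
    d: int,
    p: int,
    coupling_spec,
    *,
    times: np.ndarray,
    srate: float = 500.0,
    noise_cov: np.ndarray | None = None,
    diag: tuple[float, ...] | None = None,
    labels: list[str] | None = None,
) -> GroundTruthTVMVAR:
    """Build a stable time-varying VAR model with prescribed couplings.

    Off-diagonal AR entries are exactly zero except where ``coupling_spec``
    places them; each coupling is a tuple ``(source, target, lag, strength,
    onset_ms, offset_ms)`` active on the half-open window [onset, offset) ms.
    Sources/targets may be channel indices or montage labels (if ``labels``
    is given).

    Parameters
    ----------
    d, p : int
        Channel count (>= 2) and lag order (>= 1).
    times : ndarray
        Epoch time axis in ms; coefficients are defined at every sample.
    noise_cov : ndarray, optional
        Innovation covariance in µV² (default: identity).
    diag : tuple of float, optional
        Self-coupling per lag on the diagonal (default 0.5 at lag 1,
        zero at higher lags) — the spontaneous-EEG backbone of the model.

    Raises
    ------
    ValueError
        If the resulting model is unstable at any sample (reported with the
        offending time index) or ``noise_cov`` is not positive-definite.
    """
    if d < 2:
        raise ValueError("need at least d = 2 channels")
    if p < 1:
        raise ValueError("lag order p must be >= 1")
    times = np.asarray(times, dtype=float)
    T = times.size
    if noise_cov is None:
        noise_cov = np.eye(d)
    if diag is None:
        diag = (0.5,) + (0.0,) * (p - 1)
    if len(diag) != p:
        raise ValueError("diag must supply one self-coupling per lag")

    def _chan(c):
        if isinstance(c, str):
            if labels is None:
                raise ValueError("labels required to resolve channel names")
            return labels.index(c)
        return int(c)

    coeffs = np.zeros((T, p, d, d))
    for k in range(p):
        coeffs[:, k, np.arange(d), np.arange(d)] = diag[k]
    change_points: set[int] = set()
    for src, tgt, lag, strength, onset_ms, offset_ms in coupling_spec:
        i, j = _chan(tgt), _chan(src)
        if not 1 <= int(lag) <= p:
            raise ValueError(f"coupling lag {lag} outside 1..{p}")
        active = (times >= onset_ms) & (times < offset_ms)
        coeffs[active, int(lag) - 1, i, j] = strength
        idx = np.flatnonzero(np.diff(active.astype(int)) != 0) + 1
        change_points.update(int(s) for s in idx)
    # stability is checked where coefficients change, plus the initial sample
    for t in sorted({0, *change_points}):
        rho = companion_spectral_radius(coeffs[t])
        if rho >= 1.0:
            raise ValueError(
                f"coupling_spec yields an unstable model at sample {t} "
                f"(t = {times[t]:.1f} ms, spectral radius {rho:.3f})"
            )
    return GroundTruthTVMVAR(
        order=p,
        coeffs=coeffs,
        noise_cov=np.asarray(noise_cov, dtype=float),
        srate=srate,
        change_points=sorted(change_points),
    )


def simulate_epochs(
    model: GroundTruthTVMVAR,
    n_trials: int,
    times: np.ndarray,
    seed,
    *,
    labels: list[str] | None = None,
    stim_site: str = "none",
    trial_noise_sd: float = 0.0,
    burnin: int | None = None,
) -> EpochsArray:
    """Draw independent multi-trial realizations of a time-varying VAR.

    Each trial starts from zeros and runs through a discarded burn-in of
    ``10 * p`` samples (under the initial coefficients) so the process
    forgets the arbitrary initial condition; the returned epochs cover
    exactly ``times``.  With ``trial_noise_sd > 0`` the innovation
    covariance of each trial is scaled by an independent log-normal factor
    ``exp(N(0, trial_noise_sd))`` emulating sweep-to-sweep nonstationarity
    of the background EEG.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    times = np.asarray(times, dtype=float)
    T = times.size
    if T != model.n_samples:
        raise ValueError("times must match the model's sample axis")
    rng = as_rng(seed)
    p, d = model.order, model.n_channels
    nb = 10 * p if burnin is None else int(burnin)
    L = np.linalg.cholesky(model.noise_cov)
    scales = (
        np.exp(rng.normal(0.0, trial_noise_sd, size=n_trials))
        if trial_noise_sd > 0
        else np.ones(n_trials)
    )
    total = T + nb
    X = np.zeros((n_trials, d, total))
    # innovations: eps[n, :, t] = L @ z, with a per-trial amplitude scale
    eps = np.einsum("ij,njt->nit", L, rng.standard_normal((n_trials, d, total)))
    eps *= scales[:, None, None]
    for t in range(total):
        A = model.coeffs[max(t - nb, 0)]  # burn-in runs under the initial coefficients
        acc = eps[:, :, t].copy()
        for k in range(1, p + 1):
            if t - k >= 0:
                acc += X[:, :, t - k] @ A[k - 1].T
        X[:, :, t] = acc
    if labels is None:
        labels = [f"ch{i}" for i in range(d)]
    return EpochsArray(
        data=X[:, :, nb:], srate=model.srate, times=times,
        labels=labels, stim_site=stim_site,
    )


def ep_template(
    times: np.ndarray,
    peaks=DEFAULT_EP_PEAKS,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Multi-peak evoked-potential waveform on the post-stimulus axis.

    A sum of Gaussian-damped deflections, one per ``(latency_ms,
    amplitude_µV, width_ms)`` atom, scaled by ``amplitude``.  Samples at
    t < 0 are zero.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros_like(times)
    post = times >= 0
    for tau, a, w in peaks:
        out[post] += a * np.exp(-0.5 * ((times[post] - tau) / w) ** 2)
    return amplitude * out


def embed_tep(
    epochs: EpochsArray,
    template: np.ndarray,
    jitter_sd: float = 0.0,
    seed=0,
) -> EpochsArray:
    """Additively embed an evoked potential into the post-stimulus interval.

    ``template`` is either a single waveform (n_post,) broadcast to all
    channels or a per-channel array (n_channels, n_post), aligned to the
    samples with t >= 0.  With ``jitter_sd > 0`` each trial receives an
    independent multiplicative gain ``N(1, jitter_sd)`` (fractional
    amplitude variability across sweeps); 0 disables jitter.  Pre-stimulus
    samples are returned bit-identical.
    """
    post = epochs.postim_mask()
    n_post = int(post.sum())
    template = np.asarray(template, dtype=float)
    if template.ndim == 1:
        template = np.broadcast_to(template, (epochs.n_channels, template.shape[0]))
    if template.shape[1] > n_post:
        raise ValueError(
            f"template ({template.shape[1]} samples) longer than the "
            f"post-stimulus window ({n_post} samples)"
        )
    rng = as_rng(seed)
    gains = (
        1.0 + rng.normal(0.0, jitter_sd, size=epochs.n_trials)
        if jitter_sd > 0
        else np.ones(epochs.n_trials)
    )
    data = epochs.data.copy()
    start = np.flatnonzero(post)[0]
    sl = slice(start, start + template.shape[1])
    data[:, :, sl] += gains[:, None, None] * template[None, :, :]
    return epochs.copy(data=data)


def simulate_mocs_session(
    alpha: float,
    beta: float,
    grid,
    n_per_level: int,
    seed,
) -> MOCSResponses:
    """Simulate phosphene reports over a Method of Constant Stimuli grid.

    Seen counts are Binomial(``n_per_level``, ``logistic(beta * (I - alpha))``)
    at each grid intensity; ``alpha`` is the 50% threshold in %MSO and
    ``beta`` the psychometric slope (per %MSO, > 0).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("intensity grid must not be empty")
    if beta <= 0:
        raise ValueError("psychometric slope beta must be > 0")
    from scipy.special import expit

    rng = as_rng(seed)
    seen = rng.binomial(n_per_level, expit(beta * (grid - alpha)))
    return MOCSResponses(intensities=grid, n_pulses_per_level=n_per_level, seen=seen)
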