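"""Time-varying effective connectivity: STOK-fitted MVAR and iPDC.

The multi-trial epochs are treated as realizations of a time-varying
multivariate autoregressive process Y_t = sum_k A_{k,t} Y_{t-k} + eps_t.
The self-tuning optimized Kalman (STOK) filter estimates A_{k,t} sample by
sample with recursive least squares across trials, an adaptive forgetting
factor (long memory while the model predicts well, short memory when the
innovation energy spikes) and eigenvalue-truncated inversion of the
regressor covariance for recursive regularization.

From the estimated coefficients the spectral characteristic
B(f, t) = I_d - sum_k A_{k,t} exp(-j 2 pi f k) (f in cycles/sample) yields
the information partial directed coherence

    iPDC_{i<-j}(f, t) = sigma_ii^{-1/2} b_ij(f, t)
                        / sqrt( b_j(f,t)^H  Sigma_eps^{-1}  b_j(f,t) )

whose magnitude is aggregated over analysis windows and a frequency band
into directed weighted adjacency matrices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import EpochsArray, IPDCTensor, SpectralTransfer, TVMVARModel, WindowedNetwork

__all__ = [
    "select_model_order_aic",
    "STOK",
    "stok_fit",
    "spectral_transfer",
    "ipdc",
    "CANONICAL_WINDOW_BOUNDARIES",
    "windows_from_boundaries",
    "aggregate_windows",
    "baseline_normalize",
]

#: Canonical post-stimulus analysis-window boundaries in ms (five windows).
CANONICAL_WINDOW_BOUNDARIES = (12.0, 24.0, 48.0, 92.0, 124.0, 240.0)


def windows_from_boundaries(boundaries=CANONICAL_WINDOW_BOUNDARIES) -> list[tuple[float, float]]:
    """Consecutive half-open [a, b) windows from a boundary list."""
    b = list(boundaries)
    if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
        raise ValueError("boundaries must be strictly increasing, >= 2 values")
    return list(zip(b[:-1], b[1:]))


def _lagged_design(Y: np.ndarray, p: int, start: int | None = None):
    """Stationary pooled design: rows (trial, t), columns (lag, channel).

    ``start`` fixes the first predicted sample so fits of different orders
    share the same target rows (comparable residual covariances).
    """
    N, d, T = Y.shape
    s = p if start is None else max(start, p)
    Z = np.concatenate([Y[:, :, s - k : T - k] for k in range(1, p + 1)], axis=1)
    # (N, p*d, T-s) -> (N*(T-s), p*d)
    Z = Z.transpose(0, 2, 1).reshape(-1, p * d)
    tgt = Y[:, :, s:].transpose(0, 2, 1).reshape(-1, d)
    return Z, tgt


def select_model_order_aic(epochs: EpochsArray, max_order: int) -> int:
    """MVAR order by Akaike's criterion on a stationary pooled fit.

    For each candidate order the model is fitted by least squares pooling
    all trials, and AIC = n log det(Sigma_hat) + 2 q d^2 is minimized.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    Y = epochs.data
    N, d, T = Y.shape
    if T <= 2 * max_order + 1:
        raise ValueError("epochs too short for the requested max_order")
    aic = np.empty(max_order)
    for q in range(1, max_order + 1):
        Z, tgt = _lagged_design(Y, q, start=max_order)
        theta, *_ = np.linalg.lstsq(Z, tgt, rcond=None)
        resid = tgt - Z @ theta
        n = resid.shape[0]
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma + 1e-12 * np.eye(d))
        aic[q - 1] = n * logdet + 2 * q * d * d
    return int(np.argmin(aic)) + 1


class STOK(BaseEstimator):
    """Self-tuning optimized Kalman filter for time-varying MVAR fitting.

    Recursive least squares over trials with exponential forgetting: at
    each sample the regressor covariance R_t and cross-covariance P_t are
    decayed by an adaptive factor lambda_t and refreshed with the current
    trials; the coefficients are Theta_t = R_t^+ P_t with eigenvalues below
    ``sv_threshold`` times the largest truncated (recursive
    regularization).  lambda_t is tuned from the ratio of the current
    innovation energy to its slow running average — a spike in innovations
    (a change in the underlying network) shortens the memory, clipped to
    [lam_min, lam_max].

    Parameters
    ----------
    p : int
        Model order (>= 1).
    lam_min, lam_max : float
        Bounds of the self-tuning forgetting factor.
    sv_threshold : float
        Relative eigenvalue truncation threshold for the pseudo-inverse.
    ratio_scale : float
        Excess innovation ratio mapped onto the full lambda range; the
        sensitivity of the memory decay.
    ratio_deadband : float
        Relative innovation excess ignored as sampling noise before the
        memory starts shortening.
    hold_steps : int
        Number of samples the memory stays pinned at ``lam_min`` after a
        strong innovation spike (refractory adaptation).

    Attributes
    ----------
    model_ : TVMVARModel
        Estimated A_{k,t}, innovation covariance and memory-decay trace.
    """

    def __init__(
        self,
        p: int = 2,
        lam_min: float = 0.95,
        lam_max: float = 0.999,
        sv_threshold: float = 0.01,
        ratio_scale: float = 0.05,
        ratio_deadband: float = 0.03,
        hold_steps: int = 12,
    ):
        self.p = p
        self.lam_min = lam_min
        self.lam_max = lam_max
        self.sv_threshold = sv_threshold
        self.ratio_scale = ratio_scale
        self.ratio_deadband = ratio_deadband
        self.hold_steps = hold_steps

    def fit(self, epochs: EpochsArray):
        if self.p < 1:
            raise ValueError("order p must be >= 1")
        Y = epochs.data
        N, d, T = Y.shape
        if N < 2:
            raise ValueError("the STOK filter needs at least 2 trials")
        if T <= self.p:
            raise ValueError("epochs shorter than the model order")
        p = self.p
        pd_ = p * d
        coeffs = np.zeros((T, p, d, d))
        lam_trace = np.full(T, self.lam_max)
        R = np.zeros((pd_, pd_))
        P = np.zeros((pd_, d))
        Theta = np.zeros((pd_, d))
        e_bar = None  # slow per-channel innovation-energy tracker
        r_smooth = 1.0
        hold = 0
        warmup = p + max(5, 2 * p)
        sig_sum = np.zeros((d, d))
        n_sig = 0
        for t in range(p, T):
            Z = np.concatenate([Y[:, :, t - k] for k in range(1, p + 1)], axis=1)
            Yt = Y[:, :, t]
            E = Yt - Z @ Theta
            e_t = np.sum(E * E, axis=0)  # per-channel innovation energy
            if e_bar is None:
                e_bar = e_t.copy()
            # self-tuning memory decay: the worst channel's innovation
            # energy relative to its slow running average, lightly smoothed;
            # a network change spikes the ratio and shortens the memory
            ratio = float(np.max(e_t / (e_bar + 1e-300)))
            r_smooth = 0.5 * r_smooth + 0.5 * ratio
            excess = max(0.0, max(ratio, r_smooth) - 1.0 - self.ratio_deadband)
            if excess >= self.ratio_scale:
                hold = self.hold_steps  # pin the memory short while adapting
            if hold > 0:
                lam, hold = self.lam_min, hold - 1
            else:
                lam = self.lam_max - (self.lam_max - self.lam_min) * min(
                    1.0, excess / self.ratio_scale
                )
            e_bar = 0.99 * e_bar + 0.01 * e_t
            # convex-combination update: the forgetting rate is exactly
            # (1 - lam) regardless of how much history has accumulated
            R = lam * R + (1.0 - lam) * (Z.T @ Z / N)
            P = lam * P + (1.0 - lam) * (Z.T @ Yt / N)
            w, V = np.linalg.eigh(R)
            keep = w > self.sv_threshold * w[-1]
            if not keep.any():
                raise ValueError(
                    f"regressor covariance numerically null at sample {t}: "
                    f"eigenvalues {w}"
                )
            Theta = (V[:, keep] / w[keep]) @ (V[:, keep].T @ P)
            coeffs[t] = Theta.reshape(p, d, d).transpose(0, 2, 1)
            lam_trace[t] = lam
            if t >= warmup:
                E2 = Yt - Z @ Theta
                sig_sum += E2.T @ E2 / N
                n_sig += 1
        coeffs[:p] = coeffs[p]
        if n_sig == 0:  # very short epochs: use whatever residuals exist
            E2 = Y[:, :, -1] - Z @ Theta
            sig_sum, n_sig = E2.T @ E2 / N, 1
        innov = sig_sum / n_sig
        innov = 0.5 * (innov + innov.T)
        innov += 1e-8 * np.trace(innov) / d * np.eye(d)  # ridge before inversion
        self.model_ = TVMVARModel(
            order=p,
            coeffs=coeffs,
            innov_cov=innov,
            srate=epochs.srate,
            times=epochs.times,
            memory_decay_trace=lam_trace,
            labels=list(epochs.labels),
        )
        return self


def stok_fit(epochs: EpochsArray, p: int, **kwargs) -> TVMVARModel:
    """Functional wrapper over :class:`STOK`."""
    return STOK(p=p, **kwargs).fit(epochs).model_


def spectral_transfer(model: TVMVARModel, freqs) -> SpectralTransfer:
    """B(f, t) = I_d - sum_k A_{k,t} exp(-j 2 pi f k), f in cycles/sample."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid must not be empty")
    if np.any(freqs <= 0) or np.any(freqs >= model.srate / 2):
        raise ValueError("frequencies must lie in (0, srate/2)")
    fc = freqs / model.srate  # cycles per sample
    k = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * fc[:, None] * k[None, :])  # (F, p)
    B = -np.einsum("fk,tkij->ftij", phase, model.coeffs)
    d = model.n_channels
    B[:, :, np.arange(d), np.arange(d)] += 1.0
    return SpectralTransfer(B=B, freqs=freqs, times=model.times,
                            srate=model.srate, labels=model.labels)


def ipdc(transfer: SpectralTransfer, innov_cov: np.ndarray) -> IPDCTensor:
    """|iPDC| magnitudes from the spectral transfer and Sigma_eps.

    With Sigma_eps = sigma^2 I the measure reduces to the column-normalized
    |b_ij| / ||b_j||, so the squared magnitudes sum to 1 over targets for
    every (source, f, t).
    """
    innov_cov = np.asarray(innov_cov, dtype=float)
    d = innov_cov.shape[0]
    if np.linalg.matrix_rank(innov_cov) < d:
        raise ValueError("innovation covariance is singular")
    M = np.linalg.inv(innov_cov)
    B = transfer.B  # (F, T, i, j)
    # Q[f, t, j] = b_j^H Sigma^{-1} b_j  (real, positive)
    Q = np.einsum("ftaj,ab,ftbj->ftj", B.conj(), M, B).real
    sii = np.sqrt(np.diag(innov_cov))
    vals = np.abs(B) / (sii[None, None, :, None] * np.sqrt(Q)[:, :, None, :])
    # reorder to (target i, source j, f, t)
    return IPDCTensor(
        values=vals.transpose(2, 3, 0, 1),
        freqs=transfer.freqs,
        times=transfer.times,
        labels=transfer.labels,
    )


def aggregate_windows(
    tensor: IPDCTensor,
    windows,
    band: tuple[float, float] = (1.0, 40.0),
) -> list[WindowedNetwork]:
    """Mean |iPDC| per directed pair over each time window and the band.

    Windows are half-open [a, b) in ms; the band is inclusive in Hz.  The
    diagonal (self-influence) is zeroed: it is excluded from analysis.
    """
    fmask = (tensor.freqs >= band[0]) & (tensor.freqs <= band[1])
    if not fmask.any():
        raise ValueError(f"band {band} contains no grid frequencies")
    nets = []
    d = tensor.values.shape[0]
    for a, b in windows:
        tmask = (tensor.times >= a) & (tensor.times < b)
        if not tmask.any():
            raise ValueError(f"window [{a}, {b}) ms contains no samples")
        adj = tensor.values[:, :, fmask, :][:, :, :, tmask].mean(axis=(2, 3))
        adj[np.arange(d), np.arange(d)] = 0.0
        nets.append(WindowedNetwork(adjacency=adj, window=(a, b), band=tuple(band),
                                    labels=tensor.labels))
    return nets


def baseline_normalize(
    post_nets: list[WindowedNetwork], pre_net: WindowedNetwork
) -> list[WindowedNetwork]:
    """Subtract the pre-stimulus (basal) network from each window network."""
    out = []
    for net in post_nets:
        if net.adjacency.shape != pre_net.adjacency.shape:
            raise ValueError("pre/post network dimensions differ")
        if tuple(net.band) != tuple(pre_net.band):
            raise ValueError("pre/post networks use different bands")
        out.append(net.copy(adjacency=net.adjacency - pre_net.adjacency))
    return out
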