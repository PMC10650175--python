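"""TMS-evoked potential estimation: Bayesian sweep smoothing and averaging.

Each sweep y is modelled as y = u + v, where the unknown evoked potential u
is an m-fold integrated white-noise process (a smoothness prior; m = 2 by
default) and the background EEG v is an AR process fitted to the
pre-stimulus interval of that same sweep.  The posterior-mean estimate of
u is the linear-Gaussian smoother

    u_hat = (A'A + gamma F'F)^{-1} A'A y

with A the AR whitening matrix, F the m-th difference operator and gamma
the regularization (noise-to-signal variance ratio).  gamma is selected
per sweep by the discrepancy criterion: the whitened residual energy is
matched to its expectation n * sigma^2.  The TEP is the weighted average
of the smoothed sweeps, each weight inversely proportional to the expected
squared norm of that sweep's filter error; conventional averaging (CA) is
the plain arithmetic mean baseline.

The global mean field power GMFP(t) = sqrt(sum_i (V_i(t) - Vmean(t))^2 / K)
summarizes a K-channel estimate as the spatial standard deviation over
channels at each sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .containers import EpochsArray, TEPEstimate

__all__ = [
    "ARNoiseModel",
    "fit_prestim_ar",
    "SmoothedSweep",
    "bayesian_smooth_sweep",
    "weighted_average_sweeps",
    "conventional_average",
    "BayesianTEP",
    "gmfp",
    "compare_gmfp",
]


@dataclass
class ARNoiseModel:
    """AR model of the pre-stimulus background EEG of one sweep."""

    coeffs: np.ndarray  # a_1..a_q
    variance: float  # innovation variance, µV²
    order: int
    fpe_curve: np.ndarray  # FPE per candidate order 1..max_order

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("innovation variance must be > 0")


def _ar_least_squares(x: np.ndarray, q: int, start: int | None = None):
    """LS fit of an AR(q); returns (coefficients, innovation variance).

    ``start`` fixes the first predicted sample so fits of different orders
    share the same target rows (comparable residual variances).
    """
    n = x.size
    s = q if start is None else max(start, q)
    X = np.column_stack([x[s - k - 1 : n - k - 1] for k in range(q)])
    y = x[s:]
    a, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ a
    s2 = float(resid @ resid) / y.size
    return a, s2


def fit_prestim_ar(prestim: np.ndarray, max_order: int = 20) -> ARNoiseModel:
    """Fit an AR model to pre-stimulus EEG, order chosen by minimum FPE.

    The final prediction error FPE(q) = s2_q * (n + q + 1) / (n - q - 1)
    is evaluated for q = 1..max_order; coefficients come from least squares
    on the pre-stimulus samples at the selected order.  If the LS estimate
    is non-stationary the Yule-Walker solution (always stationary for the
    biased autocovariance) is used instead.
    """
    x = np.asarray(prestim, dtype=float)
    if x.size < 5 * max_order:
        raise ValueError("pre-stimulus series too short for max_order")
    x = x - x.mean()
    if np.var(x) < 1e-12:
        raise ValueError("degenerate (near-constant) pre-stimulus series")
    n = x.size
    fpe = np.empty(max_order)
    fits = []
    for q in range(1, max_order + 1):
        # common target rows across orders: residual variances comparable
        a, s2 = _ar_least_squares(x, q, start=max_order)
        fits.append((a, s2))
        fpe[q - 1] = s2 * (n + q + 1) / (n - q - 1)
    order = int(np.argmin(fpe)) + 1
    a, s2 = fits[order - 1]
    s2 = max(s2, 1e-30)
    roots = np.roots(np.concatenate([[1.0], -a]))
    if np.any(np.abs(roots) >= 1.0):
        # fall back to Yule-Walker (guaranteed stationary)
        r = np.array([x[: n - k] @ x[k:] for k in range(order + 1)]) / n
        a = linalg.solve_toeplitz((r[:-1], r[:-1]), r[1:])
        s2 = float(r[0] - a @ r[1:])
        s2 = max(s2, 1e-12)
    return ARNoiseModel(coeffs=a, variance=s2, order=order, fpe_curve=fpe)


@dataclass
class SmoothedSweep:
    """One Bayesian-filtered post-stimulus sweep and its reliability."""

    waveform: np.ndarray  # µV, post-stimulus samples
    expected_err: float  # E ||u - u_hat||^2, µV²

    def __post_init__(self) -> None:
        if self.expected_err <= 0:
            raise ValueError("expected_err must be > 0")


def _difference_operator(n: int, m: int) -> np.ndarray:
    """m-th order difference matrix (n x n, nonsingular lower-triangular)."""
    D = np.eye(n) - np.eye(n, k=-1)
    F = np.eye(n)
    for _ in range(m):
        F = D @ F
    return F


def _whitening_matrix(n: int, coeffs: np.ndarray) -> np.ndarray:
    """AR whitening operator: (A v)_t = v_t - sum_k a_k v_{t-k}."""
    A = np.eye(n)
    for k, a in enumerate(coeffs, start=1):
        A -= a * np.eye(n, k=-k)
    return A


def bayesian_smooth_sweep(
    postim: np.ndarray,
    noise: ARNoiseModel,
    prior_order: int = 2,
    reg="auto",
) -> SmoothedSweep:
    """Posterior-mean estimate of the evoked potential in one sweep.

    Everything is computed in the generalized eigenbasis of (A'A, F'F):
    with A'A V = F'F V diag(s) and c = V^{-1} y, the smoother is
    u_hat = V diag(s / (s + gamma)) c, so any number of candidate gammas
    costs one eigendecomposition.

    Parameters
    ----------
    postim : ndarray
        Post-stimulus samples of the sweep (µV).
    noise : ARNoiseModel
        Background model fitted to the sweep's pre-stimulus interval.
    prior_order : int
        Multiplicity m of the integrated-white-noise prior (m = 2: doubly
        integrated, i.e. a smooth second-order random walk).
    reg : float, "auto" or "discrepancy"
        Regularization gamma >= 0.  "auto" minimizes generalized
        cross-validation GCV(gamma) = (WRSS/n) / (1 - edf/n)^2 on the
        whitened residuals; "discrepancy" matches the whitened residual
        energy to n * sigma^2 (fragile when the sweep is much cleaner than
        the prior expects, kept as an alternative).

    Returns
    -------
    SmoothedSweep
        The smoothed waveform and the expected squared norm of the filter
        error, sigma^2 * trace((A'A + gamma F'F)^{-1}).
    """
    if prior_order < 1:
        raise ValueError("prior_order must be >= 1")
    y = np.asarray(postim, dtype=float)
    n = y.size
    s2 = noise.variance
    A = _whitening_matrix(n, noise.coeffs)
    AtA = A.T @ A
    F = _difference_operator(n, prior_order)
    FtF = F.T @ F
    s, V = linalg.eigh(AtA, FtF)
    s = np.maximum(s, 0.0)
    c = np.linalg.solve(V, y)
    sc2 = s * c * c
    vnorm2 = np.sum(V * V, axis=0)  # tr(M^{-1}) = sum vnorm2 / (s + gamma)

    def whitened_rss(gamma):
        return float(np.sum(sc2 * (gamma / (s + gamma)) ** 2))

    if reg == "auto":

        def gcv(log_g):
            g = 10.0 ** log_g
            edf = np.sum(s / (s + g))
            return whitened_rss(g) / n / (1.0 - edf / n) ** 2

        res = optimize.minimize_scalar(gcv, bounds=(-6.0, 6.0), method="bounded")
        gamma = 10.0 ** res.x
    elif reg == "discrepancy":
        target = n * s2
        lo, hi = -8.0, 8.0
        if whitened_rss(10.0 ** hi) <= target:
            gamma = 10.0 ** hi
        elif whitened_rss(10.0 ** lo) >= target:
            gamma = 10.0 ** lo
        else:
            gamma = 10.0 ** optimize.brentq(
                lambda lg: whitened_rss(10.0 ** lg) - target, lo, hi, xtol=1e-3
            )
    else:
        gamma = float(reg)
        if gamma < 0:
            raise ValueError("reg must be nonnegative")
    u = V @ (s / (s + gamma) * c) if gamma > 0 else y.copy()
    err = s2 * float(np.sum(vnorm2 / (s + gamma)))
    return SmoothedSweep(waveform=u, expected_err=max(err, 1e-300))


def weighted_average_sweeps(sweeps: list[SmoothedSweep]) -> np.ndarray:
    """Reliability-weighted average: w_s ∝ 1 / expected_err_s, normalized."""
    if not sweeps:
        raise ValueError("need at least one sweep")
    inv = np.array([1.0 / s.expected_err for s in sweeps])
    w = inv / inv.sum()
    wave = np.sum([wi * s.waveform for wi, s in zip(w, sweeps)], axis=0)
    return wave, w


def conventional_average(epochs: EpochsArray) -> TEPEstimate:
    """Conventional averaging: per-channel arithmetic mean over trials."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    post = epochs.postim_mask()
    return TEPEstimate(
        waveform=epochs.data[:, :, post].mean(axis=0),
        times=epochs.times[post],
        method="CA",
        labels=list(epochs.labels),
    )


class BayesianTEP(BaseEstimator):
    """Sweep-by-sweep Bayesian TEP estimator (sklearn-style).

    Each channel is processed independently: per sweep, an AR background
    model is fitted to the pre-stimulus samples, the post-stimulus samples
    are smoothed under the integrated-white-noise prior, and the channel
    TEP is the inverse-error-weighted average of the smoothed sweeps.

    Parameters
    ----------
    prior_order : int
        Multiplicity of the integrated-white-noise prior (default 2).
    max_ar_order : int
        Upper bound of the FPE order search for the background AR model.
    reg : float or "auto"
        Per-sweep regularization; "auto" = discrepancy criterion.

    Attributes
    ----------
    tep_ : TEPEstimate
        The estimated evoked potential (method "Bayes") with per-sweep
        weights.
    """

    def __init__(self, prior_order: int = 2, max_ar_order: int = 15, reg="auto"):
        self.prior_order = prior_order
        self.max_ar_order = max_ar_order
        self.reg = reg

    def fit(self, epochs: EpochsArray):
        if epochs.n_trials < 1:
            raise ValueError("need at least one trial")
        pre = epochs.prestim_mask()
        post = epochs.postim_mask()
        if not pre.any():
            raise ValueError("Bayesian smoothing needs pre-stimulus samples")
        waves = np.empty((epochs.n_channels, int(post.sum())))
        weights = np.empty((epochs.n_channels, epochs.n_trials))
        for c in range(epochs.n_channels):
            sweeps = []
            for s in range(epochs.n_trials):
                noise = fit_prestim_ar(epochs.data[s, c, pre], self.max_ar_order)
                sweeps.append(
                    bayesian_smooth_sweep(
                        epochs.data[s, c, post], noise,
                        prior_order=self.prior_order, reg=self.reg,
                    )
                )
            waves[c], weights[c] = weighted_average_sweeps(sweeps)
        self.tep_ = TEPEstimate(
            waveform=waves, times=epochs.times[post], method="Bayes",
            labels=list(epochs.labels), weights=weights,
        )
        return self


def gmfp(tep) -> np.ndarray:
    """Global mean field power: spatial SD over channels per sample.

    Accepts a TEPEstimate or a (channels × samples) array; returns a
    nonnegative series in µV, zero wherever all channels agree.  A single
    channel yields the all-zero series (warned: the spatial SD is
    degenerate).
    """
    V = tep.waveform if isinstance(tep, TEPEstimate) else np.asarray(tep, float)
    if V.ndim != 2:
        raise ValueError("expected channels × samples")
    if V.shape[0] < 2:
        import warnings

        warnings.warn("GMFP of a single channel is identically zero", stacklevel=2)
        return np.zeros(V.shape[1])
    return np.sqrt(np.mean((V - V.mean(axis=0, keepdims=True)) ** 2, axis=0))


def compare_gmfp(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    """Paired per-sample Wilcoxon comparison of two GMFP conditions.

    Parameters
    ----------
    a, b : ndarray, shape (n_subjects, n_samples)
        Per-subject GMFP series under the two estimators/conditions.
    alpha : float
        Significance level after Bonferroni correction over samples.

    Returns
    -------
    mask : ndarray of bool
        Samples where the Bonferroni-corrected p is below ``alpha``.
    p_corrected : ndarray
        The corrected p-values (clipped at 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired GMFP arrays must share their shape")
    n_subj, n_samp = a.shape
    if n_subj < 5:
        raise ValueError("paired Wilcoxon needs at least 5 subjects")
    p = np.ones(n_samp)
    for t in range(n_samp):
        diff = a[:, t] - b[:, t]
        if np.all(diff == 0):
            continue
        p[t] = stats.wilcoxon(a[:, t], b[:, t], zero_method="wilcox").pvalue
    p_corr = np.minimum(p * n_samp, 1.0)
    return p_corr < alpha, p_corr
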