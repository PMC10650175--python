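"""Phosphene-threshold estimation from Method of Constant Stimuli data.

A two-parameter cumulative logistic P(seen | I) = 1 / (1 + exp(-beta (I -
alpha))) is fitted to per-intensity report counts by maximum likelihood;
the phosphene threshold (PT) is the intensity at which the fitted function
crosses a criterion probability (0.5 by default, at which it equals alpha
exactly).  No guess or lapse rates are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .containers import MOCSResponses

__all__ = [
    "intensity_grid",
    "PT_GRID",
    "PsychometricFit",
    "LogisticPsychometric",
    "fit_logistic_mle",
    "derive_pt",
]


def intensity_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic intensity sequence in %MSO.

    Rejects ranges not divisible by the step (the endpoint would be
    ambiguous).  ``intensity_grid(60, 78, 3)`` is the canonical 7-level
    grid.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    n = (hi - lo) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"range {hi - lo} is not divisible by step {step}")
    return lo + step * np.arange(int(round(n)) + 1)


#: The study's MOCS grid: 60..78 %MSO in steps of 3 (7 levels).
PT_GRID = intensity_grid(60.0, 78.0, 3.0)


@dataclass
class PsychometricFit:
    """Fitted two-parameter logistic psychometric function."""

    alpha: float  # %MSO location (50% point)
    beta: float  # slope, per %MSO
    loglik: float
    converged: bool
    flags: tuple[str, ...] = ()

    def predict(self, intensity) -> np.ndarray:
        return special.expit(self.beta * (np.asarray(intensity, float) - self.alpha))


class LogisticPsychometric(BaseEstimator):
    """Maximum-likelihood logistic psychometric fit (sklearn-style).

    Parameters
    ----------
    max_beta : float
        Upper bound on the slope; a solution at the bound is flagged as
        separation (the MLE diverges on perfectly separated data).

    Attributes
    ----------
    alpha_, beta_ : float
        Location (%MSO) and slope (per %MSO) of the fitted logistic.
    loglik_ : float
        Binomial log-likelihood at the optimum (includes the binomial
        coefficients, hence <= 0).
    converged_ : bool
    flags_ : tuple of str
        Diagnostic flags: "separation", "flat-proportions", "optimizer".
    """

    def __init__(self, max_beta: float = 50.0):
        self.max_beta = max_beta

    def fit(self, intensities, seen, n_per_level: int):
        I = np.asarray(intensities, dtype=float)
        k = np.asarray(seen, dtype=float)
        n = float(n_per_level)
        if I.size < 2:
            raise ValueError("need at least two intensity levels")
        prop = k / n
        flags: list[str] = []

        if np.ptp(prop) == 0:
            # flat observed proportions: alpha (and for 0/1 data beta) is
            # unidentifiable -- no silent estimate
            flags.append("flat-proportions")
            self.alpha_, self.beta_ = float(np.median(I)), 0.0
            self.loglik_ = float(
                np.sum(stats.binom.logpmf(k, n, np.clip(prop.mean(), 1e-12, 1 - 1e-12)))
            )
            self.converged_ = False
            self.flags_ = tuple(flags)
            return self

        separated = bool(np.all((prop == 0) | (prop == 1)))

        # moment-based initialization: alpha from the interpolated 50%
        # crossing, beta from the intensity range
        above = np.flatnonzero(prop >= 0.5)
        if above.size and above[0] > 0:
            j = above[0]
            p0, p1 = prop[j - 1], prop[j]
            frac = (0.5 - p0) / (p1 - p0) if p1 > p0 else 0.5
            alpha0 = I[j - 1] + frac * (I[j] - I[j - 1])
        else:
            alpha0 = float(np.median(I))
        beta0 = 4.0 / max(np.ptp(I), 1.0)

        lnC = special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)

        def nll(theta):
            a, log_b = theta
            z = np.exp(log_b) * (I - a)
            # stable binomial log-likelihood: k*log(p) + (n-k)*log(1-p)
            ll = lnC + k * (-np.logaddexp(0.0, -z)) + (n - k) * (-np.logaddexp(0.0, z))
            return -np.sum(ll)

        res = optimize.minimize(
            nll,
            x0=[alpha0, np.log(beta0)],
            method="L-BFGS-B",
            bounds=[(I.min() - 5 * np.ptp(I), I.max() + 5 * np.ptp(I)),
                    (np.log(1e-6), np.log(self.max_beta))],
        )
        self.alpha_ = float(res.x[0])
        self.beta_ = float(np.exp(res.x[1]))
        self.loglik_ = float(-res.fun)
        ok = bool(res.success)
        if not res.success:
            flags.append("optimizer")
        if separated or self.beta_ >= 0.99 * self.max_beta:
            flags.append("separation")
            ok = False
        self.converged_ = ok
        self.flags_ = tuple(flags)
        return self

    def predict_proba(self, intensity) -> np.ndarray:
        return special.expit(self.beta_ * (np.asarray(intensity, float) - self.alpha_))

    def threshold(self, criterion: float = 0.5) -> float:
        """Intensity at which the fitted function equals ``criterion``."""
        if not 0.0 < criterion < 1.0:
            raise ValueError("criterion must lie in (0, 1)")
        if not self.converged_:
            raise ValueError(f"fit did not converge (flags: {self.flags_})")
        return self.alpha_ + np.log(criterion / (1.0 - criterion)) / self.beta_


def fit_logistic_mle(responses: MOCSResponses) -> PsychometricFit:
    """Fit the psychometric function to a MOCS session by maximum likelihood."""
    est = LogisticPsychometric().fit(
        responses.intensities, responses.seen, responses.n_pulses_per_level
    )
    return PsychometricFit(
        alpha=est.alpha_, beta=est.beta_, loglik=est.loglik_,
        converged=est.converged_, flags=est.flags_,
    )


def derive_pt(fit: PsychometricFit, criterion: float = 0.5) -> float:
    """Phosphene threshold: intensity at the criterion detection probability.

    For the two-parameter logistic at criterion 0.5 this equals ``alpha``
    exactly.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must lie in (0, 1)")
    if not fit.converged:
        raise ValueError(f"cannot derive PT from a non-converged fit (flags: {fit.flags})")
    return fit.alpha + float(np.log(criterion / (1.0 - criterion))) / fit.beta
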