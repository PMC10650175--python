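"""Shared small utilities: ms <-> sample conversion and RNG normalization."""

from __future__ import annotations

import numpy as np

__all__ = ["ms_to_sample", "time_axis", "as_rng"]


def ms_to_sample(times: np.ndarray, t_ms: float) -> int:
    """Index of the sample nearest to ``t_ms`` on a ms time axis.

    All ms -> sample conversions in the package go through this rule
    (round to nearest sample).
    """
    return int(np.argmin(np.abs(np.asarray(times) - t_ms)))


def time_axis(start_ms: float, stop_ms: float, srate: float) -> np.ndarray:
    """Uniform ms axis from start to stop inclusive at 1000/srate spacing.

    The axis always contains an exact t = 0 sample when start <= 0 <= stop.
    """
    step = 1000.0 / srate
    n_pre = int(round(-start_ms / step)) if start_ms < 0 else 0
    n_post = int(round(stop_ms / step)) if stop_ms > 0 else 0
    if start_ms >= 0:  # purely post-stimulus axis
        k0 = int(round(start_ms / step))
        return step * np.arange(k0, n_post + 1)
    return step * np.arange(-n_pre, n_post + 1)


def as_rng(seed) -> np.random.Generator:
    """Normalize an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
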