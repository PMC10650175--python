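"""Paired nonparametric contrasts between stimulation conditions.

All contrasts use the Wilcoxon signed-rank test on per-subject paired
values: per GMFP sample (Bonferroni-corrected, alpha 0.05), per connectivity
edge and per graph metric (uncorrected, alpha 0.001), with signed reporting
of the direction (condition A stronger vs condition B stronger).  Zero
differences are discarded before ranking (classical treatment); the exact
null distribution is used for n <= 25 pairs and the normal approximation
with continuity correction beyond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .connectivity import CANONICAL_WINDOW_BOUNDARIES, windows_from_boundaries
from .containers import WindowedNetwork

__all__ = [
    "StatContrast",
    "wilcoxon_paired",
    "contrast_edges",
    "contrast_degrees",
    "windows_from_gmfp_peaks",
]

logger = logging.getLogger(__name__)


@dataclass
class StatContrast:
    """Signed result of one paired Wilcoxon contrast."""

    statistic: float
    p: float
    direction: str  # "<A>><B>", "<B>><A>" or "none"
    alpha: float
    n: int
    corrected: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def wilcoxon_paired(
    x, y, alpha: float = 0.05, labels: tuple[str, str] = ("A", "B"),
    corrected: bool = False,
) -> StatContrast:
    """Two-sided paired Wilcoxon signed-rank test with signed direction.

    Zero differences are removed before ranking; at least 5 nonzero pairs
    are required.  Direction is the sign of the median difference, reported
    only when the test is significant at ``alpha`` (otherwise "none").
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d paired samples")
    diff = x - y
    nz = diff[diff != 0]
    if nz.size == 0:
        return StatContrast(statistic=0.0, p=1.0, direction="none",
                            alpha=alpha, n=0, corrected=corrected)
    if nz.size < 5:
        raise ValueError("paired Wilcoxon needs >= 5 nonzero differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", method=method,
                         correction=(method == "approx"))
    med = np.median(nz)
    if res.pvalue < alpha and med != 0:
        direction = f"{labels[0]}>{labels[1]}" if med > 0 else f"{labels[1]}>{labels[0]}"
    else:
        direction = "none"
    return StatContrast(statistic=float(res.statistic), p=float(res.pvalue),
                        direction=direction, alpha=alpha, n=int(nz.size),
                        corrected=corrected)


def contrast_edges(
    nets_a: list[list[WindowedNetwork]],
    nets_b: list[list[WindowedNetwork]],
    alpha: float = 0.001,
    labels: tuple[str, str] = ("O1", "O2"),
) -> pd.DataFrame:
    """Per-edge, per-window signed Wilcoxon contrast of two conditions.

    Parameters
    ----------
    nets_a, nets_b : list over subjects of lists over windows
        Per-subject windowed networks; condition B must already be flipped
        into the condition-A frame, with identical window sets.
    alpha : float
        Uncorrected significance level (0.001 for edge-level contrasts).

    Returns
    -------
    DataFrame with columns (window_start, window_end, target, source,
    statistic, p, sign); ``sign`` is +1 where A > B, -1 where B > A,
    containing only the significant edges.
    """
    if len(nets_a) != len(nets_b):
        raise ValueError("conditions must have the same subjects, in order")
    if len(nets_a) == 0:
        raise ValueError("need at least one subject")
    n_win = len(nets_a[0])
    for nets in (*nets_a, *nets_b):
        if len(nets) != n_win:
            raise ValueError("all subjects must share the same windows")
    rows = []
    d = nets_a[0][0].n_nodes
    names = nets_a[0][0].labels or [str(i) for i in range(d)]
    for w in range(n_win):
        win = nets_a[0][w].window
        A = np.stack([nets[w].adjacency for nets in nets_a])  # (subj, d, d)
        B = np.stack([nets[w].adjacency for nets in nets_b])
        for i in range(d):
            for j in range(d):
                if i == j:
                    continue
                try:
                    c = wilcoxon_paired(A[:, i, j], B[:, i, j], alpha=alpha,
                                        labels=labels)
                except ValueError:
                    # fewer than 5 nonzero differences: untestable edge
                    continue
                if c.significant and c.direction != "none":
                    rows.append({
                        "window_start": win[0], "window_end": win[1],
                        "target": names[i], "source": names[j],
                        "statistic": c.statistic, "p": c.p,
                        "sign": 1 if c.direction == f"{labels[0]}>{labels[1]}" else -1,
                    })
    return pd.DataFrame(
        rows, columns=["window_start", "window_end", "target", "source",
                       "statistic", "p", "sign"],
    )


def contrast_degrees(
    deg_a: dict,
    deg_b: dict,
    alpha: float = 0.001,
    labels: tuple[str, str] = ("O1", "O2"),
) -> pd.DataFrame:
    """Per (macro-area, window) signed contrast of pooled degree values.

    Parameters
    ----------
    deg_a, deg_b : dict
        ``{window: {area: values (n_subjects, n_electrodes)}}``; pooled
        values are paired on (subject, electrode) across conditions.

    Returns
    -------
    DataFrame with one row per (window, area): statistic, p, significant,
    sign.
    """
    if deg_a.keys() != deg_b.keys():
        raise ValueError("conditions must share their windows")
    rows = []
    for win in deg_a:
        if deg_a[win].keys() != deg_b[win].keys():
            raise ValueError("conditions must share their macro areas")
        for area in deg_a[win]:
            a = np.asarray(deg_a[win][area], float)
            b = np.asarray(deg_b[win][area], float)
            if a.size == 0 or b.size == 0:
                raise ValueError(f"empty degree pool for area {area!r}")
            if a.ndim < 2 or a.shape[0] < 2:
                raise ValueError("degree contrasts need multiple subjects")
            try:
                c = wilcoxon_paired(a.ravel(), b.ravel(), alpha=alpha, labels=labels)
            except ValueError:
                c = StatContrast(statistic=np.nan, p=np.nan, direction="none",
                                 alpha=alpha, n=0)
            rows.append({
                "window_start": win[0], "window_end": win[1], "area": area,
                "statistic": c.statistic, "p": c.p,
                "significant": c.significant,
                "sign": {f"{labels[0]}>{labels[1]}": 1,
                         f"{labels[1]}>{labels[0]}": -1}.get(c.direction, 0),
            })
    return pd.DataFrame(rows)


def windows_from_gmfp_peaks(
    gmfp_values: np.ndarray,
    times: np.ndarray,
    bounds: tuple[float, float] = (12.0, 240.0),
    explicit_boundaries=None,
) -> list[tuple[float, float]]:
    """Analysis windows centred on GMFP peaks within ``bounds``.

    Local maxima of the GMFP inside the bounds define window centres;
    boundaries are the midpoints between consecutive peaks, clipped to the
    bounds.  If ``explicit_boundaries`` is given it overrides peak
    detection entirely; if no peaks are found the canonical boundaries
    (12/24/48/92/124/240 ms) are used as a logged fallback.
    """
    if explicit_boundaries is not None:
        return windows_from_boundaries(explicit_boundaries)
    times = np.asarray(times, float)
    g = np.asarray(gmfp_values, float)
    if times[0] > bounds[0] or times[-1] < bounds[1]:
        raise ValueError("GMFP series does not cover the requested bounds")
    mask = (times >= bounds[0]) & (times <= bounds[1])
    peaks, _ = signal.find_peaks(g[mask])
    peak_times = times[mask][peaks]
    if peak_times.size == 0:
        logger.warning("no GMFP peaks in %s ms; falling back to canonical windows",
                       bounds)
        return windows_from_boundaries(CANONICAL_WINDOW_BOUNDARIES)
    mids = (peak_times[:-1] + peak_times[1:]) / 2.0
    boundaries = [bounds[0], *mids, bounds[1]]
    return windows_from_boundaries(boundaries)
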