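"""Deterministic signal conditioning for TMS-EEG epochs.

The chain mirrors the conventional TMS-EEG workflow: segmentation around
the pulse, cubic interpolation over the pulse-artifact window (-2..10 ms),
anti-aliased downsampling to 500 Hz, zero-phase Butterworth filtering
(band-pass 0.1-100 Hz, 49-51 Hz notch, 40 Hz low-pass) and pre-stimulus
demeaning.  Artifact-component removal (ICA), re-referencing and automatic
trial rejection are out of scope: the pipeline accepts already-cleaned
epochs.

All window conventions are closed on both ends in ms; ms -> sample mapping
rounds to the nearest sample.  "Zero-phase fourth-order Butterworth" means
an order-4 design applied forward-backward (zero group delay, effective
order-8 magnitude response).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._utils import ms_to_sample
from .containers import EpochsArray

__all__ = [
    "FilterSpec",
    "segment_epochs",
    "interpolate_pulse_window",
    "resample_epochs",
    "apply_filter",
    "demean_prestim",
    "read_continuous",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Butterworth filter description.

    kind : {"bandpass", "bandstop", "lowpass"}
    order : design order (applied forward-backward when zero_phase)
    band : Hz edge(s) -- two edges for bandpass/bandstop, one for lowpass
    """

    kind: str
    band: tuple[float, ...]
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"bandpass", "bandstop", "lowpass"}:
            raise ValueError("kind must be bandpass, bandstop or lowpass")
        n_edges = 1 if self.kind == "lowpass" else 2
        if len(self.band) != n_edges:
            raise ValueError(f"{self.kind} needs {n_edges} band edge(s)")
        if self.zero_phase and self.order % 2:
            raise ValueError("zero-phase application requires an even order")


def segment_epochs(
    continuous: np.ndarray,
    srate: float,
    pulse_samples,
    labels: list[str],
    pre_ms: float = 1000.0,
    post_ms: float = 1000.0,
    stim_site: str = "none",
) -> EpochsArray:
    """Cut stimulus-locked epochs out of a continuous recording.

    Each epoch spans ``pre_ms`` before to ``post_ms`` after its pulse
    sample inclusive (at 5000 Hz and ±1000 ms: 10,001 samples, t = 0 at the
    pulse).  Events without enough surrounding data are skipped and logged.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_pre = int(round(pre_ms * srate / 1000.0))
    n_post = int(round(post_ms * srate / 1000.0))
    total = continuous.shape[1]
    kept, trials = [], []
    for ev in pulse_samples:
        ev = int(ev)
        if ev - n_pre < 0 or ev + n_post >= total:
            logger.warning("event at sample %d too close to recording edge; skipped", ev)
            continue
        trials.append(continuous[:, ev - n_pre : ev + n_post + 1])
        kept.append(ev)
    data = (
        np.stack(trials, axis=0)
        if trials
        else np.empty((0, continuous.shape[0], n_pre + n_post + 1))
    )
    times = (np.arange(-n_pre, n_post + 1)) * 1000.0 / srate
    return EpochsArray(data=data, srate=srate, times=times, labels=labels,
                       stim_site=stim_site)


def interpolate_pulse_window(
    epochs: EpochsArray,
    from_ms: float = -2.0,
    to_ms: float = 10.0,
    support: int = 20,
) -> EpochsArray:
    """Replace the pulse-artifact window with a cubic fit through its flanks.

    Samples with t in [from_ms, to_ms] (closed, nearest-sample) are
    replaced, per channel and per trial, by a cubic polynomial fitted by
    least squares to ``support`` samples on each side of the window; all
    other samples are returned bit-identical.
    """
    i0 = ms_to_sample(epochs.times, from_ms)
    i1 = ms_to_sample(epochs.times, to_ms)
    n = epochs.n_samples
    if i0 <= 0 and i1 >= n - 1:
        raise ValueError("interpolation window covers the entire epoch")
    left = np.arange(max(i0 - support, 0), i0)
    right = np.arange(i1 + 1, min(i1 + 1 + support, n))
    flank = np.concatenate([left, right])
    if flank.size < 4:
        raise ValueError("not enough flanking samples for a cubic fit")
    inside = np.arange(i0, i1 + 1)
    # centre/scale the abscissa for conditioning; one pseudo-inverse serves
    # every trial and channel
    x0, sc = epochs.times[i1], max(np.ptp(epochs.times[flank]), 1.0)
    xf = (epochs.times[flank] - x0) / sc
    xi = (epochs.times[inside] - x0) / sc
    V = np.vander(xf, 4)
    Vi = np.vander(xi, 4)
    coef = np.linalg.pinv(V) @ epochs.data[:, :, flank].reshape(-1, flank.size).T
    fitted = (Vi @ coef).T.reshape(epochs.n_trials, epochs.n_channels, inside.size)
    data = epochs.data.copy()
    data[:, :, inside] = fitted
    return epochs.copy(data=data)


def resample_epochs(epochs: EpochsArray, new_srate: float = 500.0) -> EpochsArray:
    """Anti-aliased downsampling that preserves the t = 0 sample.

    The decimation factor ``srate / new_srate`` must be an integer and the
    t = 0 sample index must be divisible by it, so the pulse-locked sample
    survives decimation.  A 10,001-sample epoch at 5000 Hz becomes 1001
    samples at 500 Hz (endpoints kept).  A handful of samples at the epoch
    edges carry the anti-alias FIR transient; analysis windows are
    interior, so these are left in place.
    """
    if new_srate >= epochs.srate:
        raise ValueError("new_srate must be lower than the current rate")
    q = epochs.srate / new_srate
    if abs(q - round(q)) > 1e-9:
        raise ValueError("srate must be an integer multiple of new_srate")
    q = int(round(q))
    t0 = ms_to_sample(epochs.times, 0.0)
    if t0 % q:
        raise ValueError("t = 0 sample would not survive decimation")
    data = signal.decimate(epochs.data, q, axis=2, ftype="fir", zero_phase=True)
    return EpochsArray(
        data=data, srate=new_srate, times=epochs.times[::q],
        labels=list(epochs.labels), stim_site=epochs.stim_site,
    )


def apply_filter(epochs: EpochsArray, spec: FilterSpec) -> EpochsArray:
    """Apply a Butterworth filter along time (zero-phase by default)."""
    nyq = epochs.srate / 2.0
    if any(not 0.0 < e < nyq for e in spec.band):
        raise ValueError(f"band edges {spec.band} outside (0, {nyq}) Hz")
    btype = {"bandpass": "bandpass", "bandstop": "bandstop", "lowpass": "lowpass"}[spec.kind]
    Wn = spec.band if len(spec.band) > 1 else spec.band[0]
    sos = signal.butter(spec.order, Wn, btype=btype, fs=epochs.srate, output="sos")
    poles = signal.sos2zpk(sos)[1]
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(
            f"unstable design: order-{spec.order} {spec.kind} at {spec.band} Hz "
            f"(max pole modulus {np.max(np.abs(poles)):.6f})"
        )
    if spec.zero_phase:
        data = signal.sosfiltfilt(sos, epochs.data, axis=2)
    else:
        data = signal.sosfilt(sos, epochs.data, axis=2)
    return epochs.copy(data=np.ascontiguousarray(data))


def demean_prestim(epochs: EpochsArray) -> EpochsArray:
    """Subtract the pre-stimulus mean from each sweep, per channel.

    After the operation the mean over t < 0 is zero for every trial and
    channel; applying it twice equals applying it once.
    """
    pre = epochs.prestim_mask()
    if not pre.any():
        raise ValueError("epochs contain no pre-stimulus samples")
    baseline = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - baseline)


def read_continuous(path):
    """Read a continuous BrainVision (.vhdr) or EDF recording via MNE.

    Returns ``(data_µV (channels × samples), srate, labels)``.  Requires
    the optional ``mne`` dependency.
    """
    import mne

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)
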