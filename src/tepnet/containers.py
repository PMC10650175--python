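"""Core in-memory containers shared across the pipeline.

All voltages are in microvolts (µV), all times in milliseconds relative to
the TMS pulse (t = 0 at the pulse), all frequencies in Hz.  Epoched data are
stored trials × channels × samples, matching the multi-trial realization
view of the EEG used by the time-varying MVAR machinery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "EpochsArray",
    "GroundTruthTVMVAR",
    "SessionPlan",
    "MOCSResponses",
    "TVMVARModel",
    "SpectralTransfer",
    "IPDCTensor",
    "WindowedNetwork",
    "TEPEstimate",
    "companion_spectral_radius",
]


def _uniform_times(times: np.ndarray, srate: float) -> bool:
    if times.ndim != 1 or times.size < 2:
        return times.ndim == 1
    dt = np.diff(times)
    return bool(np.allclose(dt, 1000.0 / srate, rtol=1e-6, atol=1e-9))


@dataclass
class EpochsArray:
    """Stimulus-locked epoched EEG: trials × channels × samples in µV.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltages in µV.
    srate : float
        Sampling rate in samples/s.
    times : ndarray, shape (n_samples,)
        Time axis in ms, t = 0 at the TMS pulse, uniformly spaced at
        ``1000 / srate`` ms.
    labels : list of str
        10-10 system channel names, unique, one per channel.
    stim_site : {"O1", "O2", "none"}
        Stimulated electrode site.
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    labels: list[str]
    stim_site: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = [str(l) for l in self.labels]
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length must match the sample dimension")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("number of labels must equal channel dimension")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not _uniform_times(self.times, self.srate):
            raise ValueError("times must be uniform at 1000/srate ms spacing")
        if self.stim_site not in {"O1", "O2", "none"}:
            raise ValueError("stim_site must be one of {'O1', 'O2', 'none'}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def prestim_mask(self) -> np.ndarray:
        """Boolean mask of pre-stimulus samples (t < 0)."""
        return self.times < 0

    def postim_mask(self) -> np.ndarray:
        """Boolean mask of post-stimulus samples (t >= 0, pulse included)."""
        return self.times >= 0

    def copy(self, data: np.ndarray | None = None) -> "EpochsArray":
        return EpochsArray(
            data=self.data.copy() if data is None else data,
            srate=self.srate,
            times=self.times.copy(),
            labels=list(self.labels),
            stim_site=self.stim_site,
        )

    # -- hierarchical container IO -------------------------------------
    def to_hdf5(self, path) -> None:
        """Write to an HDF5 file with layout /data /times /labels /srate /stim_site."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset(
                "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
            )
            f.create_dataset("srate", data=float(self.srate))
            f.create_dataset("stim_site", data=self.stim_site)

    @classmethod
    def from_hdf5(cls, path) -> "EpochsArray":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                srate=float(f["srate"][()]),
                times=f["times"][()],
                labels=[s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["labels"][()]],
                stim_site=(lambda s: s.decode() if isinstance(s, bytes) else str(s))(
                    f["stim_site"][()]
                ),
            )

    def to_mne(self):
        """Convert to an :class:`mne.EpochsArray` (volts, seconds). Requires mne."""
        import mne

        info = mne.create_info(self.labels, self.srate, ch_types="eeg")
        return mne.EpochsArray(
            self.data * 1e-6, info, tmin=self.times[0] / 1000.0, verbose="error"
        )


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix for lag matrices ``A``.

    Parameters
    ----------
    A : ndarray, shape (p, d, d)
        AR matrices A_1..A_p; the process is stable iff the return value < 1.
    """
    A = np.asarray(A, dtype=float)
    p, d, _ = A.shape
    comp = np.zeros((p * d, p * d))
    comp[:d, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[d:, : (p - 1) * d] = np.eye((p - 1) * d)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GroundTruthTVMVAR:
    """Known time-varying VAR generator: A_{k,t}, innovation covariance, rate.

    ``coeffs`` has shape (n_samples, p, d, d); ``coeffs[t, k-1]`` is A_{k,t}.
    Stability (companion spectral radius < 1 at every t) and a symmetric
    positive-definite noise covariance are enforced at construction.
    """

    order: int
    coeffs: np.ndarray
    noise_cov: np.ndarray
    srate: float
    change_points: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[1] != self.order:
            raise ValueError("coeffs must be (n_samples, p, d, d)")
        d = self.coeffs.shape[2]
        if self.coeffs.shape[3] != d or self.noise_cov.shape != (d, d):
            raise ValueError("inconsistent channel dimension")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.noise_cov)) <= 0:
            raise ValueError("noise_cov must be positive-definite")
        # stability only needs checking where the coefficients change
        check_at = [0] + [t for t in self.change_points if 0 < t < len(self.coeffs)]
        for t in check_at:
            rho = companion_spectral_radius(self.coeffs[t])
            if rho >= 1.0:
                raise ValueError(
                    f"unstable tvMVAR at sample {t}: companion spectral radius {rho:.3f} >= 1"
                )

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class SessionPlan:
    """Trial structure of one stimulation session.

    Defaults mirror the experimental protocol: 6 blocks of 60 trials
    (360 pulses), a 700–1000 ms random pre-interval, a 2000 ms response
    window and a 1300 ms inter-trial interval.
    """

    n_blocks: int = 6
    trials_per_block: int = 60
    pre_interval: tuple[float, float] = (700.0, 1000.0)
    response_window: float = 2000.0
    iti: float = 1300.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("block counts must be positive")
        lo, hi = self.pre_interval
        if lo <= 0 or hi < lo or self.response_window <= 0 or self.iti <= 0:
            raise ValueError("all durations must be positive")

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class MOCSResponses:
    """Phosphene reports from a Method of Constant Stimuli session."""

    intensities: np.ndarray  # % of maximum stimulator output, strictly increasing
    n_pulses_per_level: int
    seen: np.ndarray  # count of "phosphene present" reports per level

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.seen = np.asarray(self.seen, dtype=int)
        if self.intensities.size != self.seen.size:
            raise ValueError("intensities and seen must have equal length")
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if self.n_pulses_per_level < 1:
            raise ValueError("n_pulses_per_level must be positive")
        if np.any(self.seen < 0) or np.any(self.seen > self.n_pulses_per_level):
            raise ValueError("seen counts must be within [0, n_pulses_per_level]")

    @property
    def proportions(self) -> np.ndarray:
        return self.seen / self.n_pulses_per_level


@dataclass
class TVMVARModel:
    """Estimated time-varying MVAR model Y_t = sum_k A_{k,t} Y_{t-k} + eps_t.

    ``coeffs`` has shape (n_samples, p, d, d) with ``coeffs[t, k-1] = A_{k,t}``;
    ``innov_cov`` is the innovation covariance Sigma_eps in µV².
    """

    order: int
    coeffs: np.ndarray
    innov_cov: np.ndarray
    srate: float
    times: np.ndarray
    memory_decay_trace: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.innov_cov = np.asarray(self.innov_cov, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coefficients must be finite")
        if not np.allclose(self.innov_cov, self.innov_cov.T):
            raise ValueError("innov_cov must be symmetric")
        if np.min(np.linalg.eigvalsh(self.innov_cov)) <= 0:
            raise ValueError("innov_cov must be positive-definite")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]


@dataclass
class SpectralTransfer:
    """Spectral characteristic B(f, t) = I_d - sum_k A_{k,t} e^{-j 2 pi f k}.

    ``B`` has shape (n_freqs, n_samples, d, d), complex; ``freqs`` in Hz.
    """

    B: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    srate: float
    labels: list[str] | None = None


@dataclass
class IPDCTensor:
    """|iPDC| magnitudes, indexed (target i, source j, frequency, time)."""

    values: np.ndarray  # (d, d, n_freqs, n_samples), nonnegative
    freqs: np.ndarray
    times: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("|iPDC| values must be finite and nonnegative")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("ipdc", data=self.values)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            if self.labels is not None:
                f.create_dataset(
                    "labels", data=np.array(self.labels, dtype=h5py.string_dtype())
                )

    @classmethod
    def from_hdf5(cls, path) -> "IPDCTensor":
        with h5py.File(path, "r") as f:
            labels = None
            if "labels" in f:
                labels = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["labels"][()]]
            return cls(
                values=f["ipdc"][()], freqs=f["freqs"][()], times=f["times"][()],
                labels=labels,
            )


@dataclass
class WindowedNetwork:
    """Directed weighted adjacency for one analysis window and band.

    ``adjacency[i, j]`` is the j -> i influence (|iPDC| aggregated); the
    diagonal is excluded from analysis and kept at 0.
    """

    adjacency: np.ndarray
    window: tuple[float, float]  # ms, half-open [a, b)
    band: tuple[float, float]  # Hz, inclusive
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.ndim != 2 or self.adjacency.shape[0] != self.adjacency.shape[1]:
            raise ValueError("adjacency must be square")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def copy(self, adjacency: np.ndarray | None = None) -> "WindowedNetwork":
        return WindowedNetwork(
            adjacency=self.adjacency.copy() if adjacency is None else adjacency,
            window=tuple(self.window),
            band=tuple(self.band),
            labels=None if self.labels is None else list(self.labels),
        )


@dataclass
class TEPEstimate:
    """A TMS-evoked potential estimate: channels × post-stimulus samples (µV)."""

    waveform: np.ndarray  # (n_channels, n_post)
    times: np.ndarray  # ms, post-stimulus axis
    method: str  # {"CA", "Bayes"}
    labels: list[str] | None = None
    weights: np.ndarray | None = None  # (n_channels, n_sweeps), Bayes only

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.method not in {"CA", "Bayes"}:
            raise ValueError("method must be 'CA' or 'Bayes'")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w <= 0):
                raise ValueError("Bayes weights must be positive")
            if not np.allclose(w.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError("Bayes weights must sum to 1 per channel")
            self.weights = w
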