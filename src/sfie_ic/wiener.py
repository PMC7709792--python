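"""Second-order Wiener-kernel receptive-field analysis.

A neuron's second-order Wiener kernel h2 is estimated from its spike times
during wideband Gaussian noise by averaging the outer products of the
pre-spike stimulus segments and subtracting the mean-rate-weighted stimulus
autocovariance. The kernel is a symmetric matrix over pairs of pre-spike
lags; it captures quadratic (envelope-sensitive) stimulus dependence, which
dominates in the midbrain where phase locking to fine structure is weak.

Eigendecomposition of h2 separates excitation (positive eigenvalues) from
inhibition (negative eigenvalues). Rendering each significant eigenvector
as a short-time Fourier magnitude and summing |eigenvalue|-weighted energy
per sign yields a time-frequency receptive field whose smoothed local
maxima give the center frequency and latency of each excitatory and
inhibitory input — the quantities used to parameterize the
inhibition-excitation cell models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.linalg import toeplitz

from .periphery import RateResponse
from .stimuli import Stimulus

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain",
    "WienerKernel2",
    "ReceptiveField",
    "RFPeaks",
    "poisson_spikes",
    "estimate_h2",
    "decompose_kernel",
    "find_peaks",
    "kernel_fourier_rf",
    "shuffled_kernel_stats",
]

DEFAULT_LAG_WINDOW_S = 0.016
DEFAULT_FS_K = 10_000.0


@dataclass
class SpikeTrain:
    """Ordered spike times within [0, duration]."""

    times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        if self.times_s.size:
            if np.any(np.diff(self.times_s) < 0):
                raise ValueError("spike times must be nondecreasing")
            if self.times_s[0] < 0 or self.times_s[-1] > self.duration_s:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


@dataclass
class WienerKernel2:
    """Second-order Wiener kernel over pre-spike lag pairs.

    ``k2[i, j]`` weights the product of the stimulus at lags ``i/fs`` and
    ``j/fs`` before a spike; units rate * Pa^-2.
    """

    k2: np.ndarray
    fs: float
    n_spikes: int
    lag_window_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k2 = np.asarray(self.k2, dtype=np.float64)
        if self.k2.ndim != 2 or self.k2.shape[0] != self.k2.shape[1]:
            raise ValueError("k2 must be square")
        if not np.array_equal(self.k2, self.k2.T):
            raise ValueError("k2 must be exactly symmetric")
        if not np.all(np.isfinite(self.k2)):
            raise ValueError("k2 must be finite")

    @property
    def lags_s(self) -> np.ndarray:
        return np.arange(self.k2.shape[0]) / self.fs


@dataclass
class ReceptiveField:
    """Time-frequency receptive field split into signed components.

    ``rf = rf_exc - rf_inh`` with both component maps nonnegative; axes are
    pre-spike lag (s) by frequency (Hz).
    """

    rf: np.ndarray
    rf_exc: np.ndarray
    rf_inh: np.ndarray
    lags_s: np.ndarray
    freqs_hz: np.ndarray
    eigvals: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.rf_exc < 0) or np.any(self.rf_inh < 0):
            raise ValueError("component maps must be nonnegative")


@dataclass
class RFPeaks:
    """Excitatory and inhibitory RF peaks as (freq_hz, latency_s, magnitude),
    each list sorted by decreasing magnitude."""

    exc: list[tuple[float, float, float]]
    inh: list[tuple[float, float, float]]


def poisson_spikes(rate: RateResponse, seed: int = 0) -> SpikeTrain:
    """Inhomogeneous Poisson spike train from an instantaneous rate.

    Bin-wise Poisson counts at the rate waveform's resolution, with spikes
    placed uniformly within their bin; expected count is the integral of
    the rate.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate.fs
    counts = rng.poisson(rate.rate * dt)
    idx = np.repeat(np.arange(len(counts)), counts)
    times = (idx + rng.random(idx.size)) * dt
    return SpikeTrain(np.sort(times), duration_s=rate.duration_s)


def _decimate_stimulus(stim: Stimulus, fs_k: float) -> np.ndarray:
    """Brick-wall low-pass (zero phase, no latency shift) and subsample."""
    if fs_k >= stim.fs:
        return stim.samples
    step = stim.fs / fs_k
    if abs(step - round(step)) > 1e-9:
        raise ValueError("analysis rate must divide the stimulus rate")
    spec = np.fft.rfft(stim.samples)
    freqs = np.fft.rfftfreq(len(stim.samples), 1.0 / stim.fs)
    spec[freqs > fs_k / 2.0] = 0.0
    return np.fft.irfft(spec, n=len(stim.samples))[:: int(round(step))]


def _spike_segments(
    x: np.ndarray, spikes: SpikeTrain, fs_k: float, n_lags: int
) -> np.ndarray:
    """Matrix of time-reversed pre-spike stimulus segments, one row per spike."""
    idx = np.round(spikes.times_s * fs_k).astype(int)
    ok = (idx >= n_lags - 1) & (idx < len(x))
    n_skip = int(np.sum(~ok))
    if n_skip:
        logger.info("skipping %d spikes outside the usable lag window", n_skip)
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no usable spikes within the lag window")
    # rows: s(t_i), s(t_i - dt), ..., s(t_i - (L-1) dt)
    offsets = -np.arange(n_lags)
    return x[idx[:, None] + offsets[None, :]]


def _stim_autocov(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Stationary autocovariance Toeplitz matrix over the lag window (FFT)."""
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(n + n_lags)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n_lags] / n
    return toeplitz(acf)


def estimate_h2(
    stim: Stimulus,
    spikes: SpikeTrain,
    lag_window_s: float = DEFAULT_LAG_WINDOW_S,
    fs_k: float = DEFAULT_FS_K,
) -> WienerKernel2:
    """Estimate the second-order Wiener kernel from spikes during noise.

    k2 = (1/T) * sum_i s_i s_i^T  -  (N/T) * C_stim

    where ``s_i`` is the time-reversed pre-spike stimulus segment of spike i
    and ``C_stim`` the stimulus autocovariance over the same lag pairs; the
    baseline term makes the estimate converge to zero when spiking does not
    depend on the stimulus. The stimulus is zero-phase low-passed and
    decimated to ``fs_k`` first.
    """
    if spikes.n_spikes == 0:
        raise ValueError("cannot estimate a kernel from zero spikes")
    x = _decimate_stimulus(stim, fs_k)
    n_lags = int(round(lag_window_s * fs_k))
    segs = _spike_segments(x, spikes, fs_k, n_lags)
    T = stim.duration_s
    k2 = segs.T @ segs / T - (segs.shape[0] / T) * _stim_autocov(x, n_lags)
    k2 = (k2 + k2.T) / 2.0
    return WienerKernel2(
        k2,
        fs=fs_k,
        n_spikes=segs.shape[0],
        lag_window_s=lag_window_s,
        meta={"n_spikes_total": spikes.n_spikes},
    )


def _eig_stft_map(
    v: np.ndarray, fs: float, window_s: float, nfft: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|STFT|^2 of one eigenvector: (lags, freqs, power[lag, freq])."""
    nper = max(int(round(window_s * fs)), 4)
    freqs, times, z = signal.stft(
        v,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=nper - 1,
        nfft=nfft,
        boundary="zeros",
        padded=True,
    )
    return times, freqs, np.abs(z.T) ** 2


def decompose_kernel(
    k2: WienerKernel2,
    eig_threshold: float = 0.0,
    window_s: float = 0.004,
    nfft: int = 512,
) -> ReceptiveField:
    """Split the kernel into excitatory and inhibitory receptive-field maps.

    Eigenvectors with positive eigenvalues span the excitatory subspace,
    negative the inhibitory. Each retained eigenvector (|eigenvalue| >
    ``eig_threshold``) is rendered as a short-time Fourier power map and the
    maps are summed with |eigenvalue| weights per sign.
    """
    lam, vec = np.linalg.eigh(k2.k2)
    order = np.argsort(-np.abs(lam))
    lam, vec = lam[order], vec[:, order]
    # relative floor keeps numerically-zero eigenvalues of low-rank kernels
    # out of the component maps
    floor = max(eig_threshold, 1e-10 * np.abs(lam).max()) if lam.size else 0.0
    lags = freqs = None
    exc = inh = None
    for lv, v in zip(lam, vec.T):
        if abs(lv) <= floor:
            continue
        t, f, p = _eig_stft_map(v, k2.fs, window_s, nfft)
        if exc is None:
            lags, freqs = t, f
            exc = np.zeros_like(p)
            inh = np.zeros_like(p)
        if lv > 0:
            exc += lv * p
        else:
            inh += -lv * p
    if exc is None:  # every eigenvalue below threshold
        t, f, p = _eig_stft_map(vec[:, 0], k2.fs, window_s, nfft)
        lags, freqs = t, f
        exc, inh = np.zeros_like(p), np.zeros_like(p)
    return ReceptiveField(
        rf=exc - inh, rf_exc=exc, rf_inh=inh, lags_s=lags, freqs_hz=freqs, eigvals=lam
    )


def kernel_fourier_rf(k2: WienerKernel2) -> np.ndarray:
    """Signed time-frequency view via a 1-D Fourier transform of the kernel.

    Real part of the FFT along the second lag axis; rows are the first lag
    (time), columns frequency. Complements the eigenvector rendering, which
    separates excitation and inhibition cleanly.
    """
    return np.real(np.fft.rfft(k2.k2, axis=1))


def _component_peaks(
    comp: np.ndarray,
    lags_s: np.ndarray,
    freqs_hz: np.ndarray,
    sigma_bins: float,
    threshold_frac: float,
) -> list[tuple[float, float, float]]:
    if not np.any(comp > 0):
        return []
    sm = ndimage.gaussian_filter(comp, sigma=sigma_bins)
    mx = ndimage.maximum_filter(sm, size=3, mode="nearest")
    peaks = (sm == mx) & (sm >= threshold_frac * sm.max()) & (sm > 0)
    out = []
    for i, j in zip(*np.nonzero(peaks)):
        out.append((float(freqs_hz[j]), float(lags_s[i]), float(sm[i, j])))
    out.sort(key=lambda p: -p[2])
    # drop plateau duplicates closer than the smoothing scale
    kept: list[tuple[float, float, float]] = []
    df = freqs_hz[1] - freqs_hz[0]
    dt = lags_s[1] - lags_s[0]
    for p in out:
        if all(
            abs(p[0] - q[0]) > 2 * sigma_bins * df or abs(p[1] - q[1]) > 2 * sigma_bins * dt
            for q in kept
        ):
            kept.append(p)
    return kept


def find_peaks(
    rf: ReceptiveField,
    sigma_bins: float = 2.0,
    threshold_frac: float = 0.3,
) -> RFPeaks:
    """Smooth each component map and return its local maxima.

    Peaks are (frequency Hz, positive pre-spike latency s, magnitude),
    magnitude-sorted. An all-zero map yields an empty list.
    """
    exc = _component_peaks(rf.rf_exc, rf.lags_s, rf.freqs_hz, sigma_bins, threshold_frac)
    inh = _component_peaks(rf.rf_inh, rf.lags_s, rf.freqs_hz, sigma_bins, threshold_frac)
    return RFPeaks(exc=exc, inh=inh)


def shuffled_kernel_stats(
    stim: Stimulus,
    spikes: SpikeTrain,
    n_surrogates: int = 20,
    seed: int = 0,
    lag_window_s: float = DEFAULT_LAG_WINDOW_S,
    fs_k: float = DEFAULT_FS_K,
) -> dict:
    """Noise-floor statistics from spike-shuffled surrogate kernels.

    Each surrogate circularly shifts the spike train by a random offset
    (destroying stimulus alignment, preserving rate statistics) and
    re-estimates the kernel. Returns the RMS peak magnitude across
    surrogates (``max_rms``, the kernel-null noise floor) and the 95th
    percentile of surrogate |eigenvalue| magnitudes (``eig_floor``, the
    eigenvalue retention threshold).
    """
    rng = np.random.default_rng(seed)
    x = _decimate_stimulus(stim, fs_k)
    n_lags = int(round(lag_window_s * fs_k))
    cov = _stim_autocov(x, n_lags)
    T = stim.duration_s
    maxima = []
    eigmags = []
    for _ in range(n_surrogates):
        shift = rng.uniform(0.05, spikes.duration_s - 0.05)
        t = np.sort(np.mod(spikes.times_s + shift, spikes.duration_s))
        segs = _spike_segments(x, SpikeTrain(t, spikes.duration_s), fs_k, n_lags)
        k2s = segs.T @ segs / T - (segs.shape[0] / T) * cov
        k2s = (k2s + k2s.T) / 2.0
        maxima.append(np.max(np.abs(k2s)))
        eigmags.append(np.abs(np.linalg.eigvalsh(k2s)))
    return {
        "max_rms": float(np.sqrt(np.mean(np.square(maxima)))),
        "max_mean": float(np.mean(maxima)),
        "eig_floor": float(np.percentile(np.concatenate(eigmags), 95)),
        "n_surrogates": n_surrogates,
    }
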