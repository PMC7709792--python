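"""Phenomenological auditory periphery: AN fiber front-end and CN stage.

The auditory-nerve (AN) stage is a deliberately simple phenomenological
model — gammatone band-pass filter at CF, saturating Boltzmann transduction,
inner-hair-cell low-pass, and two-time-constant subtractive adaptation —
that reproduces the response properties the midbrain circuit depends on:
envelope following in the CF channel, rate saturation with level, and a
spontaneous-rate floor. It is not a biophysical cochlear model; any
front-end exposing ``an_rate(stimulus, params) -> RateResponse`` can be
swapped in unchanged.

The cochlear-nucleus (CN) stage is the first inhibition-excitation cell of
the same-frequency inhibition-excitation (SFIE) cascade: excitation and
delayed, slower inhibition derived from a single AN channel, combined
through alpha-function synaptic filters and half-wave rectified. It
converts the AN's low-pass modulation response into band-pass modulation
tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import expit

from .stimuli import Stimulus

__all__ = [
    "ANParams",
    "CNParams",
    "RateResponse",
    "alpha_kernel",
    "alpha_filter",
    "delay_rate",
    "an_rate",
    "cn_rate",
]


@dataclass
class ANParams:
    """Auditory-nerve stand-in parameters.

    cf_hz : characteristic frequency (125–20000 Hz)
    filter_order : gammatone order (4 = classic)
    spont_rate, sat_rate : spontaneous and saturated discharge rates (sp/s)
    ihc_cutoff_hz : inner-hair-cell low-pass cutoff
    adapt_tau_s : (fast, short-term) adaptation time constants
    p0_pa : half-saturation pressure of the Boltzmann transduction
    gain : rate gain applied to the adapted transducer drive
    """

    cf_hz: float
    filter_order: int = 4
    spont_rate: float = 50.0
    sat_rate: float = 250.0
    ihc_cutoff_hz: float = 3000.0
    adapt_tau_s: tuple[float, float] = (0.002, 0.060)
    adapt_weights: tuple[float, float] = (0.40, 0.35)
    p0_pa: float = 3e-4
    boltzmann_bias: float = 1.0
    gain: float = 3500.0

    def __post_init__(self) -> None:
        if not (125.0 <= self.cf_hz <= 20_000.0):
            raise ValueError(f"cf_hz must lie in [125, 20000], got {self.cf_hz}")
        if self.spont_rate < 0 or self.sat_rate <= self.spont_rate:
            raise ValueError("need 0 <= spont_rate < sat_rate")


@dataclass
class CNParams:
    """SFIE cochlear-nucleus cell: same-CF excitation and delayed inhibition."""

    tau_exc_s: float = 0.5e-3
    tau_inh_s: float = 2.0e-3
    delay_s: float = 1.0e-3
    strength_exc: float = 1.5
    strength_inh: float = 0.9

    def __post_init__(self) -> None:
        if self.tau_exc_s <= 0 or self.tau_inh_s <= 0:
            raise ValueError("alpha-function time constants must be positive")
        if self.delay_s < 0:
            raise ValueError("inhibitory delay must be nonnegative")


@dataclass
class RateResponse:
    """Instantaneous firing rate (sp/s) of one model stage."""

    rate: np.ndarray
    fs: float
    stage: str = "AN"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=np.float64)
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("rate must be finite")
        if np.any(self.rate < 0):
            raise ValueError("rate must be nonnegative")

    @property
    def duration_s(self) -> float:
        return len(self.rate) / self.fs

    def mean_rate(self, onset_skip_s: float = 0.0) -> float:
        i0 = int(round(onset_skip_s * self.fs))
        return float(np.mean(self.rate[i0:]))


def alpha_kernel(tau_s: float, fs: float, length_taus: float = 10.0) -> np.ndarray:
    """Unit-area alpha function (t/tau^2)exp(-t/tau) sampled at ``fs``."""
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(0.0, length_taus * tau_s, 1.0 / fs)
    k = (t / tau_s**2) * np.exp(-t / tau_s)
    # renormalize the discrete sum so DC gain is exactly 1
    return k / (np.sum(k) / fs)


def alpha_filter(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    """Causal convolution with the unit-area alpha kernel."""
    k = alpha_kernel(tau_s, fs)
    return signal.fftconvolve(x, k, mode="full")[: len(x)] / fs


def delay_rate(x: np.ndarray, delay_s: float, fs: float) -> np.ndarray:
    """Shift a rate waveform later by ``delay_s``, padding with its first value."""
    n_d = int(round(delay_s * fs))
    if n_d == 0:
        return x
    return np.concatenate([np.full(n_d, x[0]), x[:-n_d]])


def _onepole_lowpass(x: np.ndarray, tau_s: float, fs: float) -> np.ndarray:
    a = 1.0 - np.exp(-1.0 / (tau_s * fs))
    return signal.lfilter([a], [1.0, -(1.0 - a)], x)


def an_rate(stim: Stimulus, params: ANParams, decim: int = 10) -> RateResponse:
    """Instantaneous AN firing rate for one CF channel.

    Cascade: gammatone band-pass at CF -> Boltzmann transduction ->
    IHC low-pass -> causal anti-alias + ``decim``-fold decimation ->
    subtractive two-time-constant adaptation -> half-wave rectified rate
    with a spontaneous floor. All filtering is causal so downstream latency
    estimates are physical.
    """
    if params.cf_hz >= stim.fs / 2.0:
        raise ValueError(
            f"cf {params.cf_hz} Hz at or above Nyquist ({stim.fs / 2} Hz)"
        )
    b, a = signal.gammatone(params.cf_hz, "iir", fs=stim.fs)
    y = signal.lfilter(b, a, stim.samples)

    u = expit(y / params.p0_pa - params.boltzmann_bias)
    u_rest = expit(-params.boltzmann_bias)

    b_lp, a_lp = signal.butter(2, params.ihc_cutoff_hz, fs=stim.fs)
    u = signal.lfilter(b_lp, a_lp, u)

    fs_out = stim.fs / decim
    if decim > 1:
        b_aa, a_aa = signal.butter(4, 0.8 * fs_out / 2.0, fs=stim.fs)
        u = signal.lfilter(b_aa, a_aa, u)[::decim]

    z = u - u_rest
    (tau_f, tau_s_), (w_f, w_s) = params.adapt_tau_s, params.adapt_weights
    z_ad = z - w_f * _onepole_lowpass(z, tau_f, fs_out) - w_s * _onepole_lowpass(
        z, tau_s_, fs_out
    )
    rate = params.spont_rate + params.gain * np.maximum(z_ad, 0.0)
    return RateResponse(rate, fs_out, stage="AN", meta={"cf_hz": params.cf_hz})


def cn_rate(an: RateResponse, params: CNParams | None = None) -> RateResponse:
    """SFIE cochlear-nucleus cell rate from one AN channel.

    rate = rectify(s_exc * (an (*) alpha(tau_exc))
                   - s_inh * delay(an (*) alpha(tau_inh), d))

    With unit-area kernels the DC gain is ``s_exc - s_inh``; the delayed,
    slower inhibition carves out low modulation frequencies, making the
    output band-pass modulation-tuned.
    """
    if an.stage != "AN":
        raise ValueError(f"cn_rate expects an AN-stage input, got {an.stage!r}")
    p = params or CNParams()
    e = alpha_filter(an.rate, p.tau_exc_s, an.fs)
    i = delay_rate(alpha_filter(an.rate, p.tau_inh_s, an.fs), p.delay_s, an.fs)
    rate = np.maximum(p.strength_exc * e - p.strength_inh * i, 0.0)
    return RateResponse(rate, an.fs, stage="CN", meta=dict(an.meta))
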