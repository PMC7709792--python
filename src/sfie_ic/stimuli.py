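"""Acoustic stimulus synthesis and calibration.

All stimuli used to probe modulation tuning and tone-in-noise coding in the
midbrain model are generated here: sinusoidally amplitude-modulated (AM)
tones and wideband noise, tone-in-noise (TIN) with a 1/3-octave masker, and
band-limited white noise for receptive-field estimation.

Conventions
-----------
* Pressure waveforms are in pascals; levels are dB SPL re 20 uPa RMS.
* Noise band-limiting uses an FFT brick-wall so band edges are exact.
* Every stimulus gets 10-ms raised-cosine on/off ramps; final RMS scaling
  happens after ramping so the measured level matches the request exactly.
* AM modulator is ``1 + m*sin(2*pi*fm*t - pi/2)`` — envelope minimum at
  stimulus onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.signal import hilbert

P_REF = 20e-6  # Pa, dB SPL reference
DEFAULT_FS = 100_000.0
RAMP_S = 0.010

__all__ = [
    "Stimulus",
    "AMSpec",
    "TINSpec",
    "measure_db_spl",
    "synth_am_tone",
    "synth_am_noise",
    "synth_tin",
    "synth_white_noise",
    "attenuate",
    "envelope_stats",
    "mod_freq_grid",
    "TIN_SNR_GRID",
    "TIN_NOISE_LEVELS",
    "write_wav",
]

TIN_NOISE_LEVELS = (35.0, 45.0, 55.0, 65.0, 75.0)
TIN_SNR_GRID = (-np.inf, -12.0, -8.0, -4.0, 0.0, 4.0, 8.0)


@dataclass
class Stimulus:
    """A calibrated pressure waveform.

    Attributes
    ----------
    samples : ndarray
        Pressure in Pa.
    fs : float
        Sample rate in Hz.
    level_db_spl : float
        Measured overall level (dB SPL re 20 uPa RMS) of ``samples``.
    meta : dict
        Free-form descriptor (stimulus class and synthesis parameters).
    """

    samples: np.ndarray
    fs: float
    level_db_spl: float
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")


@dataclass
class AMSpec:
    """Amplitude-modulated stimulus parameters.

    ``level_db`` is overall dB SPL for a tone carrier, or spectrum level in
    dB SPL/Hz for a noise carrier.
    """

    carrier: Literal["tone", "noise"]
    mod_freq_hz: float
    mod_depth: float = 1.0
    carrier_freq_hz: float | None = None
    band_hz: tuple[float, float] = (100.0, 10_000.0)
    level_db: float = 70.0

    def __post_init__(self) -> None:
        if not (2.0 <= self.mod_freq_hz <= 1024.0):
            raise ValueError(
                f"mod_freq_hz must lie in [2, 1024] Hz, got {self.mod_freq_hz}"
            )
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError(f"mod_depth must lie in [0, 1], got {self.mod_depth}")
        if self.carrier == "tone" and self.carrier_freq_hz is None:
            raise ValueError("tone carrier requires carrier_freq_hz")


@dataclass
class TINSpec:
    """Tone in a 1/3-octave band of Gaussian noise.

    ``snr_db`` is the tone level relative to the overall band level;
    ``-inf`` means noise alone.
    """

    tone_freq_hz: float
    band_center_hz: float
    noise_level_db_spl: float
    snr_db: float
    duration_s: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_level_db_spl not in TIN_NOISE_LEVELS:
            raise ValueError(
                f"noise_level_db_spl must be one of {TIN_NOISE_LEVELS}, "
                f"got {self.noise_level_db_spl}"
            )
        finite_ok = -12.0 <= self.snr_db <= 8.0
        if not (finite_ok or np.isneginf(self.snr_db)):
            raise ValueError(f"snr_db must be in [-12, 8] or -inf, got {self.snr_db}")
        lo, hi = self.band_edges_hz
        if not (lo <= self.tone_freq_hz <= hi):
            raise ValueError("tone frequency must lie within the 1/3-octave band")

    @property
    def band_edges_hz(self) -> tuple[float, float]:
        c = self.band_center_hz
        return c * 2.0 ** (-1.0 / 6.0), c * 2.0 ** (1.0 / 6.0)


def measure_db_spl(samples: np.ndarray) -> float:
    """Overall level of a pressure waveform in dB SPL re 20 uPa RMS."""
    rms = float(np.sqrt(np.mean(np.square(samples))))
    if rms <= 0.0:
        return -np.inf
    return 20.0 * np.log10(rms / P_REF)


def _n_samples(duration_s: float, fs: float) -> int:
    return int(round(duration_s * fs))


def _time(n: int, fs: float) -> np.ndarray:
    return np.arange(n) / fs


def _ramp(x: np.ndarray, fs: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Apply raised-cosine on/off ramps in place-safe fashion."""
    n_r = int(round(ramp_s * fs))
    if n_r == 0 or 2 * n_r > len(x):
        return x
    w = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_r) / n_r))
    y = x.copy()
    y[:n_r] *= w
    y[-n_r:] *= w[::-1]
    return y


def _scale_to_level(x: np.ndarray, level_db_spl: float) -> np.ndarray:
    rms = np.sqrt(np.mean(np.square(x)))
    if rms == 0.0:
        raise ValueError("cannot calibrate an all-zero waveform")
    return x * (P_REF * 10.0 ** (level_db_spl / 20.0) / rms)


def _brickwall(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Zero-phase FFT brick-wall band-pass (exact band edges, no delay)."""
    if lo_hz >= hi_hz:
        raise ValueError(f"degenerate band: lo {lo_hz} >= hi {hi_hz}")
    if hi_hz > fs / 2.0:
        raise ValueError(f"band edge {hi_hz} Hz above Nyquist ({fs / 2} Hz)")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    spec[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    return np.fft.irfft(spec, n=len(x))


def _am_envelope(n: int, fs: float, fm: float, depth: float) -> np.ndarray:
    t = _time(n, fs)
    return 1.0 + depth * np.sin(2.0 * np.pi * fm * t - np.pi / 2.0)


def synth_am_tone(
    spec: AMSpec, fs: float = DEFAULT_FS, duration_s: float = 1.0, seed: int | None = None
) -> Stimulus:
    """Sinusoidally amplitude-modulated tone, calibrated to overall SPL.

    The carrier sits at the cell's characteristic frequency in the standard
    protocol; the whole modulated waveform is scaled to ``spec.level_db``.
    ``seed`` is accepted for interface uniformity and unused (deterministic).
    """
    if spec.carrier != "tone":
        raise ValueError("synth_am_tone requires a tone-carrier AMSpec")
    fc = float(spec.carrier_freq_hz)
    if fc >= fs / 2.0:
        raise ValueError(f"carrier {fc} Hz at or above Nyquist ({fs / 2} Hz)")
    n = _n_samples(duration_s, fs)
    t = _time(n, fs)
    x = _am_envelope(n, fs, spec.mod_freq_hz, spec.mod_depth) * np.sin(
        2.0 * np.pi * fc * t
    )
    x = _scale_to_level(_ramp(x, fs), spec.level_db)
    return Stimulus(
        x,
        fs,
        measure_db_spl(x),
        meta={
            "class": "am_tone",
            "carrier_freq_hz": fc,
            "mod_freq_hz": spec.mod_freq_hz,
            "mod_depth": spec.mod_depth,
            "level_db_spl": spec.level_db,
        },
    )


def synth_am_noise(
    spec: AMSpec, fs: float = DEFAULT_FS, duration_s: float = 1.0, seed: int = 0
) -> Stimulus:
    """Amplitude-modulated band-limited Gaussian noise.

    The *unmodulated* carrier is calibrated so its spectrum level equals
    ``spec.level_db`` (dB SPL/Hz); overall carrier level is
    ``level_db + 10*log10(bandwidth)``. Modulation is applied after
    band-limiting and calibration.
    """
    if spec.carrier != "noise":
        raise ValueError("synth_am_noise requires a noise-carrier AMSpec")
    lo, hi = spec.band_hz
    n = _n_samples(duration_s, fs)
    rng = np.random.default_rng(seed)
    carrier = _brickwall(rng.standard_normal(n), fs, lo, hi)
    carrier_level = spec.level_db + 10.0 * np.log10(hi - lo)
    carrier = _scale_to_level(_ramp(carrier, fs), carrier_level)
    x = carrier * _am_envelope(n, fs, spec.mod_freq_hz, spec.mod_depth)
    return Stimulus(
        x,
        fs,
        measure_db_spl(x),
        meta={
            "class": "am_noise",
            "band_hz": [lo, hi],
            "mod_freq_hz": spec.mod_freq_hz,
            "mod_depth": spec.mod_depth,
            "spectrum_level_db": spec.level_db,
            "carrier_level_db_spl": carrier_level,
        },
    )


def synth_tin(spec: TINSpec, fs: float = DEFAULT_FS, seed: int = 0) -> Stimulus:
    """Tone-in-noise: 1/3-octave Gaussian masker plus a tone at ``snr_db``.

    Noise and tone branches are ramped and calibrated independently, then
    summed, so the noise-alone level and the tone-component level are each
    exact. ``snr_db = -inf`` yields the noise alone.
    """
    lo, hi = spec.band_edges_hz
    n = _n_samples(spec.duration_s, fs)
    rng = np.random.default_rng(seed)
    noise = _brickwall(rng.standard_normal(n), fs, lo, hi)
    noise = _scale_to_level(_ramp(noise, fs), spec.noise_level_db_spl)
    if np.isneginf(spec.snr_db):
        x = noise
    else:
        t = _time(n, fs)
        tone = _ramp(np.sin(2.0 * np.pi * spec.tone_freq_hz * t), fs)
        tone = _scale_to_level(tone, spec.noise_level_db_spl + spec.snr_db)
        x = noise + tone
    return Stimulus(
        x,
        fs,
        measure_db_spl(x),
        meta={
            "class": "tin",
            "tone_freq_hz": spec.tone_freq_hz,
            "band_center_hz": spec.band_center_hz,
            "band_edges_hz": [lo, hi],
            "noise_level_db_spl": spec.noise_level_db_spl,
            "snr_db": spec.snr_db,
        },
    )


def synth_white_noise(
    fs: float = DEFAULT_FS,
    seed: int = 0,
    duration_s: float = 2.0,
    band_hz: tuple[float, float] = (100.0, 20_000.0),
    level_db_spl: float = 65.0,
) -> Stimulus:
    """Band-limited (0.1–20 kHz) Gaussian noise at 65 dB SPL, 2 s by default.

    A longer ``duration_s`` may be requested for receptive-field estimation.
    """
    if fs <= 40_000.0:
        raise ValueError("white-noise synthesis needs fs > 40 kHz")
    n = _n_samples(duration_s, fs)
    rng = np.random.default_rng(seed)
    x = _brickwall(rng.standard_normal(n), fs, *band_hz)
    x = _scale_to_level(_ramp(x, fs), level_db_spl)
    return Stimulus(
        x,
        fs,
        measure_db_spl(x),
        meta={"class": "white_noise", "band_hz": list(band_hz), "level_db_spl": level_db_spl},
    )


def attenuate(stim: Stimulus, db: float) -> Stimulus:
    """Return a copy of ``stim`` attenuated by ``db`` decibels."""
    g = 10.0 ** (-db / 20.0)
    meta = dict(stim.meta)
    meta["attenuation_db"] = meta.get("attenuation_db", 0.0) + db
    return Stimulus(stim.samples * g, stim.fs, stim.level_db_spl - db, meta)


def envelope_stats(stim: Stimulus, edge_s: float = RAMP_S) -> dict:
    """Hilbert-envelope mean, SD and CV with onset/offset excluded.

    The coefficient of variation (SD/mean of the envelope) is the
    normalized envelope fluctuation measure: adding a tone to narrowband
    noise flattens the envelope, lowering it.
    """
    if stim.duration_s < 0.020:
        raise ValueError("stimulus shorter than 20 ms; envelope stats undefined")
    env = np.abs(hilbert(stim.samples))
    n_e = int(round(edge_s * stim.fs))
    core = env[n_e : len(env) - n_e] if n_e > 0 else env
    mean = float(np.mean(core))
    sd = float(np.std(core))
    return {"env_mean": mean, "env_sd": sd, "env_cv": sd / mean if mean > 0 else np.nan}


def mod_freq_grid(
    fmin_hz: float = 2.0, fmax_hz: float = 350.0, steps_per_octave: int = 2
) -> np.ndarray:
    """Log-spaced modulation-frequency grid, ``steps_per_octave`` per octave."""
    n_oct = np.log2(fmax_hz / fmin_hz)
    n = int(np.floor(n_oct * steps_per_octave)) + 1
    grid = fmin_hz * 2.0 ** (np.arange(n) / steps_per_octave)
    if grid[-1] < fmax_hz * (1 - 1e-9):
        grid = np.append(grid, fmax_hz)
    return grid


def write_wav(stim: Stimulus, path: str) -> None:
    """Write a 32-bit float WAV plus a JSON sidecar with the spec metadata."""
    from scipy.io import wavfile

    wavfile.write(path, int(stim.fs), stim.samples.astype(np.float32))
    sidecar = {
        "fs": stim.fs,
        "duration_s": stim.duration_s,
        "level_db_spl": stim.level_db_spl,
        "meta": stim.meta,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)
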