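# Methods

`sfie_ic` simulates single neurons of the inferior colliculus (IC) with a
generalized same-frequency inhibition-excitation (SFIE) circuit, probes
them with the standard physiological stimulus battery, and analyses their
spike output with second-order Wiener-kernel receptive fields — the same
analysis used to parameterize the cells, so the whole loop can be closed
and checked on model ground truth.

## The model

### Stimuli

Four calibrated stimulus classes (all in pascals, levels in dB SPL re
20 µPa RMS; 10-ms raised-cosine ramps on everything):

* **AM tones** — carrier at the cell's characteristic frequency (CF),
  modulator `1 + m·sin(2πf_m t − π/2)` (envelope minimum at onset),
  1 s, 70 dB SPL overall, modulation frequencies 2–350 Hz (up to 1024 Hz
  for high CFs), depth 1 by default.
* **AM wideband noise** — Gaussian noise brick-walled to 0.1–10 kHz at a
  30 dB SPL/Hz spectrum level (carrier calibrated before modulation), 1 s.
* **Tone-in-noise (TIN)** — a 1/3-octave Gaussian band centered at CF at
  an overall level of 35–75 dB SPL in 10-dB steps, plus a CF tone at
  SNRs −12…8 dB re the overall band level (−∞ = noise alone), 0.3 s.
  Noise and tone branches are ramped and calibrated independently so each
  component's level is exact to < 0.1 dB.
* **White noise** — 0.1–20 kHz Gaussian noise at 65 dB SPL, 2 s by
  default; receptive-field estimation uses longer renderings.

Band-limiting is an FFT brick-wall (exact, testable band edges). All noise
is reproducible from a seed. The modulation-frequency grid is log-spaced,
2 steps/octave.

### Periphery

The auditory-nerve (AN) front-end is deliberately phenomenological: a
4th-order gammatone filter at CF, a Boltzmann (logistic) transducer, a
2nd-order 3-kHz inner-hair-cell low-pass, causal anti-alias filtering with
×10 decimation (rates live at 10 kHz), and two-time-constant subtractive
adaptation (2 ms / 60 ms, weights 0.40 / 0.35) feeding a half-wave
rectified rate with a 50 sp/s spontaneous floor. It reproduces the
properties the midbrain circuit actually consumes — envelope following in
the CF channel, saturating rate-level behavior, phase locking at low CF —
and nothing more. Any front-end exposing
`an_rate(stimulus, params) → RateResponse` can substitute.

Two parameters deserve comment:

* **Transducer half-saturation `p0_pa = 3e-4 Pa` (≈24 dB SPL).** The fiber
  behaves like a high-spontaneous-rate AN fiber: threshold near 0 dB SPL,
  saturated by 30–40 dB. This is what makes the tone-in-noise behavior
  work: at every masker level in the battery the periphery is envelope-
  dominated, so adding a CF tone *flattens* the drive rather than adding
  to it, and fluctuation-driven (band-enhanced) cells slow down. With a
  higher knee the periphery is linear at 35–55 dB SPL and tone level
  trivially drives rate upward.
* **All stimuli entering the model are attenuated by 10 dB** — the model
  chain is somewhat more sensitive than real neurons.

The cochlear-nucleus (CN) stage is the first SFIE cell: excitation and
delayed inhibition from one AN channel through unit-area alpha filters
`(t/τ²)e^(−t/τ)` (τ_exc = 0.5 ms, τ_inh = 2 ms, delay 1 ms, strengths
1.5 / 0.9), half-wave rectified. Its DC gain is 0.6 and its modulation
response is band-pass.

### The generalized IC cell

An IC cell is a list of synaptic inputs, each with CF, sign, strength,
latency and alpha time constant (default τ = 2 ms). Band-enhanced (BE)
cells combine CN excitation with delayed CN inhibition; band-suppressed
(BS) cells take CN excitation and are inhibited by BE interneurons (one
per inhibitory input, original-SFIE parameterization at the input's CF by
default). Latencies are relative to the first excitatory input — only
relative timing shapes the modulation transfer function (MTF).

Named modifications fix the free structure: **a** (1 exc + 1 inh, same
CF), **b** (CFs from the receptive field), **c** (b plus a second
inhibition at the excitatory CF, both strengths 0.8), **d** (up to 2 + 2;
strengths 1/1.3, or 1, 0.8 exc with 2.2 inh as a selectable sub-variant,
or 0.8 for 1 exc + 2 inh). For a/b the inhibitory strength is 1.3. The
original SFIE reference cell uses strength 1.5 and a 2-ms inhibitory
delay. Once built, a cell is fixed across all stimulus types.

**BE output gain.** The BE cell's rectified drive is a small residual of
two nearly cancelling inputs; in this implementation it sits an order of
magnitude below the CN rates that excite a BS cell. Since the BS
combination uses *relative* strengths (0.8 per inhibitory input), the BE
output is scaled by a stage gain `BE_OUT_GAIN = 5` — the analogue of the
per-stage output scaling used throughout the SFIE literature — restoring
the BE:CN rate balance that the published relative strengths presuppose.
Classification and every ratio-based result are invariant to this scale.

Inhibitory latencies above 5 ms trigger a warning (large latency changes
can produce discontinuities in the circuit's impulse response); no
clamping is applied — the failure mode is reproduced, not hidden.

### Wiener-kernel receptive fields

Spike times (inhomogeneous Poisson draws from the model rate, binned at
10 kHz with intra-bin jitter) recorded during white noise give the
second-order kernel

    k2(τ₁, τ₂) = (1/T) Σᵢ s(tᵢ−τ₁)s(tᵢ−τ₂) − (N/T) C_stim(τ₁, τ₂)

over a 16-ms lag window at a 10-kHz analysis rate (the stimulus is
zero-phase brick-wall low-passed before subsampling, so no latency shift
is introduced). The autocovariance term makes stimulus-independent spiking
converge to a null kernel. The kernel is exactly symmetric by
construction.

Eigendecomposition separates excitation (λ > 0) from inhibition (λ < 0).
Eigenvalues are kept if their magnitude exceeds the 95th percentile of
surrogate eigenvalue magnitudes from ≥ 20 circularly spike-shuffled
kernels (shuffling destroys stimulus alignment, preserves rate
statistics). Each retained eigenvector is rendered as a short-time Fourier
power map (4-ms Hann window, hop 1 sample, nfft = 512 — the zero-padded
~20-Hz frequency grid is what makes sub-percent CF readout possible) and
the |λ|-weighted maps are summed per sign. Peaks are local maxima of each
component map after σ = 2-bin Gaussian smoothing, thresholded at 30 % of
the component maximum, reported as (frequency, positive pre-spike latency,
magnitude). A direct Fourier view of the kernel is exposed alongside, but
peaks are read from the eigenvector rendering because it separates signs
cleanly. Time reversal of the lag axis is a plotting concern only.

The kernel-null statistic compares the peak |k2| against the RMS of the
surrogate kernels' peak magnitudes: a per-entry standard error would be
the wrong yardstick for a maximum over ~25 000 entries (the expected
maximum of a null estimate is ~4 per-entry SEs by order statistics), so
the floor is itself a max statistic.

### Characterization and scoring

MTFs are mean driven rates (50-ms onset excluded) per modulation
frequency, averaged over 5 noise seeds (tone carriers are deterministic),
with the unmodulated-carrier rate alongside. Classification: BE if an
interior (8–128 Hz) peak reaches 1.2× the unmodulated rate, BS if an
interior trough falls below 0.8× — conventional IC criteria, scale
invariant, config-exposed. TIN surfaces are mean driven rates per
(level, SNR) with one noise seed shared across each SNR column (paired
comparisons); trends are Spearman correlations of rate vs finite SNR per
level. Model-vs-reference scoring uses Pearson r with the t-transform
p-value, per noise level for TIN plus the across-level mean of valid
levels; zero-variance curves are flagged and excluded rather than poisoned
into the means. A batch driver writes every panel as fixed-format CSV/JSON
so a rerun with the same seed is byte-identical.

## What the synthetic fixtures do and do not show

The registry holds the two published example parameterizations
(`fig3_be_modb`: exc 2083 Hz / inh 1833 Hz, 2.3-ms delay, strength 1.3;
`fig4_bs_modc`: exc 800 Hz, inhibitions at 800 and 960 Hz, 4-ms delays,
strengths 0.8), the original-SFIE reference, two extra BE cells
(1200/1000 Hz Δ3 ms; 1600/1400 Hz Δ2.5 ms) for parameter-recovery
exercises, LN toy neurons (gammatone → squarer or rectifier → Poisson)
whose kernels are known from Wiener theory, and a noisy-reference
generator (Gaussian rate noise, floored at zero) standing in for recorded
rate curves. Excitatory absolute latency in example cells is set to the
circuit's own processing lag; only relative timing matters.

Because every "neuron" here is the model itself, passing tests demonstrate
internal consistency — the circuit produces the claimed MTF classes and
TIN trends, and the analysis recovers the parameters that generated the
data — not fidelity to any particular recorded neuron. Known limits:

* The AN stand-in has no two-tone suppression, so suppression-induced
  high-side inhibition in receptive fields will not reproduce.
* The Wiener receptive field shows *net* excitation/inhibition. When
  inputs overlap in frequency (same-CF cells) the excitation tail cancels
  the early inhibition and biases its apparent latency late by ~1 ms;
  for BS cells the BE interneuron adds its own ~4-ms processing lag on
  top of the synaptic delay. Parameter-recovery guarantees (CF within
  15 %, relative latency within 1 ms) therefore apply to cells whose
  inhibition reaches the IC directly and at a distinct CF; for the other
  architectures the bias is structural, not an estimator defect.
* Recovery uses 60 s of white noise (~5000 spikes at typical model rates);
  distinct-CF cells show residual latency biases of +0.3–0.5 ms.

## Numerical choices

* Default sample rate 100 kHz (headroom above the 20-kHz noise band);
  rates decimated ×10 after the IHC low-pass. All rate-path filtering is
  causal; only stimulus-side brick-walls are zero-phase.
* Discrete alpha kernels are renormalized to unit area so DC analysis is
  exact; delays pad with the first sample.
* Calibration scales after ramping, so measured RMS hits the target level
  exactly; `Stimulus.level_db_spl` always records the measured overall
  level of the rendered waveform (for modulated noise this exceeds the
  carrier level by `10·log10(1+m²/2)`; the requested spectrum level lives
  in the metadata).
* Seed handling: every stochastic routine takes an explicit seed;
  composite routines split a `SeedSequence`, and derived seeds are reduced
  below 2³¹.
* Degenerate inputs are rejected with diagnostics (carrier above Nyquist,
  degenerate noise bands, zero-spike kernels, non-symmetric kernels,
  missing CN channels named by CF); all-zero receptive-field maps yield
  empty peak lists rather than errors.

## Problem sizes in the shipped checks

The test suite and the acceptance script run MTFs at 5 noise seeds over
the default 16-point grid, TIN at 5 seeds over 5 levels × 7 SNRs,
envelope-flattening statistics over 400–1500 paired seeds (1/3-octave band
at 8 kHz, where the wider absolute bandwidth gives more independent
envelope samples per stimulus), and kernel estimation on 60 s of white
noise with 20 shuffled surrogates. These sizes were chosen so every
statistic sits several standard errors from its decision boundary.
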