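"""Canonical ground-truth fixtures.

Model cells with published example parameterizations (a band-enhanced
modification-b cell and a band-suppressed modification-c cell), the
original-SFIE reference cell, linear-nonlinear (LN) toy neurons with
analytically known kernels for validating the Wiener-kernel pipeline, and
a noisy-reference generator that stands in for recorded rate curves when
exercising the scoring path.

The neural recordings these example cells were fit to are not distributed;
every fixture here is model-generated and its ``expected`` map states the
properties the package's own tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .periphery import RateResponse
from .sfie import IECellSpec, SynapticInput
from .stimuli import Stimulus

__all__ = ["Fixture", "LNSpec", "make_fixture", "ln_rate", "noisy_reference", "FIXTURE_NAMES"]

# Excitatory absolute latency used in example cells: only relative timing
# shapes the modulation transfer function, so this is a free choice.
EXC_LATENCY_S = 0.005


@dataclass
class LNSpec:
    """Linear-nonlinear toy neuron: gammatone filter -> static nonlinearity
    -> target mean rate (output is rescaled so its mean is ``target_rate``)."""

    center_hz: float
    nonlinearity: str  # "squarer" | "hwr"
    target_rate: float = 100.0


@dataclass
class Fixture:
    name: str
    cell_spec: IECellSpec | None = None
    ln_spec: LNSpec | None = None
    expected: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _fig3_be_modb() -> Fixture:
    spec = IECellSpec(
        cell_class="BE",
        modification="b",
        inputs=[
            SynapticInput(2083.0, "excitatory", 1.0, 0.0),
            SynapticInput(1833.0, "inhibitory", 1.3, 2.3e-3),
        ],
        name="fig3_be_modb",
    )
    return Fixture(
        name="fig3_be_modb",
        cell_spec=spec,
        expected={
            "mtf_class": ("BE", None),
            "f_exc_hz": (2083.0, 0.15),  # relative tolerance
            "f_inh_hz": (1833.0, 0.15),
            "delta_latency_s": (2.3e-3, 1.0e-3),  # absolute tolerance
            "tin_trend_sign": (-1, None),
        },
    )


def _fig4_bs_modc() -> Fixture:
    spec = IECellSpec(
        cell_class="BS",
        modification="c",
        inputs=[
            SynapticInput(800.0, "excitatory", 1.0, 0.0),
            SynapticInput(800.0, "inhibitory", 0.8, 4.0e-3),
            SynapticInput(960.0, "inhibitory", 0.8, 4.0e-3),
        ],
        name="fig4_bs_modc",
    )
    return Fixture(
        name="fig4_bs_modc",
        cell_spec=spec,
        expected={
            "mtf_class": ("BS", None),
            "tin_trend_sign": (+1, None),
        },
        meta={
            "note": "inhibition arrives via BE interneurons, so receptive-field "
            "inhibition latency exceeds the 4-ms synaptic delay by the "
            "interneuron lag; timing recovery applies to BE-type cells only"
        },
    )


def _sfie_original() -> Fixture:
    from .sfie import original_sfie_cell

    spec = original_sfie_cell(2000.0, name="sfie_original")
    return Fixture(
        name="sfie_original",
        cell_spec=spec,
        expected={
            "mtf_class": ("BE", None),
            "f_exc_hz": (2000.0, 0.15),
        },
        meta={
            "note": "same-CF inhibition overlaps the excitation in the net "
            "receptive field, so its apparent latency is biased late; timing "
            "recovery is specified only for cells with distinct input CFs"
        },
    )


def _be_modb_1200() -> Fixture:
    """Additional band-enhanced cell with well-separated low CFs, used to
    exercise parameter recovery away from the published examples."""
    spec = IECellSpec(
        cell_class="BE",
        modification="b",
        inputs=[
            SynapticInput(1200.0, "excitatory", 1.0, 0.0),
            SynapticInput(1000.0, "inhibitory", 1.3, 3.0e-3),
        ],
        name="be_modb_1200",
    )
    return Fixture(
        name="be_modb_1200",
        cell_spec=spec,
        expected={
            "mtf_class": ("BE", None),
            "f_exc_hz": (1200.0, 0.15),
            "f_inh_hz": (1000.0, 0.15),
            "delta_latency_s": (3.0e-3, 1.0e-3),
        },
    )


def _be_modb_1600() -> Fixture:
    spec = IECellSpec(
        cell_class="BE",
        modification="b",
        inputs=[
            SynapticInput(1600.0, "excitatory", 1.0, 0.0),
            SynapticInput(1400.0, "inhibitory", 1.3, 2.5e-3),
        ],
        name="be_modb_1600",
    )
    return Fixture(
        name="be_modb_1600",
        cell_spec=spec,
        expected={
            "mtf_class": ("BE", None),
            "f_exc_hz": (1600.0, 0.15),
            "f_inh_hz": (1400.0, 0.15),
            "delta_latency_s": (2.5e-3, 1.0e-3),
        },
    )


def _ln(name: str, center: float, nl: str) -> Fixture:
    return Fixture(
        name=name,
        ln_spec=LNSpec(center_hz=center, nonlinearity=nl),
        expected={
            "kernel_peak_freq_hz": (center, 0.05),
            "inh_energy_fraction_max": (0.2, None),
        },
    )


def _noisy_reference() -> Fixture:
    return Fixture(
        name="noisy_reference",
        expected={"identity_at_zero_sd": (True, None)},
        meta={"use": "call fixtures.noisy_reference(curve, noise_sd, seed)"},
    )


_REGISTRY = {
    "fig3_be_modb": _fig3_be_modb,
    "fig4_bs_modc": _fig4_bs_modc,
    "sfie_original": _sfie_original,
    "be_modb_1200": _be_modb_1200,
    "be_modb_1600": _be_modb_1600,
    "ln_squarer_1k": lambda: _ln("ln_squarer_1k", 1000.0, "squarer"),
    "ln_hwr_4k": lambda: _ln("ln_hwr_4k", 4000.0, "hwr"),
    "noisy_reference": _noisy_reference,
}

FIXTURE_NAMES = tuple(_REGISTRY)


def make_fixture(name: str) -> Fixture:
    """Build a named fixture; unknown names list the registry."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()


def ln_rate(stim: Stimulus, spec: LNSpec) -> RateResponse:
    """Rate of an LN toy neuron: gammatone -> squarer or half-wave rectifier.

    The output is scaled so its mean rate equals ``spec.target_rate``,
    keeping spike counts comparable across filter centers and levels.
    """
    b, a = signal.gammatone(spec.center_hz, "iir", fs=stim.fs)
    y = signal.lfilter(b, a, stim.samples)
    if spec.nonlinearity == "squarer":
        r = y**2
    elif spec.nonlinearity == "hwr":
        r = np.maximum(y, 0.0)
    else:
        raise ValueError(f"unknown nonlinearity {spec.nonlinearity!r}")
    m = np.mean(r)
    if m <= 0:
        raise ValueError("degenerate LN response")
    return RateResponse(r * (spec.target_rate / m), stim.fs, stage="AN", meta={"ln": True})


def noisy_reference(curve: np.ndarray, noise_sd: float, seed: int = 0) -> np.ndarray:
    """Add i.i.d. Gaussian rate noise to a curve, floored at zero.

    Stands in for a recorded rate curve so the correlation-scoring path can
    be exercised without neural data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    curve = np.asarray(curve, dtype=np.float64)
    if noise_sd == 0:
        return curve.copy()
    rng = np.random.default_rng(seed)
    return np.maximum(curve + rng.normal(0.0, noise_sd, size=curve.shape), 0.0)
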