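"""Generalized IC inhibition-excitation cell: construction and dynamics."""

import numpy as np
import pytest

from sfie_ic.periphery import RateResponse
from sfie_ic.sfie import (
    BE_OUT_GAIN,
    IECellSpec,
    SynapticInput,
    build_cell_from_rf,
    driven_rate,
    ic_be_rate,
    ic_bs_rate,
    linear_be_drive,
    original_sfie_cell,
    simulate_cell,
)
from sfie_ic.stimuli import AMSpec, Stimulus, synth_am_noise
from sfie_ic.wiener import RFPeaks

FS_R = 10_000.0


def _dc_inputs(cfs, r0=100.0, n=4000):
    return {cf: RateResponse(np.full(n, r0), FS_R, "CN") for cf in cfs}


def _be_spec(f_exc=2000.0, f_inh=1800.0, s_inh=1.3, delay=2e-3):
    return IECellSpec(
        "BE",
        "b",
        [
            SynapticInput(f_exc, "excitatory", 1.0, 0.0),
            SynapticInput(f_inh, "inhibitory", s_inh, delay),
        ],
    )


class TestSpecValidation:
    def test_needs_excitatory_input(self):
        with pytest.raises(ValueError, match="excitatory"):
            IECellSpec("BE", "b", [SynapticInput(1000.0, "inhibitory", 1.0)])

    @pytest.mark.parametrize("mod", ["a", "b"])
    def test_mod_ab_cardinality(self, mod):
        with pytest.raises(ValueError, match="requires"):
            IECellSpec(
                "BE",
                mod,
                [
                    SynapticInput(1000.0, "excitatory", 1.0),
                    SynapticInput(1000.0, "inhibitory", 1.3),
                    SynapticInput(900.0, "inhibitory", 1.3),
                ],
            )

    def test_mod_a_requires_same_cf(self):
        with pytest.raises(ValueError, match="matching"):
            IECellSpec(
                "BE",
                "a",
                [
                    SynapticInput(1000.0, "excitatory", 1.0),
                    SynapticInput(900.0, "inhibitory", 1.3),
                ],
            )

    def test_bs_gets_default_interneurons(self):
        spec = IECellSpec(
            "BS",
            "c",
            [
                SynapticInput(800.0, "excitatory", 1.0),
                SynapticInput(800.0, "inhibitory", 0.8, 4e-3),
                SynapticInput(960.0, "inhibitory", 0.8, 4e-3),
            ],
        )
        assert len(spec.be_specs) == 2
        assert spec.be_specs[1].excitatory[0].cf_hz == 960.0

    def test_long_inhibitory_latency_warns(self):
        with pytest.warns(UserWarning, match="discontinuities"):
            _be_spec(delay=6e-3)

    def test_serialization_round_trip(self):
        spec = IECellSpec(
            "BS",
            "c",
            [
                SynapticInput(800.0, "excitatory", 1.0),
                SynapticInput(800.0, "inhibitory", 0.8, 4e-3),
                SynapticInput(960.0, "inhibitory", 0.8, 4e-3),
            ],
            name="round_trip",
        )
        again = IECellSpec.from_dict(spec.to_dict())
        assert again.to_dict() == spec.to_dict()


class TestBuildFromRF:
    PEAKS = RFPeaks(
        exc=[(2083.0, 5.0e-3, 1.0), (2500.0, 5.5e-3, 0.6)],
        inh=[(1833.0, 7.3e-3, 0.8), (2100.0, 8.0e-3, 0.4)],
    )

    def test_mod_b_maps_strengths_and_delay(self):
        spec = build_cell_from_rf(self.PEAKS, "b")
        (inh,) = spec.inhibitory
        assert inh.cf_hz == 1833.0
        assert inh.strength == 1.3
        assert inh.latency_s == pytest.approx(2.3e-3)
        assert spec.excitatory[0].strength == 1.0

    def test_mod_a_inherits_excitatory_cf(self):
        spec = build_cell_from_rf(self.PEAKS, "a")
        assert spec.inhibitory[0].cf_hz == spec.excitatory[0].cf_hz == 2083.0

    def test_mod_c_adds_same_cf_inhibition(self):
        spec = build_cell_from_rf(self.PEAKS, "c", cell_class="BS")
        cfs = sorted(s.cf_hz for s in spec.inhibitory)
        assert cfs == [1833.0, 2083.0]
        assert all(s.strength == 0.8 for s in spec.inhibitory)

    def test_mod_d_two_exc_variants(self):
        d1 = build_cell_from_rf(self.PEAKS, "d", d_variant="d1")
        assert [s.strength for s in d1.excitatory] == [1.0, 1.0]
        assert all(s.strength == 1.3 for s in d1.inhibitory)
        d2 = build_cell_from_rf(self.PEAKS, "d", d_variant="d2")
        assert [s.strength for s in d2.excitatory] == [1.0, 0.8]
        assert all(s.strength == 2.2 for s in d2.inhibitory)

    def test_mod_d_one_exc_two_inh(self):
        peaks = RFPeaks(exc=self.PEAKS.exc[:1], inh=self.PEAKS.inh)
        spec = build_cell_from_rf(peaks, "d")
        assert all(s.strength == 0.8 for s in spec.inhibitory)

    def test_missing_inhibitory_peak_rejected(self):
        peaks = RFPeaks(exc=self.PEAKS.exc, inh=[])
        with pytest.raises(ValueError, match="inhibitory"):
            build_cell_from_rf(peaks, "b")

    def test_no_excitatory_peak_rejected(self):
        with pytest.raises(ValueError, match="excitatory"):
            build_cell_from_rf(RFPeaks(exc=[], inh=self.PEAKS.inh), "b")

    def test_negative_relative_latency_floored(self):
        peaks = RFPeaks(exc=[(2000.0, 6e-3, 1.0)], inh=[(1800.0, 5e-3, 0.5)])
        spec = build_cell_from_rf(peaks, "b")
        assert spec.inhibitory[0].latency_s == 0.0


class TestICBE:
    def test_dc_zero_when_inhibition_dominates(self):
        spec = _be_spec(s_inh=1.3)
        out = ic_be_rate(spec, _dc_inputs([2000.0, 1800.0]))
        assert out.rate[-1] == 0.0

    def test_dc_positive_when_excitation_dominates(self):
        spec = _be_spec(s_inh=0.5)
        out = ic_be_rate(spec, _dc_inputs([2000.0, 1800.0]))
        assert out.rate[-1] == pytest.approx(BE_OUT_GAIN * 100.0 * 0.5, rel=1e-3)

    def test_excitation_only_is_smoothed_input(self):
        spec = IECellSpec(
            "BE",
            "b",
            [
                SynapticInput(2000.0, "excitatory", 1.0, 0.0),
                SynapticInput(1800.0, "inhibitory", 0.0, 2e-3),
            ],
        )
        out = ic_be_rate(spec, _dc_inputs([2000.0, 1800.0]))
        assert out.rate[-1] == pytest.approx(BE_OUT_GAIN * 100.0, rel=1e-3)

    def test_missing_channel_names_cf(self):
        spec = _be_spec()
        with pytest.raises(KeyError, match="1800"):
            ic_be_rate(spec, _dc_inputs([2000.0]))

    def test_pre_rectification_drive_is_homogeneous(self):
        """Doubling all input rates doubles the linear (pre-rectified) drive."""
        spec = _be_spec()
        rng = np.random.default_rng(0)
        base = 50.0 + 10.0 * rng.standard_normal(3000).cumsum() * 0.01
        base = np.abs(base)
        cn1 = {cf: RateResponse(base, FS_R, "CN") for cf in (2000.0, 1800.0)}
        cn2 = {cf: RateResponse(2 * base, FS_R, "CN") for cf in (2000.0, 1800.0)}
        d1 = linear_be_drive(spec, cn1)
        d2 = linear_be_drive(spec, cn2)
        assert np.allclose(d2, 2 * d1, rtol=1e-10, atol=1e-9)


class TestICBS:
    def _bs(self):
        return IECellSpec(
            "BS",
            "c",
            [
                SynapticInput(800.0, "excitatory", 1.0, 0.0),
                SynapticInput(800.0, "inhibitory", 0.8, 4e-3),
                SynapticInput(960.0, "inhibitory", 0.8, 4e-3),
            ],
        )

    def test_requires_bs_class(self):
        with pytest.raises(ValueError, match="BS"):
            ic_bs_rate(_be_spec(), _dc_inputs([2000.0, 1800.0]))

    def test_dc_passes_excitation_when_interneurons_silent(self):
        # original-SFIE interneurons are silent at DC (inh > exc), so the
        # BS output equals the alpha-smoothed CN excitation
        out = ic_bs_rate(self._bs(), _dc_inputs([800.0, 960.0]))
        assert out.rate[-1] == pytest.approx(100.0, rel=1e-3)

    def test_anticorrelates_with_inhibiting_be(self):
        """BS rate vs its BE interneuron rate across fm: Pearson r < 0."""
        from sfie_ic.evaluate import compute_mtf

        spec = self._bs()
        bs_rates, be_rates = [], []
        for fm in (4.0, 16.0, 45.0, 90.0, 256.0):
            stim = synth_am_noise(AMSpec("noise", fm, 1.0, level_db=30.0), seed=3)
            bs = simulate_cell(spec, stim)
            be = simulate_cell(spec.be_specs[0], stim)
            bs_rates.append(driven_rate(bs))
            be_rates.append(driven_rate(be))
        r = np.corrcoef(bs_rates, be_rates)[0, 1]
        assert r < 0


class TestSimulateCell:
    def test_zero_stimulus_silences_default_be(self):
        spec = _be_spec()
        stim = Stimulus(np.zeros(int(0.3 * 100_000)), 100_000.0, -np.inf)
        out = simulate_cell(spec, stim)
        assert out.rate[int(0.1 * out.fs) :].mean() < 1.0

    def test_determinism(self):
        spec = _be_spec()
        stim = synth_am_noise(AMSpec("noise", 32.0, 1.0, level_db=30.0), seed=9)
        a = simulate_cell(spec, stim)
        b = simulate_cell(spec, stim)
        assert np.array_equal(a.rate, b.rate)

    def test_mod_a_equals_mod_b_at_same_cf(self):
        """Modification a == b when the RF inhibitory CF equals the excitatory CF."""
        peaks = RFPeaks(exc=[(2000.0, 5e-3, 1.0)], inh=[(2000.0, 7e-3, 0.5)])
        spec_a = build_cell_from_rf(peaks, "a")
        spec_b = build_cell_from_rf(peaks, "b")
        stim = synth_am_noise(AMSpec("noise", 64.0, 1.0, level_db=30.0), seed=2)
        ra = simulate_cell(spec_a, stim)
        rb = simulate_cell(spec_b, stim)
        assert np.allclose(ra.rate, rb.rate, rtol=1e-12, atol=1e-9)

    def test_original_runs_without_rf(self):
        spec = original_sfie_cell(2000.0)
        stim = synth_am_noise(AMSpec("noise", 64.0, 1.0, level_db=30.0), seed=2)
        out = simulate_cell(spec, stim)
        assert out.stage == "IC-BE" and np.all(np.isfinite(out.rate))
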