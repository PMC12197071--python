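"""Analog front-end model: response, cutoffs, conditioning, tolerances, ADC."""

import math

import numpy as np
import pytest

from motkit import (
    ChainParams,
    EMGTrace,
    FrequencyResponse,
    SynthSpec,
    ToleranceSpec,
    apply_chain,
    corner_scale,
    extract_cutoffs,
    frequency_response,
    generate_semg,
    highpass_response,
    lowpass_response,
    quantize,
    tolerance_monte_carlo,
)
from motkit.signal_chain import default_freq_grid

HP_ANALYTIC_F_LOW = 20.0 * math.sqrt(1.0 / (math.sqrt(2.0) - 1.0))  # ~31.08 Hz


class TestFrequencyResponse:
    def test_midband_gain_is_product_of_stage_gains(self, chain_params):
        fr = frequency_response(chain_params, np.array([150.0]))
        expected = 20 * math.log10(100 * 9.27)  # 59.34 dB
        assert fr.magnitude_db[0] == pytest.approx(expected, abs=0.2)

    def test_dc_is_blocked(self, chain_params):
        fr = frequency_response(chain_params, np.array([1e-3, 1e-2]))
        assert fr.magnitude_db[0] < -100
        assert fr.magnitude_db[0] < fr.magnitude_db[1]

    def test_two_cascaded_sections_give_6db_at_corner(self, chain_params):
        # each first-order section contributes -3.01 dB at its corner
        fr = highpass_response(chain_params, np.array([20.0, 1e5]))
        assert fr.magnitude_db[0] - fr.magnitude_db[1] == pytest.approx(
            -2 * 10 * math.log10(2), abs=1e-3
        )

    def test_asymptotic_slope_above_lowpass_is_40db_per_decade(self, chain_params):
        fr = frequency_response(chain_params, np.array([1e4, 1e5]))
        slope = fr.magnitude_db[1] - fr.magnitude_db[0]
        assert slope == pytest.approx(-40.0, abs=0.5)

    def test_rejects_nonpositive_frequency(self, chain_params):
        with pytest.raises(ValueError):
            frequency_response(chain_params, np.array([0.0, 10.0]))

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            ChainParams(hp_fc=600.0, lp_fc=500.0)
        with pytest.raises(ValueError):
            ChainParams(v_offset=4.0)


class TestExtractCutoffs:
    def test_highpass_stage_low_cutoff_near_31hz(self, chain_params):
        f_low, f_high = extract_cutoffs(highpass_response(chain_params))
        assert f_low == pytest.approx(HP_ANALYTIC_F_LOW, abs=0.05)
        assert math.isnan(f_high)  # high-pass never falls off on the right

    def test_full_chain_low_cutoff(self, chain_params):
        # the 500 Hz stage pulls the curve maximum slightly below the
        # mid-band product, moving the -3 dB-from-max point to ~30 Hz
        f_low, f_high = extract_cutoffs(frequency_response(chain_params))
        assert f_low == pytest.approx(30.0, abs=0.5)
        assert f_high == pytest.approx(509.0, abs=2.0)

    def test_butterworth_lowpass_cuts_at_design_frequency(self, chain_params):
        _, f_high = extract_cutoffs(lowpass_response(chain_params))
        assert f_high == pytest.approx(500.0, rel=1e-3)

    def test_ideal_rectangular_bandpass(self):
        freqs = default_freq_grid(1.0, 1000.0)
        mags = np.where((freqs >= 50) & (freqs <= 100), 0.0, -60.0)
        f_low, f_high = extract_cutoffs(FrequencyResponse(freqs, mags))
        assert f_low == pytest.approx(50.0, rel=0.01)
        assert f_high == pytest.approx(100.0, rel=0.01)

    def test_single_first_order_corner_is_its_design_frequency(self):
        freqs = default_freq_grid(1.0, 1e5)
        mags = 20 * np.log10(freqs / np.sqrt(freqs**2 + 20.0**2))
        f_low, _ = extract_cutoffs(FrequencyResponse(freqs, mags))
        assert f_low == pytest.approx(20.0, rel=1e-3)

    def test_invariant_to_constant_db_offset(self, chain_params):
        fr = frequency_response(chain_params)
        shifted = FrequencyResponse(fr.freqs, fr.magnitude_db + 17.0)
        assert extract_cutoffs(fr) == pytest.approx(extract_cutoffs(shifted))


class TestApplyChain:
    def test_zero_input_sits_at_dc_offset(self, chain_params):
        trace = EMGTrace(np.zeros(10_000), 10_000.0)
        out = apply_chain(trace, chain_params)
        assert np.all(out.samples == chain_params.v_offset)

    def test_midband_sinusoid_amplified_by_927(self, chain_params):
        fs, f = 10_000.0, 150.0
        t = np.arange(int(fs)) / fs
        a = 1e-3
        trace = EMGTrace(a * np.sin(2 * np.pi * f * t), fs)
        out = apply_chain(trace, chain_params).samples - chain_params.v_offset
        tail = out[len(out) // 2 :]
        measured = (tail.max() - tail.min()) / 2
        fr = frequency_response(chain_params, np.array([f]))
        expected = a * 10 ** (fr.magnitude_db[0] / 20)
        assert measured == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("f", np.logspace(1, 3, 7).round(2))
    def test_time_domain_matches_analytic_response(self, chain_params, f):
        fs = 20_000.0
        t = np.arange(int(fs)) / fs
        a = 1e-3
        trace = EMGTrace(a * np.sin(2 * np.pi * f * t), fs)
        y = apply_chain(trace, chain_params).samples - chain_params.v_offset
        tail = slice(len(y) // 2, None)
        design = np.column_stack(
            [np.sin(2 * np.pi * f * t[tail]), np.cos(2 * np.pi * f * t[tail])]
        )
        coef, *_ = np.linalg.lstsq(design, y[tail], rcond=None)
        measured = float(np.hypot(*coef))
        fr = frequency_response(chain_params, np.array([f]))
        assert measured == pytest.approx(a * 10 ** (fr.magnitude_db[0] / 20), rel=0.02)

    def test_rail_clipping_is_exact(self, chain_params):
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        trace = EMGTrace(0.1 * np.sin(2 * np.pi * 100 * t), fs)  # grossly overdriven
        out = apply_chain(trace, chain_params).samples
        assert out.min() == chain_params.v_rail_lo
        assert out.max() == chain_params.v_rail_hi

    def test_rejects_too_low_simulation_rate(self, chain_params):
        with pytest.raises(ValueError):
            apply_chain(EMGTrace(np.zeros(100), 2000.0), chain_params)


class TestToleranceMonteCarlo:
    def test_zero_tolerance_reproduces_nominal(self, chain_params):
        res = tolerance_monte_carlo(
            chain_params, ToleranceSpec(r_tol=0.0, c_tol=0.0, n_draws=5, seed=1)
        )
        assert np.allclose(res.f_low, res.nominal_f_low)
        assert np.allclose(res.f_high, res.nominal_f_high)
        assert res.nominal_f_low == pytest.approx(HP_ANALYTIC_F_LOW, abs=0.05)
        assert res.nominal_f_high == pytest.approx(500.0, rel=1e-3)

    def test_capacitors_at_minus_ten_percent_scale_corner_by_1_11(self):
        assert corner_scale(0.0, -0.10) == pytest.approx(1 / 0.9)
        assert corner_scale(0.0, +0.10) == pytest.approx(1 / 1.1)

    def test_draws_respect_interval_arithmetic_bounds(self, chain_params):
        res = tolerance_monte_carlo(chain_params, ToleranceSpec(n_draws=1000, seed=0))
        lo = 1.0 / (1.10 * 1.01)
        hi = 1.0 / (0.90 * 0.99)
        for factors in (res.f_low / res.nominal_f_low, res.f_high / res.nominal_f_high):
            assert factors.min() >= lo - 1e-9
            assert factors.max() <= hi + 1e-9

    def test_fixed_seed_reproducible(self, chain_params):
        tol = ToleranceSpec(n_draws=50, seed=3)
        a = tolerance_monte_carlo(chain_params, tol)
        b = tolerance_monte_carlo(chain_params, tol)
        assert np.array_equal(a.f_low, b.f_low)


class TestQuantize:
    def _trace(self, volts, fs=10_000.0):
        return EMGTrace(np.asarray(volts, dtype=float), fs)

    def test_midscale_voltage_maps_to_code_2048(self):
        dt = quantize(self._trace([1.65] * 10), fs=10_000.0)
        assert np.all(dt.codes == 2048)

    def test_clamping_at_rails(self):
        dt = quantize(self._trace([-1.0, 0.0, 3.3, 5.0]), fs=10_000.0)
        assert list(dt.codes) == [0, 0, 4095, 4095]

    def test_reconstruction_error_within_half_lsb(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.0, 3.3, size=1000)
        trace = self._trace(v)
        dt = quantize(trace, fs=10_000.0)
        lsb = 3.3 / 4096
        err = np.abs(v - dt.to_volts())
        assert err.max() <= lsb / 2 + 1e-12

    def test_decimation_keeps_every_kth_sample(self):
        v = np.linspace(0.0, 3.2, 100)
        dt = quantize(self._trace(v, fs=10_000.0), fs=1000.0)
        assert len(dt.codes) == 10
        expected = np.floor(v[::10] / 3.3 * 4096).astype(int)
        assert np.array_equal(dt.codes, expected)

    def test_rejects_non_integer_decimation(self):
        with pytest.raises(ValueError):
            quantize(self._trace(np.zeros(100), fs=2500.0), fs=1000.0)
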