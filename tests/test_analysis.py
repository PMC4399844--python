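"""Haemodynamic indices and input impedance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dissectlpm as d
from dissectlpm.analysis import (
    AnalysisError,
    fpi,
    index_of_direction,
    input_impedance,
    pressure_indices,
    tear_velocity,
    tsf,
)
from dissectlpm.simulate import SimulationResult
from dissectlpm.waveforms import PeriodicWaveform


def _result_from_pressures(p_tl, p_fl, period=1.0, **extra):
    n = len(p_tl)
    t = np.arange(n) * period / n
    zeros = np.zeros(n)
    base = dict(
        time=t, p_tl=np.asarray(p_tl, float), p_fl=np.asarray(p_fl, float),
        p_dt=np.asarray(p_fl, float), p_ph=np.asarray(p_tl, float),
        q_i=zeros, q_tli=zeros, q_tlo=zeros, q_pt=zeros, q_fl=zeros, q_ph=zeros,
        period=period, cycles_run=3, converged=True,
    )
    base.update(extra)
    return SimulationResult(**base)


class TestPressureIndices:
    def test_sinusoid_extrema(self):
        t = np.arange(100) / 100
        res = _result_from_pressures(100 + 20 * np.sin(2 * np.pi * t), 90 + 10 * np.sin(2 * np.pi * t))
        idx = pressure_indices(res)
        pi = idx["proximal"]["tl"]
        assert pi.sp == pytest.approx(120, abs=0.05)
        assert pi.dp == pytest.approx(80, abs=0.05)
        assert pi.pp == pytest.approx(40, abs=0.1)

    def test_constant_pressure_zero_pulse(self):
        res = _result_from_pressures(np.full(100, 80.0), np.full(100, 80.0))
        pi = pressure_indices(res)["distal"]["fl"]
        assert pi.sp == pi.dp == 80.0 and pi.pp == 0.0

    def test_nonconverged_rejected_unless_forced(self, result_s44):
        res = _result_from_pressures(np.ones(100), np.ones(100), converged=False)
        with pytest.raises(AnalysisError):
            pressure_indices(res)
        assert pressure_indices(res, force=True)


class TestFPI:
    def test_equal_pressures_hundred_percent(self):
        t = np.arange(100) / 100
        p = 100 + 20 * np.sin(2 * np.pi * t)
        out = fpi(_result_from_pressures(p, p))
        assert out["proximal"]["systolic"] == pytest.approx(100.0)
        assert out["proximal"]["diastolic"] == pytest.approx(100.0)

    def test_ratio_arithmetic(self):
        t = np.arange(100) / 100
        res = _result_from_pressures(
            60 + 40 * np.sin(2 * np.pi * t), 60 + 34.2 * np.sin(2 * np.pi * t)
        )
        out = fpi(res)
        assert out["proximal"]["systolic"] == pytest.approx(94.2, abs=0.1)


class TestTSF:
    def _res_with_peaks(self, t_tl, t_fl, period=1.0, n=100):
        t = np.arange(n) * period / n
        p_tl = 100 + 10 * np.cos(2 * np.pi * (t - t_tl) / period)
        p_fl = 95 + 8 * np.cos(2 * np.pi * (t - t_fl) / period)
        return _result_from_pressures(p_tl, p_fl)

    def test_identical_waveforms_zero_shift(self):
        res = self._res_with_peaks(0.30, 0.30)
        assert tsf(res)["proximal"] == pytest.approx(0.0, abs=1e-12)

    def test_later_fl_peak_positive(self):
        assert tsf(self._res_with_peaks(0.30, 0.35))["proximal"] == pytest.approx(0.05, abs=1e-9)

    def test_circular_wrap(self):
        assert tsf(self._res_with_peaks(0.95, 0.05))["proximal"] == pytest.approx(0.10, abs=1e-9)

    def test_flat_waveform_undefined(self):
        res = _result_from_pressures(np.full(100, 90.0), np.ones(100))
        with pytest.raises(AnalysisError):
            tsf(res)


class TestIndexOfDirection:
    def test_codirected_is_one(self):
        q = np.maximum(np.sin(2 * np.pi * np.arange(100) / 100), 0.0)
        assert index_of_direction(q, q) == pytest.approx(1.0)

    def test_counter_directed_is_zero(self):
        q = np.sin(2 * np.pi * np.arange(100) / 100) + 0.3
        assert index_of_direction(q, -q) == pytest.approx(0.0, abs=1e-12)

    def test_constant_example_third(self):
        q_pt = np.ones(100)
        q_dt = np.full(100, -0.5)
        assert index_of_direction(q_pt, q_dt) == pytest.approx(1.0 / 3.0, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_bounded_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=64), rng.normal(size=64)
        val = index_of_direction(a, b)
        assert 0.0 <= val <= 1.0

    def test_zero_series_undefined(self):
        with pytest.raises(AnalysisError):
            index_of_direction(np.zeros(10), np.zeros(10))


class TestTearVelocity:
    def test_area_arithmetic(self):
        v = tear_velocity(np.array([1.0]), diameter=0.010, obstruction_fraction=0.0)
        assert v[0] == pytest.approx(0.01273, rel=1e-3)

    def test_obstruction_scales_four_thirds(self):
        q = np.array([2.5, -1.0])
        v0 = tear_velocity(q, 0.004, 0.0)
        v25 = tear_velocity(q, 0.004, 0.25)
        assert np.allclose(v25, v0 * 4.0 / 3.0)

    def test_zero_flow_zero_velocity(self):
        assert tear_velocity(np.zeros(5), 0.004)[2] == 0.0

    def test_full_obstruction_rejected(self):
        with pytest.raises(AnalysisError):
            tear_velocity(np.ones(3), 0.004, 1.0)


class TestInputImpedance:
    def test_pure_resistor(self):
        t = np.arange(128) / 128
        q = 50 + 20 * np.sin(2 * np.pi * t) + 5 * np.cos(6 * np.pi * t)
        R = 1.7
        spec = input_impedance(R * q, q)
        assert np.allclose(spec.modulus[spec.defined], R, rtol=1e-9)
        assert np.allclose(spec.phase[spec.defined], 0.0, atol=1e-9)

    def test_dc_harmonic_is_mean_ratio(self, result_s44):
        spec = input_impedance(result_s44.p_tl, result_s44.q_i)
        assert spec.modulus[0] == pytest.approx(
            result_s44.p_tl.mean() / result_s44.q_i.mean(), rel=1e-9
        )
        assert spec.phase[0] == 0.0

    def test_rc_phase_closed_form(self):
        """Pressure synthesised analytically through a parallel-RC load;
        the DFT-ratio impedance must recover -atan(w R C) per harmonic."""
        R, C, T, n = 1.5, 0.12, 1.0, 256
        t = np.arange(n) * T / n
        q = 60 + 25 * np.sin(2 * np.pi * t / T) + 10 * np.sin(6 * np.pi * t / T + 0.4)
        p = np.full(n, 60.0 * R)
        for k, amp, ph0 in [(1, 25.0, 0.0), (3, 10.0, 0.4)]:
            w = 2 * math.pi * k / T
            zmag = R / math.hypot(1.0, w * R * C)
            zph = -math.atan(w * R * C)
            p += amp * zmag * np.sin(w * t + ph0 + zph)
        spec = input_impedance(p, q)
        for k in (1, 3):
            w = 2 * math.pi * k / T
            assert spec.phase[k] == pytest.approx(-math.atan(w * R * C), abs=1e-6)
            assert spec.modulus[k] == pytest.approx(R / math.hypot(1.0, w * R * C), rel=1e-6)

    def test_undefined_harmonics_flagged(self):
        t = np.arange(64) / 64
        q = 10 + np.sin(2 * np.pi * t)  # only harmonics 0 and 1 present
        spec = input_impedance(np.ones(64), q)
        assert spec.defined[0] and spec.defined[1]
        assert not spec.defined[5]
        assert np.isnan(spec.modulus[5])

    def test_full_model_dc_impedance_equals_network_resistance(
        self, result_s1010, model_s1010, peripheral
    ):
        spec = input_impedance(result_s1010.p_tl, result_s1010.q_i)
        r_tl = model_s1010.tl_elements.resistance
        r_path = (
            model_s1010.proximal_tear.resistance
            + model_s1010.fl_elements.resistance
            + model_s1010.distal_tear.resistance
        )
        expected = peripheral.resistance + r_tl * r_path / (r_tl + r_path)
        assert spec.modulus[0] == pytest.approx(expected, rel=5e-3)
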