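import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoloop import (LoopConfig, NoBandwidthError, ao_bandwidth,
                    bandwidth_vs_rate_gain, continuous_loop,
                    continuous_two_frame_loop, conventional_loop,
                    fig_rate_family_loop, low_frequency_rejection_ratio,
                    noise_propagated_rms, noise_transfer_power_curve,
                    open_loop_transfer, rejection_power_curve, ultrafast_loop)


class TestLoopConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            LoopConfig(t_integration=-1e-3)
        with pytest.raises(ValueError):
            LoopConfig(loop_rate=0.0)
        with pytest.raises(ValueError):
            LoopConfig(loop_gain=2.0)
        with pytest.raises(ValueError):
            LoopConfig(scheme="triggered")

    def test_discontinuous_rate_bound(self):
        # a discontinuous loop cannot cycle faster than integration + readout
        with pytest.raises(ValueError):
            LoopConfig(t_integration=2e-3, t_delay=2e-3, loop_rate=300.0)

    def test_rate_gain_products(self):
        assert ultrafast_loop().rate_gain_product == pytest.approx(233.0)
        assert continuous_loop().rate_gain_product == pytest.approx(153.9)


class TestOpenLoopTransfer:
    def test_integrator_pole_at_low_frequency(self):
        cfg = ultrafast_loop()
        f = np.array([1e-4])
        expected = cfg.rate_gain_product / (2 * np.pi * f[0])
        assert abs(open_loop_transfer(cfg, f)[0]) == pytest.approx(expected, rel=1e-2)

    def test_exposure_factor_sinc_limit(self):
        # vanishing integration time: exposure averaging factor -> 1
        short = LoopConfig(t_integration=1e-9, loop_rate=233.0, scheme="continuous")
        ref = LoopConfig(t_integration=0.126e-3, loop_rate=233.0, scheme="continuous")
        g_short = open_loop_transfer(short, 10.0)
        s = 2j * np.pi * 10.0
        bare = np.exp(-s * short.t_delay) / s / (1 + short.t_dm * 10.0) * 233.0
        assert abs(g_short / bare - 1.0) < 1e-6
        assert abs(g_short) > abs(open_loop_transfer(ref, 10.0))

    def test_modulus_is_product_of_factor_moduli(self):
        # term-by-term oracle at 20 Hz
        cfg = ultrafast_loop()
        f = 20.0
        s = 2j * np.pi * f
        m1 = abs((1 - np.exp(-s * cfg.t_integration)) / (s * cfg.t_integration))
        m2 = abs(np.exp(-s * cfg.t_delay) / s)
        m3 = 1.0 / (1.0 + cfg.t_dm * f)
        assert abs(open_loop_transfer(cfg, f)) == pytest.approx(
            m1 * m2 * m3 * cfg.rate_gain_product, rel=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            open_loop_transfer(ultrafast_loop(), 0.0)


class TestRejectionCurve:
    def test_perfect_dc_rejection(self):
        curve = rejection_power_curve(ultrafast_loop(), np.array([1e-5]))
        assert curve.power_rejection[0] < 1e-10

    def test_low_frequency_asymptote(self):
        # |H_reject|^2 -> (2*pi*f / rate-gain)^2 as f -> 0
        curve = rejection_power_curve(ultrafast_loop(), np.array([1.0]))
        assert curve.power_rejection[0] == pytest.approx(
            (2 * np.pi / 233.0) ** 2, rel=0.05)

    def test_unity_at_bandwidth(self):
        cfg = ultrafast_loop()
        f_c = ao_bandwidth(cfg).f_c
        curve = rejection_power_curve(cfg, np.array([f_c]))
        assert curve.power_rejection[0] == pytest.approx(1.0, abs=1e-3)

    def test_below_bandwidth_rejection_below_unity(self):
        cfg = ultrafast_loop()
        f_c = ao_bandwidth(cfg).f_c
        f = np.linspace(0.1, f_c * 0.999, 400)
        curve = rejection_power_curve(cfg, f)
        assert np.all(curve.power_rejection < 1.0)

    def test_pure_integrator_closed_form(self):
        # with all delays removed the loop is a plain integrator:
        # |H_reject|^2 = f^2 / (f^2 + (K/2pi)^2)
        cfg = LoopConfig(t_integration=0.0, t_delay=0.0, t_dm=0.0,
                         loop_rate=100.0, loop_gain=1.0, scheme="continuous")
        f = np.logspace(-1, 2, 50)
        curve = rejection_power_curve(cfg, f)
        k = cfg.rate_gain_product / (2 * np.pi)
        expected = f ** 2 / (f ** 2 + k ** 2)
        assert np.allclose(curve.power_rejection, expected, rtol=1e-6)


class TestBandwidth:
    def test_printed_bandwidths(self):
        assert ao_bandwidth(ultrafast_loop()).f_c == pytest.approx(35.0, abs=0.05)
        assert ao_bandwidth(continuous_loop()).f_c == pytest.approx(28.2, abs=0.07)

    def test_conventional_mimic_bandwidth(self):
        # quoted theoretical maximum for conventional ophthalmic AO
        assert ao_bandwidth(conventional_loop()).f_c == pytest.approx(1.4, abs=0.05)

    def test_methods_agree(self):
        for cfg in (ultrafast_loop(), continuous_loop(), conventional_loop()):
            a = ao_bandwidth(cfg, method="eq_root").f_c
            b = ao_bandwidth(cfg, method="unity_crossing").f_c
            assert abs(a - b) < 0.1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ao_bandwidth(ultrafast_loop(), method="bisect")

    def test_no_bandwidth_for_pure_integrator(self):
        # a delay-free integrator never amplifies: rejection < 1 everywhere
        cfg = LoopConfig(t_integration=0.0, t_delay=0.0, t_dm=0.0,
                         loop_rate=100.0, loop_gain=1.0, scheme="continuous")
        with pytest.raises(NoBandwidthError):
            ao_bandwidth(cfg, method="unity_crossing")

    def test_monotone_in_rate_gain_product(self):
        products = np.linspace(10.0, 500.0, 10)
        f_c = bandwidth_vs_rate_gain(ultrafast_loop(), products)
        assert np.all(np.diff(f_c) > 0)

    def test_printed_rate_gain_points(self):
        f_c = bandwidth_vs_rate_gain(ultrafast_loop(), [153.9, 233.0])
        assert f_c[0] == pytest.approx(28.2, abs=0.07)
        assert f_c[1] == pytest.approx(35.0, abs=0.05)

    def test_doubling_product_increases_bandwidth(self):
        f1, f2 = bandwidth_vs_rate_gain(ultrafast_loop(), [116.5, 233.0])
        assert f2 > f1


class TestNoiseTransfer:
    def test_unity_at_dc(self):
        curve = noise_transfer_power_curve(ultrafast_loop(), np.array([1e-4]))
        assert curve.power_rejection[0] == pytest.approx(1.0, abs=1e-4)

    def test_ultrafast_has_almost_no_amplification(self):
        f = np.linspace(0.01, 116.5, 4000)
        curve = noise_transfer_power_curve(ultrafast_loop(), f)
        assert curve.power_rejection.max() <= 1.2

    def test_two_frame_continuous_amplifies_more(self):
        f = np.linspace(0.01, 171.0, 4000)
        two_frame = noise_transfer_power_curve(continuous_two_frame_loop(), f)
        ultra = noise_transfer_power_curve(
            ultrafast_loop(), np.linspace(0.01, 116.5, 4000))
        assert two_frame.power_rejection.max() > ultra.power_rejection.max()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(t_int=st.floats(0.0, 50e-3), t_delay=st.floats(0.0, 50e-3),
           t_dm=st.floats(0.0, 2e-3), gain=st.floats(0.05, 1.5),
           rate=st.floats(1.0, 500.0))
    def test_rejection_plus_noise_transfer_is_identity(self, t_int, t_delay,
                                                       t_dm, gain, rate):
        # H_reject + H_noise = 1/(1+G) + G/(1+G) = 1 at every frequency,
        # for any loop parameters
        cfg = LoopConfig(t_integration=t_int, t_delay=t_delay, t_dm=t_dm,
                         loop_rate=rate, loop_gain=gain, scheme="continuous")
        f = np.logspace(-1, 2, 50)
        g = open_loop_transfer(cfg, f)
        assert np.allclose(1.0 / (1.0 + g) + g / (1.0 + g), 1.0, atol=1e-12)


class TestRejectionRatioAndNoisePropagation:
    def test_identical_configs_ratio_one(self):
        assert low_frequency_rejection_ratio(
            ultrafast_loop(), ultrafast_loop()) == pytest.approx(1.0, rel=1e-6)

    def test_conventional_vs_ultrafast_improvement(self):
        ratio = low_frequency_rejection_ratio(conventional_loop(), ultrafast_loop())
        assert ratio >= 500.0
        assert ratio == pytest.approx((233.0 / 10.0) ** 2, rel=0.01)

    def test_10_vs_200_hz_is_400(self):
        ratio = low_frequency_rejection_ratio(fig_rate_family_loop(10.0),
                                              fig_rate_family_loop(200.0))
        assert ratio == pytest.approx(400.0, rel=0.01)

    def test_noise_propagation_printed_value(self):
        rms = noise_propagated_rms(0.100, ultrafast_loop(), 790.0)
        assert rms == pytest.approx(12.6, abs=0.25)

    def test_noise_propagation_linearity(self):
        cfg = ultrafast_loop()
        assert noise_propagated_rms(0.0, cfg, 790.0) == 0.0
        one = noise_propagated_rms(0.05, cfg, 790.0)
        two = noise_propagated_rms(0.10, cfg, 790.0)
        assert two == pytest.approx(2 * one, rel=1e-9)
        with pytest.raises(ValueError):
            noise_propagated_rms(-0.1, cfg, 790.0)
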