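"""Analytic oracle self-checks (cheap parts; solver-vs-oracle comparisons
run in the acceptance suite)."""

import numpy as np
import pytest

from pvsporo.oracles import (brinkman_channel_reference,
                             cross_correlation_lag, terzaghi_reference)


class TestTerzaghiSeries:
    def test_full_consolidation_limit(self):
        x = np.linspace(0, 150e-6, 20)
        p = terzaghi_reference(x, t=1e4, sigma0=10.0, L=150e-6, c_v=8e-8)
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_undrained_limit(self):
        # just after loading the interior carries the full load
        x = np.linspace(0, 150e-6, 50)
        p = terzaghi_reference(x, t=2e-4, sigma0=10.0, L=150e-6, c_v=8e-8)
        interior = x > 30e-6
        assert np.allclose(p[interior], 10.0, rtol=1e-3)
        assert abs(p[0]) < 1e-9          # drained face

    def test_monotone_decay_in_time(self):
        x = np.array([100e-6])
        ts = [0.01, 0.1, 0.3, 1.0]
        vals = [terzaghi_reference(x, t, 10.0, 150e-6, 8e-8)[0] for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestBrinkmanProfile:
    def test_darcy_core_limit(self):
        # sqrt(k) << h: core velocity = k G / mu (plug flow)
        y = np.array([0.0])
        v = brinkman_channel_reference(y, k_s=1e-14, G=1e3, mu_f=1e-3,
                                       h=25e-6)
        assert np.isclose(v[0], 1e-14 * 1e3 / 1e-3, rtol=1e-6)

    def test_stokes_limit_recovers_poiseuille(self):
        # k -> inf: u -> G/(2 mu) (h^2 - y^2)
        h = 25e-6
        y = np.linspace(-h, h, 11)
        v = brinkman_channel_reference(y, k_s=1e-4, G=1e3, mu_f=1e-3, h=h)
        poiseuille = 1e3 / (2e-3) * (h**2 - y**2)
        assert np.allclose(v, poiseuille, rtol=1e-3)

    def test_no_slip_walls(self):
        v = brinkman_channel_reference(np.array([-25e-6, 25e-6]),
                                       2e-12, 1e3, 1e-3, 25e-6)
        assert np.allclose(v, 0.0, atol=1e-20)


class TestCrossCorrelationLag:
    def test_known_shift_recovered(self):
        dt = 0.01
        t = np.arange(0, 6, dt)
        f = np.exp(-(t - 1.5) ** 2 / 0.1)
        shift = 0.37
        g = np.exp(-(t - 1.5 - shift) ** 2 / 0.1)
        assert np.isclose(cross_correlation_lag(f, g, dt), shift,
                          atol=1.5 * dt)

    def test_zero_lag_for_identical_signals(self):
        dt = 0.02
        f = np.sin(np.linspace(0, 3, 200)) ** 2
        assert cross_correlation_lag(f, f.copy(), dt) == 0.0
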