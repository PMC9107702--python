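"""Boundary-condition data: wall motion, Robin resistance, SAS pressures."""

import numpy as np
import pytest

from pvsporo.bc import (RobinOutflowBC, SASPressureBC, WallMotionBC,
                        robin_outflow_pressure, wall_displacement)
from pvsporo.units import MMHG, UM
from pvsporo.waveforms import WaveformSpec


@pytest.fixture
def wall():
    return WallMotionBC(WaveformSpec(kind="asymmetric"))


class TestWallMotion:
    def test_zero_at_t0(self, wall):
        X = np.array([[10e-6, 0.0, 75e-6], [0.0, 10e-6, 160e-6]])
        assert np.allclose(wall.displacement(X, 0.0), 0.0)
        assert np.allclose(wall.velocity(X, 0.0), 0.0, atol=1e-20)

    def test_twenty_percent_dilation_peak(self, wall):
        # 20% diameter dilation peaks at an1 = 2 um at R0 = 10 um
        X = np.array([[10e-6, 0.0, 100e-6]])
        tp = wall.waveform.t_peak
        u = wall.displacement(X, tp)
        assert np.isclose(np.linalg.norm(u), 2e-6, rtol=1e-3)

    def test_radial_scaling_formula(self):
        # point (x, y) = (10, 0) um with an1 = 2 -> u = (2, 0, 0) um
        wf = lambda t: (2.0, 0.0)
        u, v = wall_displacement(0.0, np.array([[10e-6, 0.0, 50e-6]]), wf)
        assert np.allclose(u, [[2e-6, 0.0, 0.0]])
        assert np.allclose(v, 0.0)
        # deep point at smaller radius moves proportionally less
        u2, _ = wall_displacement(0.0, np.array([[7.5e-6, 0.0, 0.0]]), wf)
        assert np.allclose(u2, [[1.5e-6, 0.0, 0.0]])

    def test_velocity_is_time_derivative(self, wall):
        X = np.array([[9e-6, 2e-6, 80e-6]])
        t, h = 1.3, 1e-6
        num = (wall.displacement(X, t + h) - wall.displacement(X, t - h)) \
            / (2 * h)
        assert np.allclose(wall.velocity(X, t), num, rtol=1e-5)

    def test_amplitude_tapers_to_zero_at_dura(self, wall):
        tp = wall.waveform.t_peak
        high = wall.displacement(np.array([[10e-6, 0.0, 195e-6]]), tp)
        assert np.allclose(high, 0.0)


class TestRobin:
    def test_zero_flow_zero_pressure(self):
        assert robin_outflow_pressure(0.0) == 0.0

    def test_reference_resistance_coefficient(self):
        # 10 * (150e-6 * 1e-3 / 2e-14) / (pi ((13e-6)^2 - (7.5e-6)^2))
        bc = RobinOutflowBC()
        assert np.isclose(bc.coefficient, 2.117e17, rtol=1e-3)

    def test_linearity_and_dissipativity(self):
        bc = RobinOutflowBC()
        q = 3.3e-18
        assert np.isclose(bc.pressure(2 * q), 2 * bc.pressure(q))
        for qq in (q, -q):
            assert bc.pressure(qq) * qq >= 0.0


class TestSASPressure:
    def test_ramp_profile(self):
        bc = SASPressureBC()
        v0 = bc.values(0.0)
        vh = bc.values(0.05)
        v1 = bc.values(0.5)
        assert v0["sas_inlet"] == 0.0
        assert np.isclose(vh["sas_inlet"], 0.5 * 0.01 * MMHG)
        assert np.isclose(v1["sas_inlet"], 0.01 * MMHG)
        assert v1["sas_outlet"] == 0.0

    def test_reduced_pressure_variant(self):
        bc = SASPressureBC(P1_mmHg=0.001)
        assert np.isclose(bc.values(1.0)["sas_inlet"], 0.001 * MMHG)
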