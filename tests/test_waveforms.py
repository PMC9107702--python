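"""Wall-motion waveform shapes, derivatives and event trains."""

import numpy as np
import pytest

from pvsporo.waveforms import (WaveformSpec, event_train, make_waveform,
                               waveform_metrics)


@pytest.fixture(scope="module")
def sym():
    return WaveformSpec(kind="symmetric")


@pytest.fixture(scope="module")
def asym():
    return WaveformSpec(kind="asymmetric")


class TestPulseShapes:
    def test_peak_amplitude_awake_and_sleep(self, sym, asym):
        # 2 um radial = 20% of the 20 um diameter; sleep doubles it
        for spec in (sym, asym):
            assert np.isclose(waveform_metrics(spec)["peak_displacement"],
                              2.0, rtol=1e-3)
        sleep = make_waveform("asymmetric", "sleep")
        assert np.isclose(waveform_metrics(sleep)["peak_displacement"], 4.0,
                          rtol=1e-3)

    def test_zero_at_event_boundaries(self, sym, asym):
        for spec in (sym, asym):
            v, dv = spec.pulse(np.array([0.0, spec.T_d]))
            assert np.allclose(v, 0.0, atol=1e-12)
            assert np.allclose(dv, 0.0, atol=1e-9)

    def test_nonnegative(self, sym, asym):
        t = np.linspace(0, 10, 5001)
        for spec in (sym, asym):
            assert np.all(spec.pulse(t)[0] >= -1e-15)

    def test_symmetric_velocity_antisymmetry(self, sym):
        tau = np.linspace(0.05, 1.8, 50)
        _, d_plus = sym.pulse(sym.t_peak + tau)
        _, d_minus = sym.pulse(sym.t_peak - tau)
        assert np.allclose(d_plus, -d_minus, atol=1e-12)
        assert np.isclose(waveform_metrics(sym)["velocity_ratio"], 1.0,
                          rtol=1e-6)

    def test_asymmetric_velocity_ratio_and_rise_time(self, asym):
        m = waveform_metrics(asym)
        assert 0.4 <= m["velocity_ratio"] <= 0.6       # ~ half
        assert m["t_peak"] <= 2.0                      # fast dilation
        # slow return: below 1% of peak before the end-window shut-off
        v, _ = asym.pulse(np.array([0.85 * asym.T_d]))
        assert v[0] < 0.02 * m["peak_displacement"]

    def test_auc_ratio_near_two(self, sym, asym):
        r = waveform_metrics(asym)["auc"] / waveform_metrics(sym)["auc"]
        assert 1.8 <= r <= 2.2

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec(kind="asymmetric", alpha=1.0)      # ratio too low
        with pytest.raises(ValueError):
            WaveformSpec(kind="sawtooth")
        with pytest.raises(ValueError):
            WaveformSpec(kind="symmetric", T_d=12.0, period=10.0)


class TestDerivatives:
    @pytest.mark.parametrize("kind", ["symmetric", "asymmetric"])
    def test_analytic_matches_numeric(self, kind):
        spec = WaveformSpec(kind=kind)
        t = np.linspace(0.1, spec.T_d - 0.1, 400)
        v, dv = spec.pulse(t)
        h = 1e-6
        num = (spec.pulse(t + h)[0] - spec.pulse(t - h)[0]) / (2 * h)
        assert np.allclose(dv, num, rtol=1e-5,
                           atol=1e-6 * np.abs(dv).max())


class TestEventTrain:
    def test_six_events_in_sixty_seconds(self, asym):
        train = event_train(asym.pulse, period=10.0, T_total=60.0)
        t = np.linspace(0, 60, 60001)
        v, _ = train(t)
        # count rising crossings of half max
        up = np.sum((v[1:] > 1.0) & (v[:-1] <= 1.0))
        assert up == 6
        assert np.isclose(v.max(), 2.0, rtol=1e-3)

    def test_periodicity(self, asym):
        t = np.linspace(0.2, 9.8, 100)
        v1, d1 = asym.train(t)
        v2, d2 = asym.train(t + 10.0)
        assert np.allclose(v1, v2)
        assert np.allclose(d1, d2)


class TestMetricsScaling:
    def test_auc_linear_in_amplitude(self):
        a1 = waveform_metrics(WaveformSpec(kind="asymmetric",
                                           amplitude_um=1.0))["auc"]
        a3 = waveform_metrics(WaveformSpec(kind="asymmetric",
                                           amplitude_um=3.0))["auc"]
        assert np.isclose(a3, 3 * a1, rtol=1e-9)

    def test_doubling_dilation_time_doubles_auc(self):
        base = waveform_metrics(WaveformSpec(kind="asymmetric", T_d=8.0))
        long = waveform_metrics(WaveformSpec(kind="asymmetric", T_d=16.0,
                                             period=20.0))
        assert np.isclose(long["auc"], 2 * base["auc"], rtol=1e-3)
        # time-scaling preserves the velocity-ratio invariant
        assert np.isclose(long["velocity_ratio"], base["velocity_ratio"],
                          rtol=1e-3)
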