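"""Parametric arteriolar wall-motion waveforms (the synthetic forcing).

Two pulse shapes drive the model, both C^1 in time with analytic
derivatives, both starting and ending at zero within an event window:

* ``symmetric`` — a windowed Gaussian: dilation and re-constriction are
  mirror images, so the wall velocity is odd about the peak time (the
  rectification null case);
* ``asymmetric`` — a gamma-variate pulse emulating functional hyperemia:
  rapid dilation (peak within 2 s) followed by a slow return over several
  seconds.  The default shape parameter alpha = 4 makes the peak
  re-constriction speed about half the peak dilation speed, and its area
  under the displacement curve about twice the symmetric pulse's at equal
  amplitude.

Amplitudes are radial wall displacements in micrometres: 2 um = 20% of the
20 um arteriolar diameter (awake), 4 um = 40% (slow-wave sleep).  Events
repeat once every 10 s by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["WaveformSpec", "symmetric_pulse", "asymmetric_pulse",
           "event_train", "waveform_metrics", "make_waveform"]


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x**3 * (10.0 + x * (-15.0 + 6.0 * x))


def _smoothstep_d(x):
    inside = (x > 0.0) & (x < 1.0)
    x = np.clip(x, 0.0, 1.0)
    return np.where(inside, 30.0 * x**2 * (x - 1.0)**2, 0.0)


@dataclass(frozen=True)
class WaveformSpec:
    """Arteriolar wall-displacement pulse + event-train parameters.

    ``T_d`` is the dilation time (start of dilation to return to baseline);
    sweeps rescale the pulse in time, so the area under the displacement
    curve grows linearly with ``T_d``.
    """

    kind: str = "asymmetric"
    amplitude_um: float = 2.0       # 2 um radial = 20% diameter dilation
    period: float = 10.0            # one event every 10 s
    T_d: float | None = None        # default: 8 s asymmetric, 4 s symmetric
    t_peak: float | None = None     # default: 1.5 s asym, T_d/2 sym
    sigma: float = 0.385            # Gaussian width of the symmetric pulse
    alpha: float = 4.0              # gamma-variate shape (asymmetric)
    check: bool = True

    def __post_init__(self):
        if self.kind not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if self.T_d is None:
            object.__setattr__(self, "T_d",
                               4.0 if self.kind == "symmetric" else 8.0)
        if self.t_peak is None:
            object.__setattr__(
                self, "t_peak",
                self.T_d / 2 if self.kind == "symmetric"
                else 1.5 * self.T_d / 8.0)
        if self.T_d > self.period:
            raise ValueError("event duration exceeds the period: "
                             "overlapping events")
        if self.check and self.kind == "asymmetric":
            m = waveform_metrics(replace(self, check=False))
            r = m["velocity_ratio"]
            if not 0.4 <= r <= 0.6:
                raise ValueError(
                    f"asymmetric pulse velocity ratio {r:.3f} outside "
                    "0.5 +/- 0.1; adjust alpha/t_peak")
            if m["t_peak"] > 2.0 * self.T_d / 8.0 + 1e-9:
                raise ValueError("time-to-peak exceeds 2 s (scaled)")

    # ------------------------------------------------------------------

    def pulse(self, t):
        """(an1 [um], dan1/dt [um/s]) of a single event starting at t=0."""
        if self.kind == "symmetric":
            return symmetric_pulse(t, self)
        return asymmetric_pulse(t, self)

    def train(self, t):
        """Periodic repetition of the pulse (an1, dan1/dt)."""
        t = np.asarray(t, dtype=float)
        tau = np.mod(t, self.period)
        return self.pulse(tau)

    def __call__(self, t):
        return self.train(t)


def symmetric_pulse(t, spec: WaveformSpec):
    """Windowed Gaussian A exp(-(t-t0)^2 / 2 sigma^2); C^2 window edges.

    The C^2 window (quintic smoothstep up/down over the first/last quarter
    of the event) pins the value and slope to zero at the event boundaries.
    """
    t = np.asarray(t, dtype=float)
    A, Td, t0 = spec.amplitude_um, spec.T_d, spec.t_peak
    scale = Td / 4.0
    s = spec.sigma * Td / 4.0           # sigma is quoted for T_d = 4 s
    G = np.exp(-(t - t0) ** 2 / (2 * s * s))
    dG = G * (-(t - t0) / (s * s))
    W = _smoothstep(t / scale) * _smoothstep((Td - t) / scale)
    dW = (_smoothstep_d(t / scale) / scale * _smoothstep((Td - t) / scale)
          - _smoothstep(t / scale) * _smoothstep_d((Td - t) / scale) / scale)
    inside = (t >= 0.0) & (t <= Td)
    val = np.where(inside, A * G * W, 0.0)
    dval = np.where(inside, A * (dG * W + G * dW), 0.0)
    return val, dval


def asymmetric_pulse(t, spec: WaveformSpec):
    """Gamma-variate A (t/tp)^a exp(a(1 - t/tp)), peak A at t = tp.

    A smooth shut-off window over the last eighth of the event guarantees an
    exact, C^1 return to baseline (the bare tail there is already below 1%
    of the peak for the default shape).
    """
    t = np.asarray(t, dtype=float)
    A, Td, tp, a = spec.amplitude_um, spec.T_d, spec.t_peak, spec.alpha
    x = np.clip(t / tp, 1e-12, None)
    f = x**a * np.exp(a * (1.0 - x))
    df = (a / tp) * x ** (a - 1.0) * (1.0 - x) * np.exp(a * (1.0 - x))
    tau = Td / 8.0
    W = _smoothstep((Td - t) / tau)
    dW = -_smoothstep_d((Td - t) / tau) / tau
    inside = (t >= 0.0) & (t <= Td)
    val = np.where(inside, A * f * W, 0.0)
    dval = np.where(inside, A * (df * W + f * dW), 0.0)
    return val, dval


def event_train(pulse, period: float, T_total: float):
    """Wrap a single-event pulse into a periodic train on [0, T_total].

    ``pulse(t)`` must return (value, derivative) and be zero (with zero
    slope) outside its event window.
    """

    def train(t):
        t = np.asarray(t, dtype=float)
        if np.any(t > T_total + 1e-9):
            pass  # evaluation past the nominal window is allowed (periodic)
        return pulse(np.mod(t, period))

    return train


def waveform_metrics(spec: WaveformSpec, n: int = 20001) -> dict:
    """Quadrature metrics of a single event: peak displacement, peak
    positive/negative velocity, their ratio, area under the displacement
    curve (AUC) and the dilation time."""
    t = np.linspace(0.0, spec.T_d, n)
    v, dv = spec.pulse(t)
    auc = float(np.trapezoid(v, t))
    vmax = float(dv.max())
    vmin = float(dv.min())
    return {
        "peak_displacement": float(v.max()),
        "t_peak": float(t[np.argmax(v)]),
        "peak_velocity_pos": vmax,
        "peak_velocity_neg": vmin,
        "velocity_ratio": abs(vmin) / vmax if vmax > 0 else np.nan,
        "auc": auc,
        "dilation_time": spec.T_d,
    }


def make_waveform(kind: str = "asymmetric", mode: str = "awake",
                  T_d: float | None = None, period: float = 10.0,
                  amplitude_um: float | None = None) -> WaveformSpec:
    """Convenience constructor: awake = 2 um (20%), sleep = 4 um (40%)."""
    if amplitude_um is None:
        amplitude_um = 2.0 if mode == "awake" else 4.0
    return WaveformSpec(kind=kind, amplitude_um=amplitude_um,
                        period=period, T_d=T_d)
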