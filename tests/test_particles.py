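"""Particle seeding, pullback kinematics and advection on synthetic fields."""

import numpy as np
import pytest

from pvsporo.geometry import GeometrySpec
from pvsporo.particles import (ParticleEnsemble, advect,
                               classify_and_aggregate, pullback_velocity,
                               seed_particles)
from pvsporo.units import UM


class FakeSeries:
    dt_sample = 0.05


class UniformSampler:
    """Constant reference-frame velocity field (analytic stand-in)."""

    def __init__(self, V):
        self.V = np.asarray(V, dtype=float)
        self.series = FakeSeries()

    def velocity(self, X, t, guess=None):
        return np.broadcast_to(self.V, X.shape).copy(), \
            np.zeros(len(X), dtype=np.int64)


class TestSeeding:
    def test_default_ensemble(self):
        ens = seed_particles()
        assert ens.n == 243                       # 27 rings x 9
        spec = GeometrySpec()
        assert np.all(spec.region_of(ens.X0) == "PVS")
        # ring z-spacing 150/27 um
        z = np.unique(np.round(ens.X0[:, 2] / UM, 9))
        assert len(z) == 27
        assert np.allclose(np.diff(z), 150.0 / 27)

    def test_seed_outside_domain_rejected(self):
        spec = GeometrySpec()
        with pytest.raises(ValueError):
            bad = GeometrySpec(w_pvs_deep=-20.0)  # inverted annulus
            seed_particles(bad)


class TestPullback:
    def test_comoving_and_identity(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert np.allclose(pullback_velocity(v, v, np.eye(3)[None]), 0.0)
        assert np.allclose(pullback_velocity(v, 0 * v, np.eye(3)[None]), v)

    def test_dilated_frame(self):
        # F = 1.01 I, v_f - v_s = 1.01 um/s -> Xdot = 1 um/s
        F = 1.01 * np.eye(3)[None]
        v = np.array([[1.01e-6, 0.0, 0.0]])
        out = pullback_velocity(v, 0 * v, F)
        assert np.allclose(out, [[1e-6, 0.0, 0.0]])


class TestAdvection:
    def test_zero_field_keeps_particles_still(self):
        ens = seed_particles()
        out = advect(ens, UniformSampler([0.0, 0.0, 0.0]), T_total=2.0)
        assert np.allclose(out.trajectory[-1], ens.X0)
        assert not out.exited.any()

    def test_constant_velocity_is_exact(self):
        # backward Euler integrates a constant field exactly
        ens = ParticleEnsemble(X0=np.array([[20e-6, 0.0, 75e-6]]))
        V = [1e-6, 0.0, 2e-6]
        out = advect(ens, UniformSampler(V), T_total=3.0,
                     reflect_axis=None)
        assert np.allclose(out.trajectory[-1],
                           ens.X0 + 3.0 * np.asarray(V), rtol=1e-12)

    def test_reflection_at_symmetry_plane(self):
        ens = ParticleEnsemble(X0=np.array([[1e-6, 50e-6, 75e-6]]))
        out = advect(ens, UniformSampler([-1e-6, 0.0, 0.0]), T_total=4.0,
                     reflect_axis=0)
        assert np.all(out.trajectory[..., 0] >= 0.0)


class TestClassification:
    def test_initially_all_pvs_and_fractions_conserve(self):
        ens = seed_particles()
        out = advect(ens, UniformSampler([0.5e-6, 0.0, 0.0]), T_total=10.0)
        agg = classify_and_aggregate(out)
        frac = agg["fractions"]
        assert np.isclose(frac.iloc[0][["PVS", "ECS", "SAS"]].sum(), 100.0)
        assert frac.iloc[0]["PVS"] == 100.0
        total = frac[["PVS", "ECS", "SAS"]].sum(axis=1)
        assert np.allclose(total, 100.0)
        # outward drift moved some particles into the parenchyma
        assert agg["summary"]["into_ecs_pct"] > 0.0
        assert agg["summary"]["n_particles"] == 243
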