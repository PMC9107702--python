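"""Boundary conditions of the vasodilation model.

* Arteriolar wall: prescribed radial solid displacement (the vasodilation
  waveform), solid velocity = its exact time derivative, no-slip for the
  fluid (zero filtration velocity).
* Skull-fixed dura (z = 200 um): everything zero.
* SAS ends (y = +/-100 um): small pressure difference applied as a traction
  on the fluid phase (drives the baseline CSF current); solid held in y.
* PVS bottom (z = 0): flow-resistance (Robin) traction, 10x the Darcy
  resistance of the deep PVS annulus; solid held in z.
* Symmetry / outer surfaces: zero normal components of displacement,
  velocity and filtration velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem.mesh import SimplexMesh
from .geometry import GeometrySpec, K_PVS, smoothstep
from .params import R0
from .units import MMHG, UM

__all__ = ["WallMotionBC", "RobinOutflowBC", "SASPressureBC",
           "DirichletTable", "wall_displacement", "robin_outflow_pressure"]


# ----------------------------------------------------------------------------
# wall motion

@dataclass
class WallMotionBC:
    """Radial wall-motion Dirichlet data built from a waveform.

    ``waveform(t)`` must return ``(an1, dan1_dt)`` in micrometres (and
    um/s); conversion to metres happens here.  For the penetrating segment
    (z <= 150 um) the displacement is (x/R0, y/R0, 0)*an1; above the brain
    surface it is radially outward with the same amplitude, smoothly tapered
    to zero below the skull-fixed dura.
    """

    waveform: object
    spec: GeometrySpec = field(default_factory=GeometrySpec)

    def _amp_factor(self, z_um: np.ndarray) -> np.ndarray:
        z0, z1 = self.spec.wall_taper
        return 1.0 - smoothstep((z_um - z0) / (z1 - z0))

    def _eval(self, X_m: np.ndarray, an1_um: float) -> np.ndarray:
        X = np.atleast_2d(X_m)
        z_um = X[:, 2] / UM
        an1 = an1_um * UM
        out = np.zeros_like(X)
        deep = z_um <= self.spec.z_surface + 1e-9
        out[deep, 0] = X[deep, 0] / R0 * an1
        out[deep, 1] = X[deep, 1] / R0 * an1
        up = ~deep
        if np.any(up):
            r = np.hypot(X[up, 0], X[up, 1])
            f = self._amp_factor(z_um[up]) * an1
            out[up, 0] = X[up, 0] / r * f
            out[up, 1] = X[up, 1] / r * f
        return out

    def displacement(self, X_m: np.ndarray, t: float) -> np.ndarray:
        an1, _ = self.waveform(t)
        return self._eval(X_m, float(an1))

    def velocity(self, X_m: np.ndarray, t: float) -> np.ndarray:
        _, dan1 = self.waveform(t)
        return self._eval(X_m, float(dan1))


def wall_displacement(t: float, X_ref: np.ndarray, waveform,
                      spec: GeometrySpec | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Prescribed wall (displacement, velocity) at reference points [m]."""
    bc = WallMotionBC(waveform, spec or GeometrySpec())
    return bc.displacement(X_ref, t), bc.velocity(X_ref, t)


# ----------------------------------------------------------------------------
# Robin outflow

@dataclass(frozen=True)
class RobinOutflowBC:
    """Flow resistance at the deep end of the PVS.

    p_Robin = multiplier * (L_a mu_f / k_s) * Q1 / (pi ((R2+W2)^2 - R2^2)),
    with Q1 the deformed-configuration flux through the PVS bottom face.
    Zero pressure is assumed beyond the resistor.
    """

    R2: float = 7.5e-6
    W2: float = 5.5e-6
    L_a: float = 150e-6
    multiplier: float = 10.0
    k_s: float = K_PVS
    mu_f: float = 1e-3

    @property
    def coefficient(self) -> float:
        """p_Robin / Q1 [Pa s / m^3]."""
        area = np.pi * ((self.R2 + self.W2) ** 2 - self.R2 ** 2)
        return self.multiplier * self.L_a * self.mu_f / (self.k_s * area)

    def pressure(self, Q1: float) -> float:
        return self.coefficient * Q1


def robin_outflow_pressure(Q1: float, bc: RobinOutflowBC | None = None
                           ) -> float:
    return (bc or RobinOutflowBC()).pressure(Q1)


# ----------------------------------------------------------------------------
# SAS pressure difference

@dataclass(frozen=True)
class SASPressureBC:
    """Pressure tractions at the SAS ends.

    ``P1`` acts on the inlet (default the y = +100 um face; the orientation
    is a configuration switch because the layout description is ambiguous),
    ``P0`` on the outlet; both applied to the fluid phase only and ramped
    from zero over ``t_ramp`` at the start of the baseline solve.  The flow
    direction is reported from the solution, not assumed.
    """

    P1_mmHg: float = 0.01
    P0_mmHg: float = 0.0
    t_ramp: float = 0.1
    inlet: str = "sas_inlet"    # y = +100 face
    outlet: str = "sas_outlet"  # y = -100 face

    def values(self, t: float) -> dict[str, float]:
        ramp = min(t / self.t_ramp, 1.0) if self.t_ramp > 0 else 1.0
        return {self.inlet: self.P1_mmHg * MMHG * ramp,
                self.outlet: self.P0_mmHg * MMHG * ramp}


# ----------------------------------------------------------------------------
# Dirichlet bookkeeping

class DirichletTable:
    """Collects component-wise and vector Dirichlet constraints on the
    (u, w) fields and produces (fixed_dofs, values(t)).

    Constraints are applied in registration order; later registrations
    overwrite earlier values at shared nodes (used to let the all-zero dura
    constraint win over the tapered wall motion, which agrees there anyway).
    """

    def __init__(self, mesh: SimplexMesh, ndof_u: int):
        self.mesh = mesh
        self.d = mesh.dim
        self.offs_w = ndof_u
        self._static: dict[int, float] = {}
        self._moving: list[tuple[np.ndarray, np.ndarray, object, str]] = []

    def _tag_nodes(self, tag: str) -> np.ndarray:
        fs = self.mesh.tags[tag]
        nodes = [self.mesh.facet_nodes2(int(c), int(lf))
                 for c, lf in zip(fs.cells, fs.lfaces)]
        return np.unique(np.concatenate(nodes)) if nodes else \
            np.array([], dtype=np.int64)

    def fix_component(self, field_: str, tag: str, comp: int,
                      value: float = 0.0):
        nodes = self._tag_nodes(tag)
        off = 0 if field_ == "u" else self.offs_w
        for n in nodes:
            self._static[off + int(n) * self.d + comp] = value

    def fix_vector(self, field_: str, tag: str, value_fn=None):
        """value_fn(X, t) -> (n, d) array; None means zero."""
        nodes = self._tag_nodes(tag)
        off = 0 if field_ == "u" else self.offs_w
        if value_fn is None:
            for n in nodes:
                for i in range(self.d):
                    self._static[off + int(n) * self.d + i] = 0.0
        else:
            X = self.mesh.X2[nodes]
            dofs = (nodes[:, None] * self.d + np.arange(self.d)).ravel() + off
            self._moving.append((nodes, dofs, value_fn, field_))

    def finalize(self):
        moving_dofs = np.concatenate([m[1] for m in self._moving]) \
            if self._moving else np.array([], dtype=np.int64)
        static_dofs = np.array(sorted(self._static), dtype=np.int64)
        all_dofs = np.unique(np.concatenate([moving_dofs, static_dofs]))
        self.fixed_dofs = all_dofs
        pos = {int(d_): i for i, d_ in enumerate(all_dofs)}
        self._moving_idx = [
            np.array([pos[int(d_)] for d_ in dofs], dtype=np.int64)
            for _, dofs, _, _ in self._moving]
        self._static_idx = np.array(
            [pos[int(d_)] for d_ in static_dofs], dtype=np.int64)
        self._static_vals = np.array([self._static[d_] for d_ in static_dofs])
        return self.fixed_dofs

    def values(self, t: float) -> np.ndarray:
        vals = np.zeros(len(self.fixed_dofs))
        for (nodes, dofs, fn, _), idx in zip(self._moving, self._moving_idx):
            vals[idx] = fn(self.mesh.X2[nodes], t).ravel()
        if len(self._static_idx):
            vals[self._static_idx] = self._static_vals
        return vals
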