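"""Pointwise kinematics and constitutive relations of the biphasic mixture.

Everything here is plain batched tensor algebra on numpy arrays: vector
fields have shape ``(..., d)`` and tensor fields ``(..., d, d)`` with ``d``
the spatial dimension.  Index convention for displacement gradients:
``grad_u[..., i, J] = d u_i / d X_J`` (row = spatial component, column =
reference derivative direction), used consistently throughout the package.

The mixture is written in ALE form on the reference (undeformed-skeleton)
configuration.  Primary fields per domain: solid displacement ``u_s``, solid
velocity ``v_s``, fluid velocity ``v_f``, filtration velocity ``v_flt`` and
pore pressure ``p``.  The filtration velocity is the Darcy-flux analogue:
fluid velocity relative to the skeleton scaled by the current fluid volume
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MixtureParams

__all__ = [
    "NonPhysicalStateError",
    "KinematicState",
    "StressBundle",
    "kinematics",
    "filtration_velocity",
    "solid_stress",
    "fluid_viscous_stress",
    "mixture_traction_operator",
    "incompressibility_residual",
    "momentum_residuals",
    "strain_energy_density",
]


class NonPhysicalStateError(ValueError):
    """Raised when J <= 0 (inverted element) or J <= zeta_Rs (fluid phase
    vanishes locally)."""


def _det(F: np.ndarray) -> np.ndarray:
    return np.linalg.det(F)


def _inv(F: np.ndarray) -> np.ndarray:
    return np.linalg.inv(F)


def _transpose(A: np.ndarray) -> np.ndarray:
    return np.swapaxes(A, -1, -2)


@dataclass
class KinematicState:
    """Deformation measures and volume fractions at a set of points."""

    u_s: np.ndarray        # (..., d)
    F_s: np.ndarray        # (..., d, d)
    J_s: np.ndarray        # (...)
    zeta_s: np.ndarray     # (...)
    zeta_f: np.ndarray     # (...)


@dataclass
class StressBundle:
    """Referential (first-Piola-type) and spatial stresses of the mixture."""

    P_s: np.ndarray          # solid Piola stress (..., d, d)
    P_f: np.ndarray          # fluid viscous Piola stress (..., d, d)
    P_mix: np.ndarray        # mixture traction operator (..., d, d)
    sigma_total: np.ndarray  # total Cauchy stress (..., d, d)


def kinematics(grad_u: np.ndarray, zeta_Rs: float,
               u_s: np.ndarray | None = None,
               check: bool = True) -> KinematicState:
    """Deformation gradient, Jacobian and volume fractions from grad(u_s).

    F = grad(u) + I, J = det F, zeta_s = zeta_Rs / J, zeta_f = 1 - zeta_s.
    Raises :class:`NonPhysicalStateError` if J <= 0 or J <= zeta_Rs anywhere
    (the latter would extinguish the fluid phase).
    """
    grad_u = np.asarray(grad_u, dtype=float)
    d = grad_u.shape[-1]
    F = grad_u + np.eye(d)
    J = _det(F)
    if check:
        if np.any(J <= 0.0):
            raise NonPhysicalStateError("J <= 0: element inversion")
        if np.any(J <= zeta_Rs):
            raise NonPhysicalStateError(
                "J <= zeta_Rs: fluid volume fraction vanished")
    zeta_s = zeta_Rs / J
    if u_s is None:
        u_s = np.zeros(grad_u.shape[:-1])
    return KinematicState(u_s=u_s, F_s=F, J_s=J,
                          zeta_s=zeta_s, zeta_f=1.0 - zeta_s)


def filtration_velocity(v_f: np.ndarray, v_s: np.ndarray,
                        J_s: np.ndarray, zeta_Rs: float) -> np.ndarray:
    """v_flt = (1 - zeta_Rs / J)(v_f - v_s): Darcy-flux analogue."""
    J_s = np.asarray(J_s, dtype=float)
    if np.any(J_s <= zeta_Rs):
        raise NonPhysicalStateError("J <= zeta_Rs in filtration_velocity")
    zf = 1.0 - zeta_Rs / J_s
    return zf[..., None] * (np.asarray(v_f) - np.asarray(v_s))


def strain_energy_density(F: np.ndarray, mu_s: float) -> np.ndarray:
    """Neo-Hookean skeleton energy Psi = mu/2 (tr C - 2 ln J), C = F^T F.

    The compressible-looking form is a valid skeleton model (the porous
    skeleton compacts by draining fluid even though the solid constituent is
    incompressible) and conveniently gives zero stress at F = I.
    """
    F = np.asarray(F, dtype=float)
    C = _transpose(F) @ F
    trC = np.trace(C, axis1=-2, axis2=-1)
    J = _det(F)
    return 0.5 * mu_s * (trC - 2.0 * np.log(J))


def solid_stress(F: np.ndarray, mu_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Skeleton stress in referential and spatial form.

    Returns ``(P_s, sigma_s)`` with P_s = mu_s (F - F^{-T}) (the first-Piola
    stress of the neo-Hookean energy above, exactly zero at F = I) and
    sigma_s = J^{-1} P_s F^T its Cauchy counterpart.
    """
    F = np.asarray(F, dtype=float)
    J = _det(F)
    if np.any(J <= 0.0):
        raise NonPhysicalStateError("singular/inverted F in solid_stress")
    FinvT = _transpose(_inv(F))
    P_s = mu_s * (F - FinvT)
    sigma_s = (P_s @ _transpose(F)) / J[..., None, None]
    return P_s, sigma_s


def fluid_viscous_stress(grad_v_flt: np.ndarray, F: np.ndarray,
                         J: np.ndarray, zeta_Rs: float,
                         mu_f: float) -> np.ndarray:
    """Brinkman viscous Piola stress.

    P_f = mu_f (J - zeta_Rs) [grad(v_flt) F^{-1} + (grad(v_flt) F^{-1})^T].
    """
    J = np.asarray(J, dtype=float)
    if np.any(J <= zeta_Rs):
        raise NonPhysicalStateError("J <= zeta_Rs in fluid_viscous_stress")
    L = np.asarray(grad_v_flt) @ _inv(np.asarray(F, dtype=float))
    return mu_f * (J - zeta_Rs)[..., None, None] * (L + _transpose(L))


def mixture_traction_operator(p: np.ndarray, F: np.ndarray, J: np.ndarray,
                              P_s: np.ndarray, P_f: np.ndarray) -> np.ndarray:
    """P_mix = -J p F^{-T} + P_s + P_f.

    Contracted with a reference normal it yields the total mixture traction;
    it carries the phase-split jump conditions across the PVS-parenchyma
    interface.
    """
    FinvT = _transpose(_inv(np.asarray(F, dtype=float)))
    J = np.asarray(J, dtype=float)
    p = np.asarray(p, dtype=float)
    return -(J * p)[..., None, None] * FinvT + P_s + P_f


def total_cauchy_stress(p: np.ndarray, F: np.ndarray,
                        grad_v_flt: np.ndarray, params: MixtureParams
                        ) -> StressBundle:
    """Full stress bundle (referential and spatial) at a batch of points."""
    F = np.asarray(F, dtype=float)
    J = _det(F)
    P_s, sigma_s = solid_stress(F, params.mu_s)
    P_f = fluid_viscous_stress(grad_v_flt, F, J, params.zeta_Rs, params.mu_f)
    P_mix = mixture_traction_operator(p, F, J, P_s, P_f)
    d = F.shape[-1]
    sigma_f = (P_f @ _transpose(F)) / J[..., None, None]
    sigma = -np.asarray(p, dtype=float)[..., None, None] * np.eye(d) \
        + sigma_s + sigma_f
    return StressBundle(P_s=P_s, P_f=P_f, P_mix=P_mix, sigma_total=sigma)


def incompressibility_residual(grad_v_s: np.ndarray, grad_v_flt: np.ndarray,
                               F: np.ndarray) -> np.ndarray:
    """r = F^{-T} : grad(v_s + v_flt)  (zero divergence of the volume-
    averaged velocity, pulled back to the reference configuration)."""
    FinvT = _transpose(_inv(np.asarray(F, dtype=float)))
    G = np.asarray(grad_v_s) + np.asarray(grad_v_flt)
    return np.einsum("...ij,...ij->...", FinvT, G)


def momentum_residuals(*, grad_u: np.ndarray, grad_p: np.ndarray,
                       v_flt: np.ndarray, grad_v_f: np.ndarray,
                       dv_s_dt: np.ndarray, dv_f_dt: np.ndarray,
                       div_P_s: np.ndarray, div_P_f: np.ndarray,
                       params: MixtureParams) -> dict[str, np.ndarray]:
    """Strong-form momentum residuals of the solid and fluid phases.

    All model terms are retained (inertia, convection, drag, pressure split
    by reference volume fractions, stress divergences).  The drag exchange
    term ``(J - zeta_Rs)(mu_f/k_s) v_flt`` enters the two equations with
    opposite sign — momentum lost by one phase is gained by the other.

    Time derivatives and stress divergences must be supplied by the caller
    (they are field-level, not pointwise, quantities); a ``ValueError`` is
    raised if missing.  Used for method-of-manufactured-solutions style
    verification; the transient solver works with weak forms.
    """
    for name, arr in (("dv_s_dt", dv_s_dt), ("dv_f_dt", dv_f_dt)):
        if arr is None:
            raise ValueError(f"momentum_residuals requires {name}")
    kin = kinematics(grad_u, params.zeta_Rs)
    F, J = kin.F_s, kin.J_s
    FinvT = _transpose(_inv(F))
    Finv = _inv(F)
    zRs = params.zeta_Rs
    Jmz = (J - zRs)
    drag = Jmz[..., None] * (params.mu_f / params.k_s) * np.asarray(v_flt)

    press_s = zRs * np.einsum("...iJ,...J->...i", FinvT, grad_p)
    r_solid = (zRs * params.rho_s_star * np.asarray(dv_s_dt)
               + press_s - drag - np.asarray(div_P_s))

    conv = np.einsum("...IJ,...iI,...J->...i", Finv,
                     np.asarray(grad_v_f), np.asarray(v_flt))
    press_f = np.einsum("...iJ,...J->...i", FinvT, grad_p)
    r_fluid = (Jmz[..., None] * (params.rho_f_star * np.asarray(dv_f_dt)
                                 + press_f
                                 + (params.mu_f / params.k_s) * np.asarray(v_flt))
               + J[..., None] * params.rho_f_star * conv
               - np.asarray(div_P_f))
    return {"solid": r_solid, "fluid": r_fluid,
            "drag_solid": -drag, "drag_fluid": drag}
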