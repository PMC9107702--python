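"""Closed-form and reduced-model oracles that make the solver testable.

* The 2D *lag experiment*: the mechanism behind rectification in one
  picture.  A square poroelastic block forced at one edge either by a
  prescribed displacement pulse (with no-slip) or by a pressure-like
  traction on both phases.  Displacement forcing produces an outflow that
  tracks the wall velocity; pressure forcing produces an outflow that lags
  the pressure waveform (the consolidation-type delay long known from
  soils).  The lag asymmetry is what turns temporally asymmetric
  vasodilation into net convection.

* Terzaghi consolidation: the classical 1D series solution for a step-
  loaded, one-sided-drained column, used as an external analytic check of
  the coupled solver in the linear regime.

* Darcy-Brinkman channel flow: closed-form velocity profile for a rigid
  porous channel, validating the Brinkman operator between its Darcy and
  Stokes limits.

* Method of manufactured solutions (steady): smooth fields injected
  through volume sources; checks the convergence order of the P2/P2/P1
  discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .bc import DirichletTable
from .fem.assembly import FieldState, PoroelasticForm
from .geometry import build_2d_block
from .params import MixtureParams
from .solver import SolverConfig, TransientSolver
from .units import UM

__all__ = ["LagExperimentSpec", "run_lag_experiment", "terzaghi_reference",
           "run_terzaghi", "brinkman_channel_reference",
           "run_brinkman_channel", "run_mms_convergence"]


# ----------------------------------------------------------------------------
# lag experiment

@dataclass(frozen=True)
class LagExperimentSpec:
    """2D block forcing protocol.

    Boundary conditions (as in the reference experiment): top/bottom hold
    the vertical solid displacement and are no-slip; the right edge holds
    the horizontal solid displacement and leaves the fluid traction-free;
    the left edge carries the forcing.
    """

    length_um: float = 150.0
    n: int = 12
    mu_s: float = 2000.0
    k_s: float = 2e-14
    zeta_Rf: float = 0.8
    amplitude_um: float = 0.2      # displacement-mode pulse amplitude
    pressure_pa: float = 5.0       # pressure-mode pulse amplitude
    t_center: float = 1.2
    t_sigma: float = 0.3
    T: float = 6.0
    dt: float = 0.03


def _gauss(t, t0, s):
    g = np.exp(-(t - t0) ** 2 / (2 * s * s))
    return g, g * (-(t - t0) / (s * s))


def run_lag_experiment(mode: str, spec: LagExperimentSpec | None = None
                       ) -> dict:
    """Run one forcing mode in {'displacement', 'pressure'}.

    Returns the time series of the right-edge fluid flowrate, the forcing
    waveform, and the lag (argmax of the cross-correlation between the
    forcing-rate waveform and the flowrate).
    """
    spec = spec or LagExperimentSpec()
    if mode not in ("displacement", "pressure"):
        raise ValueError(mode)
    mesh = build_2d_block(spec.n, spec.length_um)
    mat = MixtureParams(1000.0, 1000.0, 1e-3, spec.mu_s, spec.k_s,
                        spec.zeta_Rf)
    form = PoroelasticForm(mesh, {1: mat})
    tab = DirichletTable(mesh, form.nu)
    tab.fix_component("u", "top", 1)
    tab.fix_vector("w", "top", None)
    tab.fix_component("u", "bottom", 1)
    tab.fix_vector("w", "bottom", None)
    tab.fix_component("u", "right", 0)

    A_m = spec.amplitude_um * UM
    if mode == "displacement":
        def uleft(X, t):
            g, _ = _gauss(t, spec.t_center, spec.t_sigma)
            out = np.zeros_like(X)
            out[:, 0] = A_m * g
            return out

        tab.fix_vector("u", "left", uleft)
        tab.fix_vector("w", "left", None)     # no-slip moving wall
        pressure_fn = (lambda t: {"right": 0.0})
        solid_fn = None
    else:
        def pressure_fn(t):
            g, _ = _gauss(t, spec.t_center, spec.t_sigma)
            return {"left": spec.pressure_pa * g, "right": 0.0}

        def solid_fn(t):
            g, _ = _gauss(t, spec.t_center, spec.t_sigma)
            return {"left": spec.pressure_pa * g / mat.zeta_Rs}

    tab.finalize()
    cfg = SolverConfig(dt=spec.dt, picard_tol=1e-7, picard_max=4)
    solver = TransientSolver(form, tab, cfg, pressure_bc_fn=pressure_fn,
                             solid_pressure_bc_fn=solid_fn)
    zero = FieldState(np.zeros((mesh.n2, 2)), np.zeros((mesh.n2, 2)),
                      np.zeros(mesh.n_pdofs), 0.0)
    out = solver.march(zero, 0.0, spec.T, flux_tags=("right",))
    t = out.times
    Q = out.flowrates["right"]
    g, dg = _gauss(t, spec.t_center, spec.t_sigma)
    if mode == "displacement":
        forcing = A_m * g                       # wall displacement
        forcing_rate = A_m * dg                 # wall velocity
    else:
        forcing = spec.pressure_pa * g          # pressure waveform
        forcing_rate = spec.pressure_pa * dg
    # the lag is measured between the forcing-rate waveform and the
    # flowrate: displacement forcing drives flow through incompressibility
    # (rate-coupled, no delay); pressure forcing charges poroelastic
    # storage, whose discharge at the far end is consolidation-delayed
    lag = cross_correlation_lag(forcing_rate, Q, spec.dt)
    return {"t": t, "flowrate": Q, "forcing": forcing,
            "forcing_rate": forcing_rate, "lag": lag,
            "mode": mode, "series": out}


def cross_correlation_lag(f: np.ndarray, g: np.ndarray, dt: float) -> float:
    """Lag of g behind f: argmax over tau >= 0 of sum f(t) g(t + tau)."""
    f = f - f.mean()
    g = g - g.mean()
    n = len(f)
    corr = np.correlate(g, f, mode="full")      # index n-1 <-> tau = 0
    tau = (np.arange(len(corr)) - (n - 1)) * dt
    pos = tau >= 0.0
    return float(tau[pos][np.argmax(corr[pos])])


# ----------------------------------------------------------------------------
# Terzaghi consolidation

def terzaghi_reference(x: np.ndarray, t: float, sigma0: float, L: float,
                       c_v: float, tol: float = 1e-12,
                       max_terms: int = 2000) -> np.ndarray:
    """Pore pressure of the step-loaded column, drained at x = 0.

    p(x, t) = sigma0 * sum_m 4/((2m+1) pi) sin((2m+1) pi x / 2L)
              exp(-((2m+1) pi / 2)^2 c_v t / L^2).
    Series truncated when the term bound falls below ``tol`` (always
    possible for t > 0; at very small dimensionless times many terms are
    needed, so ``max_terms`` caps the work).
    """
    x = np.asarray(x, dtype=float)
    p = np.zeros_like(x)
    for m in range(max_terms):
        M = (2 * m + 1) * np.pi / 2.0
        amp = 4.0 / ((2 * m + 1) * np.pi) * np.exp(-M * M * c_v * t / L**2)
        if amp < tol and m > 2:
            break
        p += amp * np.sin(M * x / L)
    return sigma0 * p


def run_terzaghi(n: int = 10, sigma0: float = 10.0, mu_s: float = 2000.0,
                 k_s: float = 2e-14, L_um: float = 150.0,
                 Tv_list=(0.1, 0.5, 1.0), dt: float = 0.005) -> dict:
    """Solve the consolidation problem and compare with the series.

    The consolidation coefficient of this mixture is c_v = 2 mu_s k_s /
    mu_f (confined modulus 2 mu_s for the neo-Hookean skeleton linearized
    about the reference state).  Load amplitude keeps strains ~0.25% so the
    linear series applies.
    """
    mesh = build_2d_block(n, L_um)
    mat = MixtureParams(1000.0, 1000.0, 1e-3, mu_s, k_s, 0.2)
    form = PoroelasticForm(mesh, {1: mat})
    tab = DirichletTable(mesh, form.nu)
    tab.fix_component("u", "left", 1)
    tab.fix_component("w", "left", 1)
    tab.fix_component("u", "right", 0)
    tab.fix_component("w", "right", 0)
    for tag in ("top", "bottom"):
        tab.fix_component("u", tag, 1)
        tab.fix_component("w", tag, 1)
    tab.finalize()
    cfg = SolverConfig(dt=dt, picard_tol=1e-8, picard_max=4)
    solver = TransientSolver(form, tab, cfg,
                             pressure_bc_fn=lambda t: {"left": 0.0},
                             solid_pressure_bc_fn=lambda t: {
                                 "left": sigma0 / mat.zeta_Rs})
    zero = FieldState(np.zeros((mesh.n2, 2)), np.zeros((mesh.n2, 2)),
                      np.zeros(mesh.n_pdofs), 0.0)
    c_v = 2.0 * mu_s * k_s / mat.mu_f
    L = L_um * UM
    T = max(Tv_list) * L**2 / c_v
    out = solver.march(zero, 0.0, T)
    Xp = mesh.pressure_coords()
    errors = {}
    for Tv in Tv_list:
        t = Tv * L**2 / c_v
        i = int(round(t / dt))
        p_num = out.p[i]
        p_ex = terzaghi_reference(Xp[:, 0], out.times[i], sigma0, L, c_v)
        errors[Tv] = float(np.linalg.norm(p_num - p_ex)
                           / np.linalg.norm(p_ex))
    return {"errors": errors, "c_v": c_v, "series": out,
            "max_error": max(errors.values())}


# ----------------------------------------------------------------------------
# Darcy-Brinkman channel

def brinkman_channel_reference(y: np.ndarray, k_s: float, G: float,
                               mu_f: float, h: float) -> np.ndarray:
    """u(y) = (k G / mu)(1 - cosh(y/sqrt(k)) / cosh(h/sqrt(k))).

    G is the (positive) axial pressure-gradient magnitude; y in [-h, h].
    Limits: Poiseuille as k -> inf, plug (Darcy) flow k G / mu as
    sqrt(k) << h.
    """
    y = np.asarray(y, dtype=float)
    s = np.sqrt(k_s)
    return k_s * G / mu_f * (1.0 - np.cosh(y / s) / np.cosh(h / s))


def run_brinkman_channel(k_s: float = 2e-12, n: int = 10, ny: int = 24,
                         L_um: float = 50.0, h_um: float = 25.0,
                         dp: float = 0.5) -> dict:
    """Pressure-driven flow through a rigid porous channel vs closed form.

    Rigidity is approximated with a stiff skeleton (mu_s = 1e7 Pa) and
    fully clamped solid; three long implicit steps reach the steady state
    (the fluid problem is quasi-static).
    """
    mesh = build_2d_block(n, L_um, ny=ny, height_um=2 * h_um,
                          y0_um=-h_um)
    mat = MixtureParams(1000.0, 1000.0, 1e-3, 1e7, k_s, 0.8)
    form = PoroelasticForm(mesh, {1: mat})
    tab = DirichletTable(mesh, form.nu)
    for tag in ("left", "right", "top", "bottom"):
        tab.fix_vector("u", tag, None)
    tab.fix_vector("w", "top", None)
    tab.fix_vector("w", "bottom", None)
    tab.finalize()
    cfg = SolverConfig(dt=0.1, picard_tol=1e-8, picard_max=3,
                       with_inertia=False)
    solver = TransientSolver(form, tab, cfg,
                             pressure_bc_fn=lambda t: {"left": dp,
                                                       "right": 0.0})
    zero = FieldState(np.zeros((mesh.n2, 2)), np.zeros((mesh.n2, 2)),
                      np.zeros(mesh.n_pdofs), 0.0)
    out = solver.march(zero, 0.0, 0.3)
    L, h = L_um * UM, h_um * UM
    G = dp / L
    # profile at mid-channel
    X = mesh.X2
    mid = np.abs(X[:, 0] - L / 2) < L / (2 * n) * 0.6
    y = X[mid, 1]
    wx = out.w[-1][mid, 0]
    ref = brinkman_channel_reference(y, k_s, G, mat.mu_f, h)
    err = np.max(np.abs(wx - ref)) / np.max(np.abs(ref))
    return {"y": y, "w_x": wx, "reference": ref, "max_rel_error": float(err),
            "series": out}


# ----------------------------------------------------------------------------
# manufactured solutions

def _mms_fields(L: float, mat: MixtureParams):
    """Sympy manufactured fields and the matching volume sources."""
    import sympy as sym

    x, y = sym.symbols("x y")
    s = sym.pi / L
    u0, w0, p0 = 2e-7, 1e-6, 1.0
    u = sym.Matrix([u0 * sym.sin(s * x) * sym.sin(s * y),
                    u0 * sym.cos(s * x) * sym.cos(s * y)])
    w = sym.Matrix([w0 * sym.sin(s * x) * sym.cos(s * y),
                    w0 * sym.cos(s * x) * sym.sin(s * y)])
    p = p0 * sym.cos(s * x) * sym.sin(s * y)

    X = sym.Matrix([x, y])
    gradu = u.jacobian(X)
    F = gradu + sym.eye(2)
    J = F.det()
    Finv = F.inv()
    FinvT = Finv.T
    gradp = sym.Matrix([sym.diff(p, x), sym.diff(p, y)])
    zRs = mat.zeta_Rs
    mu_f, mu_s, k = mat.mu_f, mat.mu_s, mat.k_s

    P_s = mu_s * (F - FinvT)
    gradw = w.jacobian(X)
    P_f = mu_f * (J - zRs) * (gradw * Finv + (gradw * Finv).T)

    def div_piola(P):
        return sym.Matrix([sym.diff(P[0, 0], x) + sym.diff(P[0, 1], y),
                           sym.diff(P[1, 0], x) + sym.diff(P[1, 1], y)])

    f_s = zRs * FinvT * gradp - (J - zRs) * (mu_f / k) * w - div_piola(P_s)
    f_f = (J - zRs) * (FinvT * gradp + (mu_f / k) * w) - div_piola(P_f)
    g_m = sum((FinvT[i, j] * sym.diff(w[i], X[j]))
              for i in range(2) for j in range(2))

    lam = sym.lambdify((x, y), [u[0], u[1], w[0], w[1], p,
                                f_s[0], f_s[1], f_f[0], f_f[1], g_m],
                       "numpy")
    return lam


def run_mms_convergence(ns=(4, 8, 16), L_um: float = 100.0,
                        mu_s: float = 2000.0, k_s: float = 2e-14) -> dict:
    """Steady manufactured-solution convergence study.

    Returns L2 errors of (u, w, p) per mesh and the observed orders
    between the two finest meshes.  Expected: ~3 for the P2 fields (>= 2
    required), ~2 for P1 pressure (>= 1 required).
    """
    L = L_um * UM
    mat = MixtureParams(1000.0, 1000.0, 1e-3, mu_s, k_s, 0.8)
    lam = _mms_fields(L, mat)

    def fields(X):
        return lam(X[:, 0], X[:, 1])

    errs = {"u": [], "w": [], "p": [], "h": []}
    for n in ns:
        mesh = build_2d_block(n, L_um)
        form = PoroelasticForm(mesh, {1: mat})
        vals2 = fields(mesh.X2)
        u_ex = np.column_stack(vals2[0:2])
        w_ex = np.column_stack(vals2[2:4])
        Xp = mesh.pressure_coords()
        p_ex = np.asarray(lam(Xp[:, 0], Xp[:, 1])[4])

        tab = DirichletTable(mesh, form.nu)
        for tag in ("left", "right", "top", "bottom"):
            tab.fix_vector("u", tag, lambda X, t: np.column_stack(
                fields(X)[0:2]))
            tab.fix_vector("w", tag, lambda X, t: np.column_stack(
                fields(X)[2:4]))
        tab.finalize()
        fixed = np.concatenate([tab.fixed_dofs,
                                [form.offs_p + 0]])
        fixed = np.unique(fixed)
        free = np.setdiff1d(np.arange(form.ndof), fixed)
        gvals = np.zeros(len(fixed))
        pos = np.searchsorted(fixed, tab.fixed_dofs)
        gvals[pos] = tab.values(0.0)
        gvals[np.searchsorted(fixed, form.offs_p + 0)] = p_ex[0]

        def srcs(X):
            v = fields(X)
            return v

        f_s = lambda X: np.column_stack(srcs(X)[5:7])
        f_f = lambda X: np.column_stack(srcs(X)[7:9])
        g_m = lambda X: np.asarray(srcs(X)[9])

        state = FieldState(np.zeros((mesh.n2, 2)), np.zeros((mesh.n2, 2)),
                           np.zeros(mesh.n_pdofs), 0.0)
        for _ in range(4):
            A, b = form.assemble(state, av=0.0,
                                 v_hist=np.zeros(form.nu),
                                 with_inertia=False,
                                 sources=(f_s, f_f, g_m))
            rhs = b[free] - A[free][:, fixed] @ gvals
            sol = spla.splu(A[free][:, free].tocsc()).solve(rhs)
            U = np.empty(form.ndof)
            U[free] = sol
            U[fixed] = gvals
            n2 = mesh.n2
            state = FieldState(U[:2 * n2].reshape(n2, 2),
                               U[2 * n2:4 * n2].reshape(n2, 2),
                               U[4 * n2:], 0.0)

        # L2 errors by quadrature
        def l2_p2(fh, fx):
            diff2 = np.sum((fh - fx) ** 2, axis=-1) if fh.ndim == 2 else \
                (fh - fx) ** 2
            nod = diff2[mesh.cells2]
            q = np.einsum("cq,qk,ck->", form.meas_w, form.phi2, nod)
            return np.sqrt(max(q, 0.0))

        def l2_p1(fh, fx):
            nod = ((fh - fx) ** 2)[mesh.pcells]
            q = np.einsum("cq,qk,ck->", form.meas_w, form.phi1, nod)
            return np.sqrt(max(q, 0.0))

        errs["u"].append(l2_p2(state.u, u_ex))
        errs["w"].append(l2_p2(state.w, w_ex))
        errs["p"].append(l2_p1(state.p, p_ex))
        errs["h"].append(L / n)

    def order(e):
        return float(np.log(e[-2] / e[-1])
                     / np.log(errs["h"][-2] / errs["h"][-1]))

    return {"errors": errs,
            "order_u": order(errs["u"]), "order_w": order(errs["w"]),
            "order_p": order(errs["p"])}
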