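"""Weak-form assembly for the two-domain incompressible poroelastic mixture.

Discrete unknowns per time level (Taylor-Hood-style pairing):

* ``u``  — solid displacement, vector P2 (continuous across the interface);
* ``w``  — filtration velocity, vector P2 (continuous across the interface);
* ``p``  — pore pressure, scalar P1, duplicated per domain so it may jump
  across the interface.

The solid velocity is the BDF time derivative of ``u`` (``v_s = av*u +
v_hist``) and the fluid velocity is recovered pointwise from the filtration
velocity, so the five-field mixture model reduces to three discrete fields.

Weak equations (reference configuration; overbars denote geometry factors
F, J, F^{-T} frozen at the current Picard iterate):

* solid momentum: inertia + zeta_Rs F^{-T} grad p - drag, plus the
  neo-Hookean stress term b(w_test, P_s); no boundary tractions of its own
  except optional phase tractions used by the verification oracles;
* fluid momentum: (J - zeta_Rs)[F^{-T} grad p + (mu_f/k_s) w] with the
  Brinkman term b(w_test, P_f) and pressure-traction boundary integrals on
  the open (Neumann/Robin) surfaces;
* incompressibility: b(v_s + w, p_test F^{-T}) = 0.

Interface handling follows the phase-split jump conditions: domain-1
momentum rows are dropped on interface nodes and the domain-2 rows receive
the interface integrals built from the domain-1 mixture traction operator
P_mix^1, with a single common normal (outward from the parenchyma).

The pressure gradient is kept in strong (non-integrated) form, which makes
the natural boundary condition of the fluid equation exactly the reference
fluid-phase traction condition.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..kinematics import NonPhysicalStateError
from ..params import MixtureParams
from .mesh import FacetSet, SimplexMesh
from .reference import eval_basis, n_basis, quadrature

__all__ = ["PoroelasticForm", "FieldState"]


class _Pattern:
    """Cached COO->CSR mapping: sort/deduplicate indices once, then rebuild
    only the value array on subsequent assemblies."""

    def __init__(self, rows, cols, shape):
        order = np.lexsort((cols, rows))
        r, c = rows[order], cols[order]
        new = np.ones(len(r), dtype=bool)
        new[1:] = (r[1:] != r[:-1]) | (c[1:] != c[:-1])
        self.order = order
        self.starts = np.nonzero(new)[0]
        ur, uc = r[new], c[new]
        counts = np.bincount(ur, minlength=shape[0])
        self.indptr = np.concatenate([[0], np.cumsum(counts)])
        self.indices = uc
        self.shape = shape
        self.nnz = len(uc)

    def csr(self, vals):
        data = np.add.reduceat(vals[self.order], self.starts)
        return sp.csr_matrix((data, self.indices, self.indptr),
                             shape=self.shape)


class FieldState:
    """Nodal fields at one time level."""

    __slots__ = ("u", "w", "p", "t")

    def __init__(self, u, w, p, t=0.0):
        self.u, self.w, self.p, self.t = u, w, p, t

    def copy(self):
        return FieldState(self.u.copy(), self.w.copy(), self.p.copy(), self.t)


class PoroelasticForm:
    """Assembler bound to a mesh and per-domain materials.

    Parameters
    ----------
    mesh : SimplexMesh
    materials : {domain: MixtureParams}
    k_field : optional callable ``(X_m, domain) -> k_s`` evaluated at
        quadrature points (spatially varying permeability); defaults to the
        constant ``materials[domain].k_s``.
    quad_degree : volume quadrature degree.
    """

    def __init__(self, mesh: SimplexMesh, materials: dict[int, MixtureParams],
                 k_field=None, quad_degree: int = 4):
        self.mesh = mesh
        self.materials = materials
        d = mesh.dim
        self.d = d
        self.nb2 = n_basis(d, 2)
        self.nb1 = d + 1
        self.nu = d * mesh.n2
        self.nw = d * mesh.n2
        self.np_ = mesh.n_pdofs
        self.ndof = self.nu + self.nw + self.np_
        self.offs_w = self.nu
        self.offs_p = self.nu + self.nw

        lam, wq = quadrature(d, quad_degree)
        self.lam, self.wq = lam, wq
        self.nq = len(wq)
        phi2, dphi2 = eval_basis(lam, d, 2)
        phi1, _ = eval_basis(lam, d, 1)
        self.phi2, self.phi1 = phi2, phi1
        # physical gradients of P2 basis: (nc, nq, nb2, d)
        self.dN2 = np.einsum("qka,cad->cqkd", dphi2, mesh.grad_lam)
        # P1 gradients are cell-constant: (nc, nb1, d)
        self.dN1 = mesh.grad_lam.copy()
        # quadrature point positions: (nc, nq, d)
        self.Xq = np.einsum("qa,cad->cqd", lam, mesh.X1[mesh.cells])
        self.meas_w = mesh.cell_measure[:, None] * wq[None, :]  # (nc, nq)

        # per-cell material data
        self.zRs = np.array([materials[a].zeta_Rs for a in mesh.domain])
        self.mu_s = np.array([materials[a].mu_s for a in mesh.domain])
        self.rho_s = np.array([materials[a].rho_s_star for a in mesh.domain])
        self.mu_f = materials[1].mu_f
        if k_field is None:
            kq = np.empty((mesh.n_cells, self.nq))
            for a, m in materials.items():
                kq[mesh.domain == a] = m.k_s
        else:
            kq = np.empty((mesh.n_cells, self.nq))
            for a in np.unique(mesh.domain):
                msk = mesh.domain == a
                kq[msk] = k_field(self.Xq[msk].reshape(-1, d),
                                  int(a)).reshape(-1, self.nq)
        self.k_q = kq

        # interface-node mask for dropping domain-1 momentum rows
        iface_nodes = mesh.interface_nodes()
        self.is_iface_node = np.zeros(mesh.n2, dtype=bool)
        self.is_iface_node[iface_nodes] = True
        self._facet_cache: dict = {}
        self._iface_data = None

        # local dof layout within one cell: u (nb2*d), w (nb2*d), p (nb1)
        self.nloc = 2 * self.nb2 * d + self.nb1
        c2 = mesh.cells2
        gu = (c2[:, :, None] * d + np.arange(d)).reshape(mesh.n_cells, -1)
        self.gdof = np.concatenate(
            [gu, gu + self.offs_w, mesh.pcells + self.offs_p], axis=1)
        self._vol_rows = np.repeat(self.gdof, self.nloc, axis=1).ravel()
        self._vol_cols = np.tile(self.gdof, (1, self.nloc)).ravel()

        # geometry-independent blocks, assembled once
        musw = self.mu_s[:, None] * self.meas_w
        self._Ks_const = np.einsum("cq,cqkJ,cqlJ->ckl", musw, self.dN2,
                                   self.dN2, optimize=True)
        self._Mv_const = np.einsum("cq,qk,ql->ckl",
                                   self.rho_s[:, None] * self.zRs[:, None]
                                   * self.meas_w, self.phi2, self.phi2)

    # ------------------------------------------------------------------
    # geometry factors

    def geometry_factors(self, u: np.ndarray):
        """F, J, F^{-1}, F^{-T} at all volume quadrature points."""
        d = self.d
        un = u.reshape(self.mesh.n2, d)[self.mesh.cells2]   # (nc, nb2, d)
        grad_u = np.einsum("cki,cqkJ->cqiJ", un, self.dN2)
        F = grad_u + np.eye(d)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise NonPhysicalStateError("element inversion during solve")
        if np.any(J <= self.zRs[:, None]):
            raise NonPhysicalStateError("fluid phase vanished during solve")
        Finv = np.linalg.inv(F)
        FinvT = np.swapaxes(Finv, -1, -2)
        return F, J, Finv, FinvT

    # ------------------------------------------------------------------
    # volume assembly

    def assemble(self, state: FieldState, av: float, v_hist: np.ndarray,
                 aa: float = 0.0, a_hist: np.ndarray | None = None,
                 pressure_bc: dict[str, float] | None = None,
                 solid_pressure_bc: dict[str, float] | None = None,
                 robin_bc: dict[str, float] | None = None,
                 with_inertia: bool = True,
                 sources=None):
        """Assemble the global matrix and right-hand side.

        ``v_s = av*u + v_hist`` and ``a_s = aa*u + a_hist`` (nodal arrays,
        flattened).  ``pressure_bc`` maps facet-tag names to applied fluid
        pressures p_hat [Pa]; ``solid_pressure_bc`` applies the solid-phase
        share of a pressure-like traction (verification oracles).
        Returns (A_csr, b).
        """
        mesh, d, nb2, nb1 = self.mesh, self.d, self.nb2, self.nb1
        nq = self.nq
        F, J, Finv, FinvT = self.geometry_factors(state.u)
        mw = self.meas_w
        zRs = self.zRs[:, None]
        Jmz = J - zRs
        drag = self.mu_f / self.k_q * Jmz                    # (nc, nq)

        nc = mesh.n_cells
        Aloc = np.zeros((nc, self.nloc, self.nloc))
        bloc = np.zeros((nc, self.nloc))

        phi2, dN2, dN1 = self.phi2, self.dN2, self.dN1
        phi1 = self.phi1

        # --- mass-type scalar blocks (times identity in components)
        def add_vec_mass(row0, col0, coeff):
            Mb = np.einsum("cq,qk,ql->ckl", coeff * mw, phi2, phi2)
            for i in range(d):
                Aloc[:, row0 + i:row0 + nb2 * d:d,
                     col0 + i:col0 + nb2 * d:d] += Mb

        ou, ow, op = 0, nb2 * d, 2 * nb2 * d

        # solid momentum: inertia aa*u + drag(-w) + zeta*F^-T grad p + P_s
        if with_inertia and aa != 0.0:
            Mb = aa * self._Mv_const
            for i in range(d):
                Aloc[:, ou + i:ou + nb2 * d:d,
                     ou + i:ou + nb2 * d:d] += Mb
        add_vec_mass(ou, ow, -drag)

        # strong pressure gradient blocks: rows test-P2 x cols p
        # G[c,q,i,lp] = (F^{-T} grad(phi1_lp))_i
        Gp = np.einsum("cqiJ,clJ->cqil", FinvT, dN1)
        blk = np.einsum("cq,qk,cqil->ckil", zRs * mw, phi2, Gp)
        Aloc[:, ou:ou + nb2 * d, op:op + nb1] += \
            blk.reshape(nc, nb2 * d, nb1)
        blk = np.einsum("cq,qk,cqil->ckil", Jmz * mw, phi2, Gp)
        Aloc[:, ow:ow + nb2 * d, op:op + nb1] += \
            blk.reshape(nc, nb2 * d, nb1)

        # neo-Hookean stress, consistent (Newton) linearization about ubar:
        #   P_s(u) ~ mu [grad u + F^{-T} (grad u - grad ubar)^T F^{-T}
        #             + I - F^{-T}]        (F, F^{-T} frozen at ubar)
        # The exact tangent keeps the per-step iteration contractive; a pure
        # Picard split (transpose part lagged) is only marginally stable.
        musw = self.mu_s[:, None] * mw
        Ks = self._Ks_const
        for i in range(d):
            Aloc[:, ou + i:ou + nb2 * d:d, ou + i:ou + nb2 * d:d] += Ks
        # transpose-tangent: K[(k,i),(l,m)] =
        #   int mu dNk[J] FinvT[m,J] (FinvT[i,:].dNl)
        gT = np.einsum("cqiM,cqlM->cqli", FinvT, dN2)      # FinvT[i,:].dNl
        hT = np.einsum("cqkJ,cqmJ->cqkm", dN2, FinvT)      # dNk[J] FinvT[m,J]
        Kt = np.einsum("cq,cqkm,cqli->ckilm", musw, hT, gT, optimize=True)
        Aloc[:, ou:ou + nb2 * d, ou:ou + nb2 * d] += \
            Kt.reshape(nc, nb2 * d, nb2 * d)
        # constant part: mu (I - F^{-T} - F^{-T} grad(ubar)^T F^{-T})
        grad_ub = F - np.eye(d)
        corr = np.einsum("cqiM,cqNM,cqNJ->cqiJ", FinvT, grad_ub, FinvT)
        Cs = np.einsum("cq,cqkJ,cqiJ->cki", musw, dN2,
                       np.eye(d) - FinvT - corr)
        bloc[:, ou:ou + nb2 * d] -= Cs.reshape(nc, -1)

        # fluid drag and Brinkman
        add_vec_mass(ow, ow, drag)
        coef = self.mu_f * Jmz * mw
        s1 = np.einsum("cq,cqkJ,cqMJ,cqlM->ckl", coef, dN2, Finv, dN2,
                       optimize=True)
        for i in range(d):
            Aloc[:, ow + i:ow + nb2 * d:d, ow + i:ow + nb2 * d:d] += s1
        # transpose term: test (k,i), trial (l,m) -> dNk[m] * (dNl.Finv[:,i])
        g2 = np.einsum("cqlK,cqKi->cqli", dN2, Finv)
        t2 = np.einsum("cq,cqkm,cqli->ckilm", coef, dN2, g2,
                       optimize=True)
        Aloc[:, ow:ow + nb2 * d, ow:ow + nb2 * d] += \
            t2.reshape(nc, nb2 * d, nb2 * d)

        # incompressibility rows: b(v_s + w, ptest F^{-T})
        Bu = np.einsum("cq,ql,cqiJ,cqkJ->clki", mw, phi1, FinvT, dN2,
                       optimize=True)
        Bu = Bu.reshape(nc, nb1, nb2 * d)
        Aloc[:, op:op + nb1, ou:ou + nb2 * d] += av * Bu
        Aloc[:, op:op + nb1, ow:ow + nb2 * d] += Bu
        # rhs from v_hist
        vh = v_hist.reshape(mesh.n2, d)[mesh.cells2].reshape(nc, -1)
        bloc[:, op:op + nb1] -= np.einsum("clk,ck->cl", Bu, vh)

        # inertia rhs
        if with_inertia and a_hist is not None:
            ah = a_hist.reshape(mesh.n2, d)[mesh.cells2]     # (nc, nb2, d)
            bloc[:, ou:ou + nb2 * d] -= np.einsum(
                "ckl,cli->cki", self._Mv_const, ah).reshape(nc, -1)

        # volume sources (manufactured-solution verification):
        # sources = (f_solid(X), f_fluid(X), g_mass(X)); each may be None
        if sources is not None:
            f_s, f_f, g_m = sources
            Xf = self.Xq.reshape(-1, d)
            if f_s is not None:
                val = np.asarray(f_s(Xf)).reshape(nc, nq, d)
                bloc[:, ou:ou + nb2 * d] += np.einsum(
                    "cq,qk,cqi->cki", mw, phi2, val).reshape(nc, -1)
            if f_f is not None:
                val = np.asarray(f_f(Xf)).reshape(nc, nq, d)
                bloc[:, ow:ow + nb2 * d] += np.einsum(
                    "cq,qk,cqi->cki", mw, phi2, val).reshape(nc, -1)
            if g_m is not None:
                val = np.asarray(g_m(Xf)).reshape(nc, nq)
                bloc[:, op:op + nb1] += np.einsum(
                    "cq,ql,cq->cl", mw, phi1, val)

        # --- drop domain-1 momentum rows on interface nodes
        self._mask_domain1_rows(Aloc, bloc, np.arange(nc))

        b = np.zeros(self.ndof)
        np.add.at(b, self.gdof.ravel(), bloc.ravel())

        # --- collect triplets: the sparsity layout of every contribution is
        # geometry-independent, so the assembled pattern is cached and only
        # the value vector is rebuilt on later calls.
        triplets = [(self._vol_rows, self._vol_cols, Aloc.ravel())]
        for tag in sorted(pressure_bc or {}):
            r, c, v, bf = self._fluid_pressure_facets(tag, state,
                                                      pressure_bc[tag])
            triplets.append((r, c, v))
            b += bf
        for tag in sorted(solid_pressure_bc or {}):
            b += self._solid_pressure_facets(tag, state,
                                             solid_pressure_bc[tag])
        for tag in sorted(robin_bc or {}):
            triplets.append(self._robin_facets(tag, state, robin_bc[tag]))
        if self.mesh.interface is not None:
            r, c, v, bf = self._interface_terms(state)
            triplets.append((r, c, v))
            b += bf

        key = (tuple(sorted(pressure_bc or {})), tuple(sorted(robin_bc or {})))
        vals = np.concatenate([t[2] for t in triplets])
        if getattr(self, "_pattern_key", None) != key:
            rows = np.concatenate([t[0] for t in triplets])
            cols = np.concatenate([t[1] for t in triplets])
            self._pattern = _Pattern(rows, cols, (self.ndof, self.ndof))
            self._pattern_key = key
        A = self._pattern.csr(vals)
        return A, b

    def _mask_domain1_rows(self, Aloc, bloc, cells):
        """Zero u/w test rows of domain-1 cells on interface nodes."""
        if self.mesh.interface is None:
            return
        d, nb2 = self.d, self.nb2
        dom1 = self.mesh.domain[cells] == 1
        if not np.any(dom1):
            return
        nodemask = self.is_iface_node[self.mesh.cells2[cells]]  # (nc, nb2)
        rowmask = np.repeat(nodemask, d, axis=1) & dom1[:, None]
        full = np.zeros((len(cells), self.nloc), dtype=bool)
        full[:, :nb2 * d] = rowmask
        full[:, nb2 * d:2 * nb2 * d] = rowmask
        Aloc[full] = 0.0
        bloc[full] = 0.0

    # ------------------------------------------------------------------
    # facet machinery

    def _facet_data(self, fs: FacetSet, degree: int = 4):
        """Precompute basis values at facet quadrature points of the owning
        cells.  Cached per facet set."""
        key = (id(fs), degree)
        if key in self._facet_cache:
            return self._facet_cache[key]
        mesh, d = self.mesh, self.d
        nfa = len(fs)
        lam0, wq = mesh.facet_quad_barycentric(0, degree)
        nqf = len(wq)
        phi2 = np.empty((nfa, nqf, self.nb2))
        dphi2_lam = None
        lam_all = np.empty((nfa, nqf, d + 1))
        for lf in np.unique(fs.lfaces):
            lam, _ = mesh.facet_quad_barycentric(int(lf), degree)
            sel = fs.lfaces == lf
            p2, dp2 = eval_basis(lam, d, 2)
            phi2[sel] = p2
            lam_all[sel] = lam
            if dphi2_lam is None:
                dphi2_lam = {}
            dphi2_lam[int(lf)] = dp2
        # physical gradients per facet: depend on owning cell
        dN2 = np.empty((nfa, nqf, self.nb2, d))
        for lf, dp2 in dphi2_lam.items():
            sel = fs.lfaces == lf
            dN2[sel] = np.einsum("qka,fad->fqkd", dp2,
                                 mesh.grad_lam[fs.cells[sel]])
        phi1 = np.empty((nfa, nqf, self.nb1))
        for lf in np.unique(fs.lfaces):
            lam, _ = mesh.facet_quad_barycentric(int(lf), degree)
            p1, _ = eval_basis(lam, d, 1)
            phi1[fs.lfaces == lf] = p1
        data = {"wq": wq, "phi2": phi2, "phi1": phi1, "dN2": dN2, "lam": lam_all,
                "meas_w": fs.measure[:, None] * wq[None, :]}
        self._facet_cache[key] = data
        return data

    def _facet_geometry(self, fs: FacetSet, data, u):
        d = self.d
        un = u.reshape(self.mesh.n2, d)[self.mesh.cells2[fs.cells]]
        grad_u = np.einsum("fki,fqkJ->fqiJ", un, data["dN2"])
        F = grad_u + np.eye(d)
        J = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        FinvT = np.swapaxes(Finv, -1, -2)
        return F, J, Finv, FinvT

    def _zeta_of_cells(self, cells):
        return self.zRs[cells, 0] if self.zRs.ndim == 2 else self.zRs[cells]

    def _fluid_pressure_facets(self, tag: str, state: FieldState,
                               phat: float | np.ndarray):
        """-((J - zRs) w_test, (p - p_hat) F^{-T} n)_facets.

        Matrix part couples w rows to the facet pressure DOFs; the p_hat
        part goes to the rhs.  Returns (rows, cols, vals, b).
        """
        fs = self.mesh.tags[tag]
        d = self.d
        data = self._facet_data(fs)
        F, J, Finv, FinvT = self._facet_geometry(fs, data, state.u)
        zRs = self._zeta_of_cells(fs.cells)[:, None]
        coef = (J - zRs) * data["meas_w"]                    # (nf, nq)
        nvec = np.einsum("fqiJ,fJ->fqi", FinvT, fs.normal)   # (nf, nq, d)
        # rows: w dofs of owning cell; cols: p dofs of owning cell
        blk = -np.einsum("fq,fqk,fqi,fql->fkil", coef, data["phi2"],
                         nvec, data["phi1"], optimize=True)
        rhs = np.einsum("fq,fqk,fqi->fki", coef * phat, data["phi2"], nvec)
        nb2, nb1 = self.nb2, self.nb1
        wdofs = (self.mesh.cells2[fs.cells][:, :, None] * d
                 + np.arange(d)).reshape(len(fs), -1) + self.offs_w
        pdofs = self.mesh.pcells[fs.cells] + self.offs_p
        rows = np.repeat(wdofs, nb1, axis=1).ravel()
        cols = np.tile(pdofs, (1, nb2 * d)).ravel()
        b = np.zeros(self.ndof)
        # residual constant part is +int coef*phat*(w_test.F^{-T}n); the rhs
        # vector is minus the residual constants
        np.add.at(b, wdofs.ravel(), -rhs.reshape(len(fs), -1).ravel())
        return rows, cols, blk.reshape(len(fs), -1).ravel(), b

    def _solid_pressure_facets(self, tag: str, state: FieldState,
                               phat: float | np.ndarray):
        """Solid-phase share of a pressure-like traction:
        t_s = -zeta_Rs p_hat F^{-T} n (rhs only)."""
        fs = self.mesh.tags[tag]
        if len(fs) == 0:
            return np.zeros(self.ndof)
        d = self.d
        data = self._facet_data(fs)
        F, J, Finv, FinvT = self._facet_geometry(fs, data, state.u)
        zRs = self._zeta_of_cells(fs.cells)[:, None]
        coef = zRs * data["meas_w"] * phat
        nvec = np.einsum("fqiJ,fJ->fqi", FinvT, fs.normal)
        # traction t_hat = -zRs*phat*F^{-T}n; residual -= (w_test, t_hat)
        # => rhs (minus residual constants) = -int zRs phat (w_test.F^{-T}n)
        rhs = -np.einsum("fq,fqk,fqi->fki", coef, data["phi2"], nvec)
        udofs = (self.mesh.cells2[fs.cells][:, :, None] * d
                 + np.arange(d)).reshape(len(fs), -1)
        b = np.zeros(self.ndof)
        np.add.at(b, udofs.ravel(), rhs.reshape(len(fs), -1).ravel())
        return b

    def _robin_facets(self, tag: str, state: FieldState, coeff: float):
        """Implicit flow-resistance traction p_Robin = coeff * Q1.

        Q1 = int J w . F^{-T} n over the facet set is a linear functional of
        w (geometry frozen), so the Robin pressure adds the rank-one block
        coeff * outer(a, q) to the w-w coupling, with
        a_k = int (J - zRs) phi_k F^{-T} n  and  q_l = int J phi_l F^{-T} n.
        The block is positive semidefinite (dissipative) and keeping it
        implicit avoids the violent feedback an explicit lag produces with
        the stiff physiological resistance.
        """
        fs = self.mesh.tags[tag]
        d = self.d
        data = self._facet_data(fs)
        F, J, Finv, FinvT = self._facet_geometry(fs, data, state.u)
        zRs = self._zeta_of_cells(fs.cells)[:, None]
        nvec = np.einsum("fqiJ,fJ->fqi", FinvT, fs.normal)
        a_loc = np.einsum("fq,fqk,fqi->fki", (J - zRs) * data["meas_w"],
                          data["phi2"], nvec)
        q_loc = np.einsum("fq,fqk,fqi->fki", J * data["meas_w"],
                          data["phi2"], nvec)
        wdofs = (self.mesh.cells2[fs.cells][:, :, None] * d
                 + np.arange(d)).reshape(len(fs), -1) + self.offs_w
        a = np.zeros(self.ndof)
        q = np.zeros(self.ndof)
        np.add.at(a, wdofs.ravel(), a_loc.reshape(len(fs), -1).ravel())
        np.add.at(q, wdofs.ravel(), q_loc.reshape(len(fs), -1).ravel())
        cand = np.unique(wdofs)          # fixed candidate dof set
        block = coeff * np.outer(a[cand], q[cand])
        rows = np.repeat(cand, len(cand))
        cols = np.tile(cand, len(cand))
        return rows, cols, block.ravel()

    # ------------------------------------------------------------------
    # interface terms

    def _interface_terms(self, state: FieldState):
        """Phase-split traction transfer on the PVS/parenchyma interface.

        For domain-2 test functions t (solid rows) and s (fluid rows), with
        the common normal n = n^2 (outward from the parenchyma):

            R_u -= int_I t . zRs2 (p2 F2^{-T} + J2^{-1} P_mix^1) n
            R_w -= int_I s . (J2 - zRs2)(p2 F2^{-T} + J2^{-1} P_mix^1) n

        P_mix^1 = -J1 p1 F1^{-T} + P_s^1 + P_f^1 is evaluated from the
        domain-1 side.  Linearization: geometry factors frozen, stresses
        linear in (u, w, p) of the domain-1 cell.
        """
        iface = self.mesh.interface
        fs1, fs2 = iface.side1, iface.side2
        nfa = len(fs1)
        d, nb2, nb1 = self.d, self.nb2, self.nb1
        d1 = self._facet_data(fs1)
        d2 = self._facet_data(fs2)
        F1, J1, Finv1, FinvT1 = self._facet_geometry(fs1, d1, state.u)
        F2, J2, Finv2, FinvT2 = self._facet_geometry(fs2, d2, state.u)
        n2 = fs2.normal                                     # (nf, d)
        zRs2 = self._zeta_of_cells(fs2.cells)[:, None]
        mu_s1 = self.mu_s[fs1.cells][:, None]
        zRs1 = self._zeta_of_cells(fs1.cells)[:, None]
        mw = d2["meas_w"]                                   # same measure

        trips_r, trips_c, trips_v = [], [], []
        b = np.zeros(self.ndof)

        udofs2 = (self.mesh.cells2[fs2.cells][:, :, None] * d
                  + np.arange(d)).reshape(nfa, -1)
        wdofs2 = udofs2 + self.offs_w
        udofs1 = (self.mesh.cells2[fs1.cells][:, :, None] * d
                  + np.arange(d)).reshape(nfa, -1)
        wdofs1 = udofs1 + self.offs_w
        pdofs1 = self.mesh.pcells[fs1.cells] + self.offs_p
        pdofs2 = self.mesh.pcells[fs2.cells] + self.offs_p

        def scatter(rows, cols, vals):
            trips_r.append(rows.ravel())
            trips_c.append(cols.ravel())
            trips_v.append(vals.ravel())

        for rows_dofs, weight in ((udofs2, zRs2), (wdofs2, J2 - zRs2)):
            cw = weight * mw                                # (nf, nq)
            # p2 F2^{-T} n  (cols: domain-2 facet pressure dofs)
            nvec2 = np.einsum("fqiJ,fJ->fqi", FinvT2, n2)
            blk = -np.einsum("fq,fqk,fqi,fql->fkil", cw, d2["phi2"],
                             nvec2, d2["phi1"]).reshape(nfa, -1, nb1)
            rows = np.repeat(rows_dofs, nb1, axis=1)
            cols = np.tile(pdofs2, (1, nb2 * d))
            scatter(rows, cols, blk.reshape(nfa, -1))

            # J2^{-1} P_mix^1 n: pressure part +J1/J2 p1 F1^{-T} n
            nvec1 = np.einsum("fqiJ,fJ->fqi", FinvT1, n2)
            cw1 = cw * (J1 / J2)
            blk = np.einsum("fq,fqk,fqi,fql->fkil", cw1, d2["phi2"],
                            nvec1, d1["phi1"]).reshape(nfa, -1, nb1)
            cols = np.tile(pdofs1, (1, nb2 * d))
            scatter(np.repeat(rows_dofs, nb1, axis=1), cols,
                    blk.reshape(nfa, -1))

            # solid stress part: -J2^{-1} mu_s1 (grad u + I - F1bar^{-T}) n
            cw2 = cw * mu_s1 / J2
            # matrix: trial u of cell 1: (grad u) n = dN1[l,J] n[J] delta_il
            gn = np.einsum("fqlJ,fJ->fql", d1["dN2"], n2)   # (nf, nq, nb2)
            blk = -np.einsum("fq,fqk,fql->fkl", cw2, d2["phi2"], gn)
            # expand identity in components
            big = np.zeros((nfa, nb2 * d, nb2 * d))
            for i in range(d):
                big[:, i::d, i::d] = blk
            scatter(np.repeat(rows_dofs, nb2 * d, axis=1),
                    np.tile(udofs1, (1, nb2 * d)), big)
            # rhs const from P_s^1 linearization: -J2^{-1} mu_s1 (I-F1bar^-T)n
            cvec = np.einsum("fq,fqij,fj->fqi", cw2,
                             np.eye(d)[None, None] - FinvT1, n2)
            rb = np.einsum("fqk,fqi->fki", d2["phi2"], cvec)
            # residual const = -rb => rhs vector gets +rb
            np.add.at(b, rows_dofs.ravel(), rb.reshape(nfa, -1).ravel())

            # Brinkman part: -J2^{-1} P_f^1 n, P_f^1 = mu_f (J1 - zRs1) *
            #   (grad w F1inv + (grad w F1inv)^T)
            cw3 = cw * self.mu_f * (J1 - zRs1) / J2
            # term A: (grad w Finv1) n: [i,j] n_j = dN[l,K] Finv[K,j] n_j
            #   delta_{il,i}
            a1 = np.einsum("fqlK,fqKj,fj->fql", d1["dN2"], Finv1, n2)
            blkA = -np.einsum("fq,fqk,fql->fkl", cw3, d2["phi2"], a1)
            bigA = np.zeros((nfa, nb2 * d, nb2 * d))
            for i in range(d):
                bigA[:, i::d, i::d] = blkA
            # term B: (grad w Finv1)^T n: [i,j] = (grad w Finv)[j,i];
            #   times n_j -> dN[l,K] Finv[K,i] n_{il}
            a2 = np.einsum("fqlK,fqKi->fqli", d1["dN2"], Finv1)
            blkB = -np.einsum("fq,fqk,fqli,fm->fkilm",
                              cw3, d2["phi2"], a2, n2)
            # test (k,i), trial (l,m): value blkB[f,k,i,l,m]
            bigB = blkB.reshape(nfa, nb2, d, nb2, d).transpose(
                0, 1, 2, 3, 4).reshape(nfa, nb2 * d, nb2 * d)
            scatter(np.repeat(rows_dofs, nb2 * d, axis=1),
                    np.tile(wdofs1, (1, nb2 * d)), bigA + bigB)

        return (np.concatenate(trips_r), np.concatenate(trips_c),
                np.concatenate(trips_v), b)

    # ------------------------------------------------------------------
    # diagnostics integrals

    def facet_flux(self, fs: FacetSet, state: FieldState,
                   direction: np.ndarray | None = None) -> float:
        """Deformed-configuration fluid flux  int J w . F^{-T} n  over a
        facet set (n = stored facet normal, or a fixed direction)."""
        d = self.d
        data = self._facet_data(fs)
        F, J, Finv, FinvT = self._facet_geometry(fs, data, state.u)
        wn = state.w.reshape(self.mesh.n2, d)[self.mesh.cells2[fs.cells]]
        wq = np.einsum("fki,fqk->fqi", wn, data["phi2"])
        nv = fs.normal if direction is None else \
            np.broadcast_to(direction, fs.normal.shape)
        nvec = np.einsum("fqiJ,fJ->fqi", FinvT, nv)
        return float(np.einsum("fq,fq->", data["meas_w"],
                               J * np.einsum("fqi,fqi->fq", wq, nvec)))

    def facet_area(self, fs: FacetSet, state: FieldState,
                   weight: str = "J_zeta_Rs") -> float:
        """int J zeta_Rs (reference cross-section 'fluid area') or
        int J zeta_f with weight='J_zeta_f'."""
        data = self._facet_data(fs)
        F, J, Finv, FinvT = self._facet_geometry(fs, data, state.u)
        zRs = self._zeta_of_cells(fs.cells)[:, None]
        if weight == "J_zeta_Rs":
            val = J * zRs
        elif weight == "J_zeta_f":
            val = J - zRs
        elif weight == "J":
            val = J
        else:
            raise ValueError(weight)
        return float((data["meas_w"] * val).sum())

    def facet_point_values(self, fs: FacetSet, state: FieldState) -> dict:
        """Fields and geometry at facet quadrature points.

        Returns a dict with ``X`` (positions, (nf, nq, d)), ``w``
        (filtration velocity), ``u``, ``p`` is omitted, plus the quadrature
        weights * measures ``mw`` — enough for diagnostics to build e.g.
        per-facet averages of the interface-normal filtration velocity.
        """
        d = self.d
        data = self._facet_data(fs)
        wn = state.w.reshape(self.mesh.n2, d)[self.mesh.cells2[fs.cells]]
        un = state.u.reshape(self.mesh.n2, d)[self.mesh.cells2[fs.cells]]
        wq = np.einsum("fki,fqk->fqi", wn, data["phi2"])
        uq = np.einsum("fki,fqk->fqi", un, data["phi2"])
        Xq = np.einsum("fqa,fad->fqd", data["lam"],
                       self.mesh.X1[self.mesh.cells[fs.cells]])
        return {"X": Xq, "w": wq, "u": uq, "mw": data["meas_w"],
                "normal": fs.normal}

    def energies(self, state: FieldState, v_s: np.ndarray) -> dict:
        """Stored (neo-Hookean) strain energy and solid kinetic energy [J]."""
        d = self.d
        F, J, Finv, FinvT = self.geometry_factors(state.u)
        trC = np.einsum("cqiJ,cqiJ->cq", F, F)
        psi = 0.5 * self.mu_s[:, None] * (trC - d - 2.0 * np.log(J))
        strain = float((self.meas_w * psi).sum())
        vn = v_s.reshape(self.mesh.n2, d)[self.mesh.cells2]
        vq = np.einsum("cki,qk->cqi", vn, self.phi2)
        ke = 0.5 * self.rho_s[:, None] * self.zRs[:, None] \
            * np.einsum("cqi,cqi->cq", vq, vq)
        kinetic = float((self.meas_w * ke).sum())
        return {"strain": strain, "kinetic": kinetic,
                "total": strain + kinetic}

    def domain_volume(self, state: FieldState, domain: int | None = None
                      ) -> float:
        """Deformed volume int J dOmega (per domain or total)."""
        F, J, Finv, FinvT = self.geometry_factors(state.u)
        msk = slice(None) if domain is None else self.mesh.domain == domain
        return float((self.meas_w[msk] * J[msk]).sum())

    def residual(self, state: FieldState, av, v_hist, aa=0.0, a_hist=None,
                 pressure_bc=None, solid_pressure_bc=None, robin_bc=None,
                 with_inertia=True, sources=None) -> np.ndarray:
        """Picard-consistent global residual R(U) = A(U) U - b(U)."""
        A, b = self.assemble(state, av, v_hist, aa, a_hist,
                             pressure_bc=pressure_bc,
                             solid_pressure_bc=solid_pressure_bc,
                             robin_bc=robin_bc, with_inertia=with_inertia,
                             sources=sources)
        U = np.concatenate([state.u.ravel(), state.w.ravel(), state.p])
        return A @ U - b
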