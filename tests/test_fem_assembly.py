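"""FEM kernel: reference elements, quadrature, and residual identities."""

import numpy as np
import pytest
from math import factorial

from pvsporo.fem.assembly import FieldState, PoroelasticForm
from pvsporo.fem.reference import edge_list, eval_basis, n_basis, quadrature
from pvsporo.geometry import build_2d_block, build_reference_geometry
from pvsporo.params import MixtureParams, PVS_SAS, parenchyma


def simplex_monomial_integral(powers):
    """int over unit-measure simplex of prod lambda_i^a_i (exact)."""
    d = len(powers) - 1
    num = np.prod([factorial(a) for a in powers]) * factorial(d)
    return num / factorial(sum(powers) + d)


class TestReferenceElements:
    @pytest.mark.parametrize("d", [2, 3])
    @pytest.mark.parametrize("order", [1, 2])
    def test_partition_of_unity(self, d, order, rng):
        lam = rng.dirichlet(np.ones(d + 1), size=7)
        phi, dphi = eval_basis(lam, d, order)
        assert phi.shape == (7, n_basis(d, order))
        assert np.allclose(phi.sum(axis=1), 1.0)
        # derivatives along admissible directions (zero-sum in barycentric
        # coordinates) sum to zero over the basis
        c = rng.standard_normal(d + 1)
        c -= c.mean()
        assert np.allclose(np.einsum("qka,a->qk", dphi, c).sum(axis=1),
                           0.0, atol=1e-12)

    @pytest.mark.parametrize("d", [2, 3])
    def test_nodal_interpolation_property(self, d):
        """P2 basis is 1 at its own node, 0 at the others."""
        nv = d + 1
        lam_nodes = list(np.eye(nv))
        for a, b in edge_list(d):
            mid = np.zeros(nv)
            mid[a] = mid[b] = 0.5
            lam_nodes.append(mid)
        phi, _ = eval_basis(np.array(lam_nodes), d, 2)
        assert np.allclose(phi, np.eye(len(lam_nodes)), atol=1e-14)

    @pytest.mark.parametrize("d,degree", [(2, 2), (2, 4), (2, 5),
                                          (3, 2), (3, 4)])
    def test_quadrature_exactness(self, d, degree):
        lam, w = quadrature(d, degree)
        for _ in range(30):
            powers = np.random.RandomState(abs(hash((d, degree))) % 2**31
                                           ).multinomial(degree,
                                                         np.ones(d + 1)
                                                         / (d + 1))
            break
        # systematically test all monomials up to the stated degree
        from itertools import product
        for powers in product(range(degree + 1), repeat=d + 1):
            if sum(powers) > degree:
                continue
            val = np.sum(w * np.prod(lam ** np.array(powers), axis=1))
            assert np.isclose(val, simplex_monomial_integral(powers),
                              rtol=1e-12, atol=1e-14)


@pytest.fixture(scope="module")
def block_form():
    mesh = build_2d_block(4)
    mat = MixtureParams(1000.0, 1000.0, 1e-3, 2000.0, 2e-14, 0.2)
    return PoroelasticForm(mesh, {1: mat})


@pytest.fixture(scope="module")
def two_domain_form():
    mesh = build_reference_geometry(resolution="tiny")
    return PoroelasticForm(mesh, {1: PVS_SAS, 2: parenchyma("awake")})


class TestResidualIdentities:
    def test_zero_state_zero_residual(self, block_form):
        form = block_form
        n2 = form.mesh.n2
        st = FieldState(np.zeros((n2, 2)), np.zeros((n2, 2)),
                        np.zeros(form.mesh.n_pdofs))
        r = form.residual(st, av=1.0, v_hist=np.zeros(form.nu),
                          pressure_bc={"left": 0.0, "right": 0.0})
        assert np.allclose(r, 0.0)

    def test_uniform_pressure_rest_state(self, two_domain_form):
        """Uniform pore pressure with matching boundary tractions is an
        equilibrium of the full two-domain weak form, including the
        phase-split interface terms."""
        form = two_domain_form
        n2 = form.mesh.n2
        p0 = 5.0
        st = FieldState(np.zeros((n2, 3)), np.zeros((n2, 3)),
                        np.full(form.mesh.n_pdofs, p0))
        r = form.residual(st, av=0.0, v_hist=np.zeros(form.nu),
                          with_inertia=False,
                          pressure_bc={"sas_inlet": p0, "sas_outlet": p0,
                                       "pvs_bottom": p0})
        # rows fixed by Dirichlet data would be overwritten by the solver;
        # check the remaining (interior + Neumann) rows
        from pvsporo.bc import DirichletTable
        tab = DirichletTable(form.mesh, form.nu)
        for tag in ("wall", "skull"):
            tab.fix_vector("u", tag, None)
            tab.fix_vector("w", tag, None)
        for tag, comp in (("symmetry", 0), ("outer_x", 0), ("outer_y", 1),
                          ("tissue_bottom", 2)):
            tab.fix_component("u", tag, comp)
            tab.fix_component("w", tag, comp)
        tab.finalize()
        free = np.setdiff1d(np.arange(form.ndof), tab.fixed_dofs)
        scale = p0 * form.mesh.cell_measure.max() ** (2 / 3)
        assert np.max(np.abs(r[free])) < 1e-8 * scale

    def test_uniform_strain_patch(self, block_form):
        """Spatially uniform strain with zero pressure: the stress
        divergence vanishes, so interior momentum rows are zero."""
        form = block_form
        mesh = form.mesh
        eps = 1e-3
        u = np.zeros((mesh.n2, 2))
        u[:, 0] = eps * mesh.X2[:, 0]
        st = FieldState(u, np.zeros((mesh.n2, 2)),
                        np.zeros(mesh.n_pdofs))
        r = form.residual(st, av=0.0, v_hist=np.zeros(form.nu),
                          with_inertia=False)
        # interior u rows only (boundary rows carry the traction imbalance)
        X = mesh.X2
        L = X[:, 0].max()
        interior = np.where((X[:, 0] > 1e-9) & (X[:, 0] < L - 1e-9)
                            & (X[:, 1] > 1e-9) & (X[:, 1] < L - 1e-9))[0]
        rows = (interior[:, None] * 2 + np.arange(2)).ravel()
        assert np.max(np.abs(r[rows])) < 1e-9 * 2000.0 * eps * L


class TestEnergies:
    def test_reference_state_has_zero_energy(self, block_form):
        form = block_form
        n2 = form.mesh.n2
        st = FieldState(np.zeros((n2, 2)), np.zeros((n2, 2)),
                        np.zeros(form.mesh.n_pdofs))
        e = form.energies(st, np.zeros(form.nu))
        assert np.isclose(e["total"], 0.0, atol=1e-20)

    def test_energy_positive_under_deformation(self, block_form, rng):
        form = block_form
        n2 = form.mesh.n2
        u = 1e-7 * rng.standard_normal((n2, 2))
        st = FieldState(u, np.zeros((n2, 2)), np.zeros(form.mesh.n_pdofs))
        e = form.energies(st, np.ones(form.nu))
        assert e["strain"] > 0.0
        assert e["kinetic"] > 0.0
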