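"""Reference geometry, meshing and spatial material fields."""

import numpy as np
import pytest

from pvsporo.geometry import (GeometrySpec, RESOLUTIONS, build_2d_block,
                              build_reference_geometry, material_field,
                              refine, smoothstep)
from pvsporo.units import UM


class TestGeometrySpec:
    def test_reference_cross_sections(self):
        spec = GeometrySpec()
        # brain surface: 20 um diameter vessel, 8 um PVS annulus
        assert np.isclose(spec.r_arteriole(150.0), 10.0)
        assert np.isclose(spec.r_pvs_outer(150.0), 18.0)
        # deep end: 15 um diameter, 5.5 um annulus
        assert np.isclose(spec.r_arteriole(0.0), 7.5)
        assert np.isclose(spec.r_pvs_outer(0.0), 13.0)

    def test_bounding_box_dimensions(self):
        spec = GeometrySpec()
        # full model before halving: 2*80 x 200 x 200 um
        assert 2 * spec.box_x == 160.0
        assert 2 * spec.y_half == 200.0
        assert spec.z_total == 200.0

    def test_region_classification(self):
        spec = GeometrySpec()
        pts = np.array([[12.0, 0.0, 75.0],    # inside PVS annulus
                        [50.0, 0.0, 75.0],    # parenchyma
                        [40.0, 0.0, 180.0]])  # SAS
        assert list(spec.region_of(pts * UM)) == ["PVS", "ECS", "SAS"]


class Test2DBlock:
    def test_area_and_counts(self):
        m = build_2d_block(30)
        assert m.n_cells == 2 * 30**2
        assert np.isclose(m.cell_measure.sum(), (150e-6) ** 2)

    def test_refinement_quadruples_triangles(self):
        assert build_2d_block(16).n_cells == 4 * build_2d_block(8).n_cells

    def test_boundary_fully_tagged(self):
        m = build_2d_block(8)
        assert sum(len(v) for v in m.tags.values()) == 4 * 8


class TestReferenceGeometry:
    @pytest.fixture(scope="class")
    def mesh(self):
        return build_reference_geometry(resolution="tiny")

    def test_two_conforming_domains(self, mesh):
        assert set(np.unique(mesh.domain)) == {1, 2}
        iface = mesh.interface
        assert iface is not None and len(iface) > 0
        # facet pairs address the same geometric triangles
        from pvsporo.fem.reference import facet_vertices
        fv = facet_vertices(3)
        for k in range(len(iface)):
            v1 = sorted(mesh.cells[iface.side1.cells[k],
                                   list(fv[iface.side1.lfaces[k]])])
            v2 = sorted(mesh.cells[iface.side2.cells[k],
                                   list(fv[iface.side2.lfaces[k]])])
            assert v1 == v2

    def test_every_boundary_facet_uniquely_tagged(self, mesh):
        mesh.check_boundary_tagged()   # raises on violation

    def test_domain_volumes_near_analytic(self, mesh):
        # half box minus cavity ~ 3.17e6 um^3; chord error only
        vol = mesh.cell_measure.sum() / UM**3
        assert abs(vol - 3.174e6) / 3.174e6 < 0.02

    def test_volume_converges_under_refinement(self):
        res = RESOLUTIONS["tiny"]
        v1 = build_reference_geometry(resolution=res).cell_measure.sum()
        v2 = build_reference_geometry(resolution=refine(res)
                                      ).cell_measure.sum()
        assert abs(v2 - v1) / v2 < 0.01

    def test_wall_vertices_on_arteriole_surface(self, mesh):
        # vertices lie exactly on the circular wall; P2 midpoints sit on
        # chords (straight-sided elements), within the sagitta
        spec = GeometrySpec()
        fs = mesh.tags["wall"]
        for c, lf in zip(fs.cells[:10], fs.lfaces[:10]):
            nodes = mesh.facet_nodes2(int(c), int(lf))
            Xv = mesh.X2[nodes[:3]] / UM
            r = np.hypot(Xv[:, 0], Xv[:, 1])
            assert np.allclose(r, spec.r_arteriole(Xv[:, 2]), atol=1e-6)


class TestMaterialField:
    def test_reference_permeabilities(self):
        assert np.isclose(material_field(50.0, 1)["k_s"], 2e-14)
        assert np.isclose(material_field(180.0, 1)["k_s"], 2e-12)
        # log-interpolation midpoint of the transition band
        assert np.isclose(material_field(140.0, 1)["k_s"], 2e-13)

    def test_sleep_mode_parenchyma(self):
        awake = material_field(75.0, 2, mode="awake")
        sleep = material_field(75.0, 2, mode="sleep")
        assert np.isclose(awake["k_s"], 2e-15)
        assert np.isclose(sleep["k_s"], 4e-15)
        assert np.isclose(awake["zeta_Rf"], 0.2)
        assert np.isclose(sleep["zeta_Rf"], 0.3)

    def test_transition_monotone_and_c2(self):
        z = np.linspace(125.0, 155.0, 3001)
        k = material_field(z, 1)["k_s"]
        assert np.all(np.diff(k) >= -1e-30)
        # numerical second derivative of the smoothstep is continuous
        s = smoothstep(np.linspace(-0.1, 1.1, 12001))
        d2 = np.diff(s, 2)
        assert np.max(np.abs(np.diff(d2))) < 1e-5

    def test_out_of_range_and_bad_mode(self):
        with pytest.raises(ValueError):
            material_field(250.0, 1)
        with pytest.raises(ValueError):
            material_field(50.0, 2, mode="nap")
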