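"""Reference geometry, meshing and spatial material fields.

The model domain is a half block (symmetry plane x = 0) of cortex,
80 x 200 x 200 um, with a penetrating arteriole on the axis (x, y) = (0, 0):

* z in [150, 200] um — subarachnoid space (SAS), a 50 um porous channel
  between the brain surface and the skull-fixed dura;
* z in [0, 150] um — brain parenchyma, pierced by the arteriole (radius
  tapering 10 -> 7.5 um) and its annular paravascular space (PVS, width
  8 -> 5.5 um).

Domain 1 = PVS + SAS (fluid-filled), domain 2 = parenchyma.  The arteriole
is modelled as a straight vertical vessel continuing through the SAS to the
dura (the wall-motion amplitude is tapered to zero below the dura); the
junction of the PVS with the SAS is widened by a chamfer that stands in for
the circular fillet of the physical geometry.  Geometry metadata records
both approximations.

Meshes are block-structured: an O-grid of hexahedra in (radius, angle,
depth) coordinates, Kuhn-split into tetrahedra (conforming by
construction), with the grid graded radially away from the vessel.
Dimensions below are in micrometres; meshes are emitted in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fem.mesh import SimplexMesh
from .units import UM

__all__ = ["GeometrySpec", "Resolution", "RESOLUTIONS",
           "build_reference_geometry", "build_2d_block",
           "material_field", "smoothstep", "TISSUE_OUTER_TAGS"]

#: tags whose facets carry zero-normal-component (symmetry-like) constraints
#: on the parenchyma/outer surfaces
TISSUE_OUTER_TAGS = ("outer_x", "outer_y", "tissue_bottom")


@dataclass(frozen=True)
class GeometrySpec:
    """Reference dimensions of the model geometry, in micrometres."""

    box_x: float = 80.0          # half-separation between arterioles (x)
    y_half: float = 100.0        # SAS channel half-length (y in [-100, 100])
    z_total: float = 200.0       # skull at z = 200
    z_surface: float = 150.0     # brain surface / SAS floor
    r_art_surface: float = 10.0  # arteriole radius at the surface (20 um dia)
    r_art_deep: float = 7.5      # arteriole radius at z = 0 (15 um dia)
    w_pvs_surface: float = 8.0   # PVS annulus width at the surface
    w_pvs_deep: float = 5.5      # PVS annulus width at z = 0
    fillet_radius: float = 7.0   # PVS/SAS junction fillet (chamfer stand-in)
    wall_taper: tuple = (160.0, 190.0)  # wall amplitude -> 0 below the dura

    def r_arteriole(self, z):
        """Arteriole (wall) radius at depth z [um]."""
        z = np.asarray(z, dtype=float)
        zs = self.z_surface
        r = self.r_art_deep + (self.r_art_surface - self.r_art_deep) \
            * np.clip(z / zs, 0.0, 1.0)
        return r

    def r_pvs_outer(self, z):
        """Nominal PVS outer radius (arteriole + annulus width) [um]."""
        z = np.asarray(z, dtype=float)
        w = self.w_pvs_deep + (self.w_pvs_surface - self.w_pvs_deep) \
            * np.clip(z / self.z_surface, 0.0, 1.0)
        return self.r_arteriole(z) + w

    def r_pvs_outer_meshed(self, z):
        """PVS outer radius including the junction chamfer [um]."""
        z = np.asarray(z, dtype=float)
        c = self.fillet_radius
        zs = self.z_surface
        base = self.r_pvs_outer(np.minimum(z, zs))
        if c <= 0:
            return np.where(z >= zs, self.r_pvs_outer(zs), base)
        r_top = self.r_pvs_outer(zs) + c
        r0 = self.r_pvs_outer(zs - c)
        cham = r0 + (z - (zs - c)) * (r_top - r0) / c
        out = np.where((z > zs - c) & (z <= zs), np.maximum(base, cham), base)
        return np.where(z > zs, r_top, out)

    def region_of(self, X_m: np.ndarray) -> np.ndarray:
        """Classify reference points [m] as 'PVS', 'ECS' or 'SAS'.

        Uses the nominal (un-chamfered) geometry; points in the chamfer
        wedge count as PVS (they belong to the fluid-filled domain).
        """
        X = np.atleast_2d(X_m) / UM
        r = np.hypot(X[:, 0], X[:, 1])
        z = X[:, 2]
        out = np.where(z > self.z_surface, "SAS", "ECS").astype("<U3")
        inside_pvs = (z <= self.z_surface) & \
            (r <= self.r_pvs_outer_meshed(z) + 1e-9)
        out[inside_pvs] = "PVS"
        return out


@dataclass(frozen=True)
class Resolution:
    """Mesh resolution knobs (station counts of the structured O-grid)."""

    name: str
    n_theta: int          # angular intervals over the half circumference
    n_pvs: int            # radial intervals across the PVS annulus
    n_par: int            # radial intervals across the parenchyma
    z_lower: tuple        # z stations [um] from 0 up to the chamfer base
    n_sas: int            # z intervals across the SAS
    grading: float = 1.7  # radial geometric grading in the parenchyma
    boundary_layer_um: float = 2.5  # first parenchyma layer at the interface


RESOLUTIONS = {
    "tiny": Resolution("tiny", n_theta=4, n_pvs=2, n_par=2,
                       z_lower=(0.0, 50.0, 75.0, 110.0, 143.0), n_sas=2,
                       grading=2.4),
    "desk": Resolution("desk", n_theta=4, n_pvs=2, n_par=3,
                       z_lower=(0.0, 37.5, 75.0, 112.5, 143.0), n_sas=3),
    "fine": Resolution("fine", n_theta=8, n_pvs=3, n_par=5,
                       z_lower=(0.0, 25.0, 50.0, 75.0, 100.0, 125.0, 143.0),
                       n_sas=5),
    "workstation": Resolution("workstation", n_theta=16, n_pvs=4, n_par=12,
                        z_lower=tuple(np.r_[np.linspace(0, 137, 28), 143.0]),
                        n_sas=12, grading=1.25),
}


def refine(res: Resolution) -> Resolution:
    """One uniform refinement step (all interval counts doubled)."""
    zl = np.asarray(res.z_lower)
    zmid = 0.5 * (zl[1:] + zl[:-1])
    z_new = tuple(np.sort(np.concatenate([zl, zmid])))
    return replace(res, name=res.name + "+", n_theta=2 * res.n_theta,
                   n_pvs=2 * res.n_pvs, n_par=2 * res.n_par,
                   z_lower=z_new, n_sas=2 * res.n_sas,
                   grading=np.sqrt(res.grading))


# ----------------------------------------------------------------------------
# material fields

def smoothstep(xi):
    """Quintic smoothstep 6 xi^5 - 15 xi^4 + 10 xi^3 on [0, 1] (C2)."""
    xi = np.clip(np.asarray(xi, dtype=float), 0.0, 1.0)
    return xi**3 * (10.0 + xi * (-15.0 + 6.0 * xi))


K_PVS = 2e-14      # Darcy permeability of the PVS [m^2], z < 130 um
K_SAS = 2e-12      # Darcy permeability of the SAS [m^2], z > 150 um
K_TRANSITION = (130.0, 150.0)   # transition band [um]


def material_field(z_um, domain: int = 1, mode: str = "awake",
                   k_ecs: float | None = None) -> dict:
    """Pointwise material parameters at depth(s) ``z_um`` [micrometres].

    Domain 1 permeability steps from the PVS value (2e-14 m^2) to the SAS
    value (2e-12 m^2) across z in [130, 150] um with a quintic smoothstep
    applied in log10(k) (the permeability spans two decades, so geometric
    interpolation is the natural choice).  Domain 2 is spatially uniform;
    'sleep' raises its fluid fraction 0.2 -> 0.3 and permeability
    2e-15 -> 4e-15 m^2.  ``k_ecs`` overrides the domain-2 permeability.
    """
    z = np.asarray(z_um, dtype=float)
    if np.any((z < -1e-9) | (z > 200.0 + 1e-9)):
        raise ValueError("z out of range [0, 200] um")
    if mode not in ("awake", "sleep"):
        raise ValueError(f"unknown mode {mode!r}")
    if domain == 1:
        z0, z1 = K_TRANSITION
        s = smoothstep((z - z0) / (z1 - z0))
        log_k = np.log10(K_PVS) + s * (np.log10(K_SAS) - np.log10(K_PVS))
        return {"k_s": 10.0 ** log_k, "zeta_Rf": np.full_like(z, 0.8)}
    if domain == 2:
        if k_ecs is None:
            k_ecs = 2e-15 if mode == "awake" else 4e-15
        zf = 0.2 if mode == "awake" else 0.3
        return {"k_s": np.full_like(z, k_ecs),
                "zeta_Rf": np.full_like(z, zf)}
    raise ValueError("domain must be 1 or 2")


# ----------------------------------------------------------------------------
# 3D reference mesh

def _theta_stations(spec: GeometrySpec, n_theta: int) -> np.ndarray:
    """Angles in [-pi/2, pi/2]; the box-corner directions are snapped into
    the set so every outer facet lies exactly on one box face."""
    th = np.linspace(-np.pi / 2, np.pi / 2, n_theta + 1)
    for thc in (-np.arctan2(spec.y_half, spec.box_x),
                np.arctan2(spec.y_half, spec.box_x)):
        i = int(np.argmin(np.abs(th - thc)))
        i = min(max(i, 1), len(th) - 2)   # keep the symmetry-plane rays
        th[i] = thc
    return th


def _r_out(spec: GeometrySpec, theta: float) -> float:
    """Distance from the axis to the box boundary along direction theta."""
    c, s = np.cos(theta), np.sin(theta)
    cands = []
    if c > 1e-12:
        cands.append(spec.box_x / c)
    if s > 1e-12:
        cands.append(spec.y_half / s)
    elif s < -1e-12:
        cands.append(-spec.y_half / s)
    return min(cands)


def _graded(n: int, ratio: float) -> np.ndarray:
    """n+1 stations on [0,1], spacing growing geometrically by ``ratio``."""
    steps = ratio ** np.arange(n)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    return s / s[-1]


_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0),
               (2, 0, 1), (2, 1, 0)]


def build_reference_geometry(spec: GeometrySpec | None = None,
                             resolution: str | Resolution = "desk"
                             ) -> SimplexMesh:
    """Build the conforming two-domain tetrahedral mesh.

    Boundary tags: ``wall`` (arteriole, Dirichlet motion + no-slip),
    ``skull`` (z = 200, all zero), ``sas_inlet``/``sas_outlet`` (y = +/-100
    on domain 1, fluid pressure tractions), ``pvs_bottom`` (z = 0 on domain
    1, Robin resistance), ``symmetry`` (x = 0), and the zero-normal-flow
    group ``outer_x``, ``outer_y``, ``tissue_bottom``.  The PVS/SAS-
    parenchyma interface is discovered from the domain labels.
    """
    spec = spec or GeometrySpec()
    res = RESOLUTIONS[resolution] if isinstance(resolution, str) else resolution

    zs = spec.z_surface
    z_cham = np.array([zs]) if spec.fillet_radius <= 0 else \
        np.array([zs - spec.fillet_radius / 2.0, zs]) \
        if res.z_lower[-1] < zs - spec.fillet_radius / 2.0 else np.array([zs])
    z_low = np.asarray(res.z_lower, dtype=float)
    z_sas = np.linspace(zs, spec.z_total, res.n_sas + 1)[1:]
    z_levels = np.unique(np.concatenate([z_low, z_cham, z_sas]))
    th = _theta_stations(spec, res.n_theta)
    T = len(th)
    L = len(z_levels)
    s_par = _graded(res.n_par, res.grading)
    n_r = res.n_pvs + res.n_par + 1      # +1: interface boundary layer
    R = n_r + 1

    r_out = np.array([_r_out(spec, t) for t in th])
    nodes = np.empty((L, T, R, 3))
    for l, z in enumerate(z_levels):
        ra = float(spec.r_arteriole(z))
        rp = float(spec.r_pvs_outer_meshed(z))
        r_pvs = ra + (rp - ra) * np.linspace(0, 1, res.n_pvs + 1)
        for j, t in enumerate(th):
            # thin first parenchyma layer resolves the near-interface
            # velocity boundary region; remainder geometrically graded
            bl = min(res.boundary_layer_um, 0.2 * (r_out[j] - rp))
            r_par = np.concatenate(
                [[rp + bl], rp + bl + (r_out[j] - rp - bl) * s_par[1:]])
            rr = np.concatenate([r_pvs, r_par])
            nodes[l, j, :, 0] = rr * np.cos(t)
            nodes[l, j, :, 1] = rr * np.sin(t)
            nodes[l, j, :, 2] = z
    X = nodes.reshape(-1, 3)

    def nid(l, j, i):
        return (l * T + j) * R + i

    cells, dom = [], []
    for l in range(L - 1):
        zmid = 0.5 * (z_levels[l] + z_levels[l + 1])
        for j in range(T - 1):
            for i in range(n_r):
                # hex corners indexed by steps along (r, theta, z)
                c = np.empty((2, 2, 2), dtype=np.int64)
                for a in (0, 1):
                    for b in (0, 1):
                        for cdx in (0, 1):
                            c[a, b, cdx] = nid(l + cdx, j + b, i + a)
                d = 1 if (i < res.n_pvs or zmid > zs) else 2
                for perm in _KUHN_PERMS:
                    steps = np.zeros((4, 3), dtype=int)
                    for k_, ax in enumerate(perm):
                        steps[k_ + 1:] += np.eye(3, dtype=int)[ax]
                    tet = [c[tuple(srow)] for srow in steps]
                    cells.append(tet)
                    dom.append(d)

    mesh = SimplexMesh(X * UM, np.array(cells), np.array(dom), metadata={
        "geometry": "half-block, vertical-vessel approximation",
        "surface_arteriole": "vertical continuation (sweep along y not built)",
        "fillet": f"chamfer {spec.fillet_radius} um (circular fillet "
                  "approximated)",
        "resolution": res.name,
        "units": "m",
    })

    tol = 1e-6 * UM
    x_max, y_half, z_top = spec.box_x * UM, spec.y_half * UM, spec.z_total * UM

    def on(axis, value):
        return lambda P: np.abs(P[:, axis] - value) < tol

    def r_wall(P):
        z_um = P[:, 2] / UM
        r = np.hypot(P[:, 0], P[:, 1]) / UM
        return np.abs(r - spec.r_arteriole(z_um)) < 1e-6

    mesh.tag_boundary("skull", on(2, z_top))
    mesh.tag_boundary("wall", r_wall)
    mesh.tag_boundary("symmetry", on(0, 0.0))
    mesh.tag_boundary("outer_x", on(0, x_max))
    # skull facets also satisfy no other predicate; wall facets that touch
    # the skull plane are lateral (not all-z=200) so the tags are disjoint,
    # except skull facets adjacent to the wall: drop duplicates by priority.
    _dedup_tags(mesh, order=("skull", "wall", "symmetry", "outer_x"))

    def band(name, axis, value, dm):
        pairs = []
        for key, (c, lf) in mesh.boundary_facets():
            P = mesh.X1[list(key)]
            if np.all(np.abs(P[:, axis] - value) < tol) \
                    and mesh.domain[c] == dm:
                pairs.append((c, lf))
        fs = mesh._make_facet_set(name, pairs)
        mesh.tags[name] = fs
        return fs

    band("sas_inlet", 1, +y_half, 1)
    band("sas_outlet", 1, -y_half, 1)
    band("outer_y_pos", 1, +y_half, 2)
    band("outer_y_neg", 1, -y_half, 2)
    band("pvs_bottom", 2, 0.0, 1)
    band("tissue_bottom", 2, 0.0, 2)
    # merge the two outer_y bands
    oy = mesh.tags.pop("outer_y_pos"), mesh.tags.pop("outer_y_neg")
    from .fem.mesh import FacetSet
    mesh.tags["outer_y"] = FacetSet(
        "outer_y",
        np.concatenate([oy[0].cells, oy[1].cells]),
        np.concatenate([oy[0].lfaces, oy[1].lfaces]),
        np.concatenate([oy[0].normal, oy[1].normal]),
        np.concatenate([oy[0].measure, oy[1].measure]))

    mesh.check_boundary_tagged()
    mesh.build_interface()
    return mesh


# ----------------------------------------------------------------------------
# 2D verification block

def build_2d_block(n: int = 20, length_um: float = 150.0,
                   ny: int | None = None,
                   height_um: float | None = None,
                   y0_um: float = 0.0) -> SimplexMesh:
    """Rectangular poroelastic block (default: 150 um square, the lag-
    experiment geometry).

    Structured n x ny grid, each square split into two triangles; boundary
    tags ``left``, ``right``, ``top``, ``bottom``.
    """
    L = length_um * UM
    H = (height_um or length_um) * UM
    ny = ny or n
    sx = np.linspace(0.0, L, n + 1)
    sy = np.linspace(y0_um * UM, y0_um * UM + H, ny + 1)
    xx, yy = np.meshgrid(sx, sy, indexing="ij")
    X = np.column_stack([xx.ravel(), yy.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(n):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), \
                nid(i, j + 1)
            cells.append([a, b, c])
            cells.append([a, c, d])
    mesh = SimplexMesh(X, np.array(cells), np.ones(len(cells), dtype=int),
                       metadata={"geometry": "2d block", "units": "m"})
    tol = 1e-12
    ytop = sy[-1]
    mesh.tag_boundary("left", lambda P: np.abs(P[:, 0]) < tol)
    mesh.tag_boundary("right", lambda P: np.abs(P[:, 0] - L) < tol)
    mesh.tag_boundary("bottom", lambda P: np.abs(P[:, 1] - sy[0]) < tol)
    mesh.tag_boundary("top", lambda P: np.abs(P[:, 1] - ytop) < tol)
    # corners belong to left/right first: drop duplicates from top/bottom
    _dedup_tags(mesh, order=("left", "right", "bottom", "top"))
    mesh.check_boundary_tagged()
    return mesh


def _dedup_tags(mesh: SimplexMesh, order):
    seen = set()
    for name in order:
        fs = mesh.tags[name]
        keep = []
        for idx, (c, lf) in enumerate(zip(fs.cells, fs.lfaces)):
            key = (int(c), int(lf))
            if key not in seen:
                seen.add(key)
                keep.append(idx)
        keep = np.array(keep, dtype=int)
        mesh.tags[name] = FacetSetSlice(fs, keep)


def FacetSetSlice(fs, idx):
    from .fem.mesh import FacetSet
    return FacetSet(fs.name, fs.cells[idx], fs.lfaces[idx],
                    fs.normal[idx], fs.measure[idx])
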