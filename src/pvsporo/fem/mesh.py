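"""Simplicial two-domain meshes with P2 geometry nodes and facet tagging.

A :class:`SimplexMesh` stores straight-sided triangles (2D) or tetrahedra
(3D), a domain label per cell (1 = fluid-filled PVS/SAS, 2 = parenchyma),
tagged boundary facet sets, the shared interface facet pairs, and the
node/DOF bookkeeping needed by the solver:

* P2 nodes: mesh vertices followed by edge midpoints (displacement and
  velocity fields);
* P1 pressure DOFs duplicated per domain, so the pore pressure may jump
  across the PVS-parenchyma interface as the phase-split traction conditions
  allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .reference import edge_list, facet_vertices, quadrature

__all__ = ["FacetSet", "InterfacePairs", "SimplexMesh"]


@dataclass
class FacetSet:
    """A set of mesh facets attached to owning cells.

    ``normal`` is the outward unit normal of the owning cell in the
    *reference* configuration; ``measure`` the facet area (3D) or length (2D).
    """

    name: str
    cells: np.ndarray      # (nf,) owning cell ids
    lfaces: np.ndarray     # (nf,) local face index within the owning cell
    normal: np.ndarray = field(default=None)   # (nf, d)
    measure: np.ndarray = field(default=None)  # (nf,)

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class InterfacePairs:
    """Conforming facet pairs on the domain-1/domain-2 interface.

    ``side1`` facets are owned by domain-1 cells, ``side2`` by domain-2
    cells; entry i of both sides is the same geometric facet.  ``normal2``
    is outward from domain 2 (pointing into the fluid-filled spaces) and is
    the common normal used in the phase-split traction terms.
    """

    side1: FacetSet
    side2: FacetSet

    @property
    def normal2(self) -> np.ndarray:
        return self.side2.normal

    def __len__(self) -> int:
        return len(self.side1)


def _facet_key(verts: np.ndarray) -> tuple:
    return tuple(sorted(int(v) for v in verts))


class SimplexMesh:
    """Straight-sided simplex mesh with two-domain bookkeeping."""

    def __init__(self, X: np.ndarray, cells: np.ndarray,
                 domain: np.ndarray | None = None,
                 metadata: dict | None = None):
        self.X1 = np.ascontiguousarray(X, dtype=float)
        self.cells = np.ascontiguousarray(cells, dtype=np.int64)
        self.dim = self.X1.shape[1]
        self.nv = self.cells.shape[1]
        if self.nv != self.dim + 1:
            raise ValueError("cells must be simplices")
        self.n_cells = len(self.cells)
        if domain is None:
            domain = np.ones(self.n_cells, dtype=np.int64)
        self.domain = np.asarray(domain, dtype=np.int64)
        self.metadata = dict(metadata or {})
        self.tags: dict[str, FacetSet] = {}
        self.interface: InterfacePairs | None = None
        self._build_geometry()
        self._build_p2()
        self._build_pressure_dofs()
        self._facet_table = self._build_facet_table()
        self._tree: cKDTree | None = None

    # ------------------------------------------------------------------
    # geometry

    def _build_geometry(self):
        V = self.X1[self.cells]                      # (nc, d+1, d)
        d = self.dim
        import math
        A = np.concatenate([np.ones((self.n_cells, d + 1, 1)), V], axis=2)
        det = np.linalg.det(A)
        self.cell_measure = np.abs(det) / math.factorial(d)
        if np.any(self.cell_measure <= 0):
            raise ValueError("degenerate cell(s) in mesh")
        Ainv = np.linalg.inv(A)                      # (nc, d+1, d+1)
        # grad lambda_a = rows 1..d of column a of A^{-1}
        self.grad_lam = np.swapaxes(Ainv[:, 1:, :], 1, 2)  # (nc, d+1, d)

    def _build_p2(self):
        edges = edge_list(self.dim)
        pairs = np.vstack([
            np.sort(self.cells[:, [a, b]], axis=1) for a, b in edges
        ])  # (n_edges_per_cell * nc, 2), cell-major blocks
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        n1 = len(self.X1)
        mid = 0.5 * (self.X1[uniq[:, 0]] + self.X1[uniq[:, 1]])
        self.X2 = np.vstack([self.X1, mid])
        ne = len(edges)
        edge_ids = inv.reshape(ne, self.n_cells).T + n1   # (nc, ne)
        self.cells2 = np.hstack([self.cells, edge_ids])
        self.n1 = n1
        self.n2 = len(self.X2)

    def _build_pressure_dofs(self):
        """P1 pressure DOFs, duplicated per domain across the interface."""
        self.pcells = np.empty_like(self.cells)
        offset = 0
        self._pdof_maps = {}
        for a in (1, 2):
            mask = self.domain == a
            if not np.any(mask):
                continue
            verts = np.unique(self.cells[mask])
            vmap = -np.ones(self.n1, dtype=np.int64)
            vmap[verts] = offset + np.arange(len(verts))
            self.pcells[mask] = vmap[self.cells[mask]]
            self._pdof_maps[a] = (verts, vmap)
            offset += len(verts)
        self.n_pdofs = offset

    def pressure_coords(self) -> np.ndarray:
        """Reference coordinates of every pressure DOF."""
        out = np.empty((self.n_pdofs, self.dim))
        for a, (verts, vmap) in self._pdof_maps.items():
            out[vmap[verts]] = self.X1[verts]
        return out

    def _build_facet_table(self):
        fv = facet_vertices(self.dim)
        table: dict[tuple, list[tuple[int, int]]] = {}
        for c in range(self.n_cells):
            for lf, idx in enumerate(fv):
                key = _facet_key(self.cells[c, list(idx)])
                table.setdefault(key, []).append((c, lf))
        return table

    # ------------------------------------------------------------------
    # facet sets

    def _facet_geometry(self, cells: np.ndarray, lfaces: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Outward reference normals and measures for (cell, lface) pairs."""
        fv = facet_vertices(self.dim)
        d = self.dim
        nf = len(cells)
        normal = np.empty((nf, d))
        measure = np.empty(nf)
        for i, (c, lf) in enumerate(zip(cells, lfaces)):
            vids = self.cells[c, list(fv[lf])]
            P = self.X1[vids]
            if d == 2:
                t = P[1] - P[0]
                measure[i] = np.linalg.norm(t)
                n = np.array([t[1], -t[0]]) / measure[i]
            else:
                e1, e2 = P[1] - P[0], P[2] - P[0]
                n = np.cross(e1, e2)
                a2 = np.linalg.norm(n)
                measure[i] = 0.5 * a2
                n = n / a2
            # orient outward from the owning cell
            cc = self.X1[self.cells[c]].mean(axis=0)
            if np.dot(n, P.mean(axis=0) - cc) < 0:
                n = -n
            normal[i] = n
        return normal, measure

    def _make_facet_set(self, name, pairs) -> FacetSet:
        cells = np.array([p[0] for p in pairs], dtype=np.int64)
        lfaces = np.array([p[1] for p in pairs], dtype=np.int64)
        normal, measure = self._facet_geometry(cells, lfaces)
        return FacetSet(name, cells, lfaces, normal, measure)

    def boundary_facets(self) -> list[tuple[tuple, tuple[int, int]]]:
        return [(k, v[0]) for k, v in self._facet_table.items()
                if len(v) == 1]

    def tag_boundary(self, name: str, predicate) -> FacetSet:
        """Tag boundary facets whose vertex coordinates all satisfy
        ``predicate(X) -> bool array``."""
        pairs = []
        for key, (c, lf) in self.boundary_facets():
            P = self.X1[list(key)]
            if np.all(predicate(P)):
                pairs.append((c, lf))
        fs = self._make_facet_set(name, pairs)
        self.tags[name] = fs
        return fs

    def check_boundary_tagged(self):
        """Every boundary facet must carry exactly one tag."""
        seen: dict[tuple[int, int], list[str]] = {}
        for name, fs in self.tags.items():
            for c, lf in zip(fs.cells, fs.lfaces):
                seen.setdefault((int(c), int(lf)), []).append(name)
        problems = []
        for key, (c, lf) in self.boundary_facets():
            tags = seen.get((c, lf), [])
            if len(tags) != 1:
                problems.append((key, tags))
        if problems:
            raise ValueError(
                f"{len(problems)} boundary facets without a unique tag; "
                f"first: {problems[0]}")

    def build_interface(self) -> InterfacePairs | None:
        pairs1, pairs2 = [], []
        for key, owners in self._facet_table.items():
            if len(owners) == 2:
                (c1, f1), (c2, f2) = owners
                d1, d2 = self.domain[c1], self.domain[c2]
                if d1 == d2:
                    continue
                if d1 == 2:
                    (c1, f1), (c2, f2) = (c2, f2), (c1, f1)
                pairs1.append((c1, f1))
                pairs2.append((c2, f2))
        if not pairs1:
            self.interface = None
            return None
        self.interface = InterfacePairs(
            self._make_facet_set("interface:1", pairs1),
            self._make_facet_set("interface:2", pairs2))
        return self.interface

    def interface_nodes(self) -> np.ndarray:
        """P2 node ids lying on the interface (sorted, unique)."""
        if self.interface is None:
            return np.array([], dtype=np.int64)
        nodes = []
        for c, lf, in zip(self.interface.side1.cells,
                          self.interface.side1.lfaces):
            nodes.append(self.facet_nodes2(c, lf))
        return np.unique(np.concatenate(nodes))

    def facet_nodes2(self, cell: int, lface: int) -> np.ndarray:
        """P2 node ids on facet ``lface`` of ``cell``."""
        fv = facet_vertices(self.dim)[lface]
        verts = list(fv)
        nv = self.dim + 1
        enodes = []
        for e, (a, b) in enumerate(edge_list(self.dim)):
            if a in fv and b in fv:
                enodes.append(nv + e)
        return self.cells2[cell, verts + enodes]

    def internal_plane(self, name: str, axis: int, value: float,
                       domain: int = 1, tol: float = 1e-9) -> FacetSet:
        """Facets of ``domain`` cells lying on the plane axis = value,
        oriented with outward normal in the +axis direction."""
        pairs = []
        for key, owners in self._facet_table.items():
            P = self.X1[list(key)]
            if not np.all(np.abs(P[:, axis] - value) < tol):
                continue
            for c, lf in owners:
                if self.domain[c] != domain:
                    continue
                cc = self.X1[self.cells[c]].mean(axis=0)
                if cc[axis] < value:      # owning cell below the plane
                    pairs.append((c, lf))
                    break
            else:
                # plane on the bottom boundary: take any owning cell
                for c, lf in owners:
                    if self.domain[c] == domain:
                        pairs.append((c, lf))
                        break
        fs = self._make_facet_set(name, pairs)
        # force orientation +axis
        flip = fs.normal[:, axis] < 0
        fs.normal[flip] *= -1.0
        self.tags[name] = fs
        return fs

    # ------------------------------------------------------------------
    # evaluation helpers

    def facet_quad_barycentric(self, lface: int, degree: int
                               ) -> tuple[np.ndarray, np.ndarray]:
        """Facet quadrature expressed in the owning cell's barycentric
        coordinates: (lam (nq, d+1), w (nq,))."""
        mu, w = quadrature(self.dim - 1, degree)
        fv = facet_vertices(self.dim)[lface]
        lam = np.zeros((len(w), self.dim + 1))
        for j, v in enumerate(fv):
            lam[:, v] = mu[:, j]
        return lam, w

    def barycentric(self, cell_ids: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Barycentric coordinates of points X within given cells."""
        V = self.X1[self.cells[cell_ids, 0]]
        G = self.grad_lam[cell_ids]            # (n, d+1, d)
        # lambda_a(X) = lambda_a(V0) + grad(lambda_a).(X - V0), lambda(V0)=e0
        lam = np.einsum("nad,nd->na", G, X - V)
        lam[:, 0] += 1.0
        return lam

    def _vertex_cell_adjacency(self):
        """cells touching each vertex (list of arrays)."""
        if not hasattr(self, "_v2c"):
            v2c = [[] for _ in range(self.n1)]
            for c, verts in enumerate(self.cells):
                for v in verts:
                    v2c[v].append(c)
            self._v2c = [np.array(c, dtype=np.int64) for c in v2c]
        return self._v2c

    def cell_neighbors(self, cell: int) -> np.ndarray:
        """Cells sharing at least one vertex with ``cell`` (incl. itself)."""
        v2c = self._vertex_cell_adjacency()
        return np.unique(np.concatenate(
            [v2c[v] for v in self.cells[cell]]))

    def locate(self, X: np.ndarray, guess: np.ndarray | None = None,
               k: int = 40, tol: float = 1e-9) -> np.ndarray:
        """Cell id containing each point (or -1 if outside the mesh).

        Strategy: test the guess cell, then its vertex neighbourhood, then
        the k nearest cell centroids.  A small negative barycentric
        tolerance absorbs round-off on faces.
        """
        X = np.atleast_2d(X)
        if self._tree is None:
            centroids = self.X1[self.cells].mean(axis=1)
            self._tree = cKDTree(centroids)
        out = np.full(len(X), -1, dtype=np.int64)
        todo = np.arange(len(X))
        if guess is not None:
            lam = self.barycentric(guess, X)
            ok = np.all(lam >= -tol, axis=1)
            out[ok] = guess[ok]
            todo = np.where(~ok)[0]
            # vertex-neighbourhood pass (particles move <1 cell per step)
            still = []
            for i in todo:
                nb = self.cell_neighbors(int(guess[i]))
                lam = self.barycentric(nb, np.repeat(X[i][None], len(nb), 0))
                hit = np.where(np.all(lam >= -tol, axis=1))[0]
                if len(hit):
                    out[i] = nb[hit[0]]
                else:
                    still.append(i)
            todo = np.array(still, dtype=np.int64)
        if len(todo):
            kk = min(k, self.n_cells)
            _, cand = self._tree.query(X[todo], k=kk)
            cand = np.atleast_2d(cand)
            for j in range(kk):
                rem = out[todo] < 0
                if not np.any(rem):
                    break
                idx = todo[rem]
                cells = cand[rem, j]
                lam = self.barycentric(cells, X[idx])
                ok = np.all(lam >= -tol, axis=1)
                out[idx[ok]] = cells[ok]
        return out

    # ------------------------------------------------------------------
    # quality / summary

    def quality_min_ratio(self) -> float:
        """Min over cells of (inradius / circumradius-proxy): a standard
        shape measure; degenerate cells approach zero."""
        V = self.X1[self.cells]
        d = self.dim
        # edge lengths
        from itertools import combinations
        lens = []
        for a, b in combinations(range(d + 1), 2):
            lens.append(np.linalg.norm(V[:, a] - V[:, b], axis=1))
        hmax = np.max(lens, axis=0)
        # rho ~ d * measure / surface-ish; use measure / hmax^d as proxy
        q = self.cell_measure / hmax**d
        q0 = 1.0 / (2.0 if d == 2 else 6.0 * np.sqrt(2))  # equilateral-ish
        return float(np.min(q) / q0)

    def summary(self) -> dict:
        return {
            "dim": self.dim,
            "cells": self.n_cells,
            "vertices": self.n1,
            "p2_nodes": self.n2,
            "pressure_dofs": self.n_pdofs,
            "domains": {int(a): int((self.domain == a).sum())
                        for a in np.unique(self.domain)},
            "tags": {k: len(v) for k, v in self.tags.items()},
            "interface_facets": 0 if self.interface is None
            else len(self.interface),
            **self.metadata,
        }
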