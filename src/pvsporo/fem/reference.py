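"""Reference simplex elements: Lagrange P1/P2 bases and quadrature.

Bases are expressed in barycentric coordinates, which makes the code
dimension-generic (triangles and tetrahedra).  Quadrature points are stored
as barycentric coordinates with weights summing to one, so that

    integral over cell  =  cell_measure * sum_q w_q f(lambda_q).

Local node ordering: the d+1 vertices first, then one node per edge in the
order given by :func:`edge_list`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["edge_list", "n_basis", "eval_basis", "quadrature",
           "facet_vertices"]


def edge_list(d: int) -> list[tuple[int, int]]:
    """Local vertex pairs carrying the P2 edge nodes."""
    if d == 2:
        return [(0, 1), (0, 2), (1, 2)]
    if d == 3:
        return [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    raise ValueError("d must be 2 or 3")


def facet_vertices(d: int) -> list[tuple[int, ...]]:
    """Local vertex tuples of facet f (the facet opposite vertex f)."""
    if d == 2:
        return [(1, 2), (0, 2), (0, 1)]
    if d == 3:
        return [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]
    raise ValueError("d must be 2 or 3")


def n_basis(d: int, order: int) -> int:
    if order == 1:
        return d + 1
    if order == 2:
        return d + 1 + len(edge_list(d))
    raise ValueError("order must be 1 or 2")


def eval_basis(lam: np.ndarray, d: int, order: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate basis functions at barycentric points.

    Parameters
    ----------
    lam : (nq, d+1) barycentric coordinates.

    Returns
    -------
    phi : (nq, nb) values.
    dphi : (nq, nb, d+1) derivatives with respect to the barycentric
        coordinates; contract with grad(lambda) for physical gradients.
    """
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    nq = lam.shape[0]
    nv = d + 1
    if order == 1:
        phi = lam.copy()
        dphi = np.tile(np.eye(nv), (nq, 1, 1))
        return phi, dphi
    edges = edge_list(d)
    nb = nv + len(edges)
    phi = np.empty((nq, nb))
    dphi = np.zeros((nq, nb, nv))
    for a in range(nv):
        la = lam[:, a]
        phi[:, a] = la * (2.0 * la - 1.0)
        dphi[:, a, a] = 4.0 * la - 1.0
    for e, (a, b) in enumerate(edges):
        phi[:, nv + e] = 4.0 * lam[:, a] * lam[:, b]
        dphi[:, nv + e, a] = 4.0 * lam[:, b]
        dphi[:, nv + e, b] = 4.0 * lam[:, a]
    return phi, dphi


# ----------------------------------------------------------------------------
# Quadrature rules (barycentric points, weights summing to 1)

def _perm_all(vals: tuple[float, ...]) -> np.ndarray:
    """All distinct permutations of a barycentric coordinate tuple."""
    from itertools import permutations
    return np.array(sorted(set(permutations(vals))), dtype=float)


_TRI_RULES = {}
_TRI_RULES[1] = (np.array([[1 / 3, 1 / 3, 1 / 3]]), np.array([1.0]))
_TRI_RULES[2] = (_perm_all((2 / 3, 1 / 6, 1 / 6)), np.full(3, 1 / 3))
# Dunavant degree-4, 6 points
_a1, _a2 = 0.445948490915965, 0.091576213509771
_w1, _w2 = 0.223381589678011, 0.109951743655322
_TRI_RULES[4] = (
    np.vstack([_perm_all((1 - 2 * _a1, _a1, _a1)),
               _perm_all((1 - 2 * _a2, _a2, _a2))]),
    np.concatenate([np.full(3, _w1), np.full(3, _w2)]),
)
# Dunavant degree-5, 7 points
_b1, _b2 = 0.470142064105115, 0.101286507323456
_v1, _v2 = 0.132394152788506, 0.125939180544827
_TRI_RULES[5] = (
    np.vstack([np.array([[1 / 3, 1 / 3, 1 / 3]]),
               _perm_all((1 - 2 * _b1, _b1, _b1)),
               _perm_all((1 - 2 * _b2, _b2, _b2))]),
    np.concatenate([[0.225], np.full(3, _v1), np.full(3, _v2)]),
)

_TET_RULES = {}
_TET_RULES[1] = (np.array([[0.25, 0.25, 0.25, 0.25]]), np.array([1.0]))
_c = 0.138196601125010515
_TET_RULES[2] = (_perm_all((1 - 3 * _c, _c, _c, _c)), np.full(4, 0.25))
# Keast degree-4, 11 points (one negative weight; standard rule)
_k1 = 0.0714285714285714285
_k2 = 0.100596423833200668
_TET_RULES[4] = (
    np.vstack([np.array([[0.25, 0.25, 0.25, 0.25]]),
               _perm_all((1 - 3 * _k1, _k1, _k1, _k1)),
               _perm_all((0.5 - _k2, 0.5 - _k2, _k2, _k2))]),
    np.concatenate([[-0.0789333333333333333],
                    np.full(4, 0.0457333333333333333),
                    np.full(6, 0.1493333333333333333)]),
)

# Gauss-Legendre on [0,1] as barycentric (1-t, t) pairs for 2D edges
_gl3 = (np.array([0.5 - np.sqrt(15) / 10, 0.5, 0.5 + np.sqrt(15) / 10]),
        np.array([5 / 18, 8 / 18, 5 / 18]))
_EDGE_RULES = {
    2: (np.array([[0.5 + np.sqrt(3) / 6, 0.5 - np.sqrt(3) / 6],
                  [0.5 - np.sqrt(3) / 6, 0.5 + np.sqrt(3) / 6]]),
        np.array([0.5, 0.5])),
    5: (np.column_stack([1 - _gl3[0], _gl3[0]]), _gl3[1]),
}


def quadrature(d: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature rule on the d-simplex exact to (at least) ``degree``.

    Returns (lam (nq, d+1), w (nq,)) with weights summing to one.
    """
    if d == 1:
        rules = _EDGE_RULES
    elif d == 2:
        rules = _TRI_RULES
    elif d == 3:
        rules = _TET_RULES
    else:
        raise ValueError("d must be 1, 2 or 3")
    for deg in sorted(rules):
        if deg >= degree:
            return rules[deg]
    return rules[max(rules)]
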