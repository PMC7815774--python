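"""Independent brute-force oracle for the beam FE kernel.

Element stiffness is derived by numerical (Gauss) integration of the
Euler-Bernoulli strain energy with linear axial/torsion and cubic Hermite
bending shape functions — a derivation path independent of the hand-coded
closed-form matrix in the package.  Assembly is dense; constraints are
enforced through a dense KKT solve with numpy.
"""

from __future__ import annotations

import numpy as np

_GAUSS_X = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_W = np.array([1.0, 1.0])


def _hermite_dd(xi: float, L: float) -> np.ndarray:
    """Second derivatives of the four Hermite shape functions at
    xi in [-1, 1] (w.r.t. the physical coordinate)."""
    # x = L (xi + 1) / 2 ;  d2/dx2 = (2/L)^2 d2/dxi2
    h = np.array(
        [
            1.5 * xi,  # N1 = 1/4 (2 - 3 xi + xi^3)
            L / 2.0 * (1.5 * xi - 0.5) / 1.0,  # N2 = L/8 (1 - xi - xi^2 + xi^3)
            -1.5 * xi,  # N3
            L / 2.0 * (1.5 * xi + 0.5) / 1.0,  # N4 = L/8 (-1 - xi + xi^2 + xi^3)
        ]
    )
    return h * (2.0 / L) ** 2


def _bend_block(EI: float, L: float) -> np.ndarray:
    k = np.zeros((4, 4))
    for xi, w in zip(_GAUSS_X, _GAUSS_W):
        B = _hermite_dd(xi, L)
        k += w * np.outer(B, B)
    return EI * k * (L / 2.0)


def oracle_local_stiffness(L, E, G, A, Iy, Iz, J) -> np.ndarray:
    """12x12 local stiffness by numerical integration."""
    k = np.zeros((12, 12))
    # axial (linear shape functions, 1-point rule is exact)
    ka = E * A / L
    for i, j, v in ((0, 0, ka), (0, 6, -ka), (6, 0, -ka), (6, 6, ka)):
        k[i, j] += v
    kt = G * J / L
    for i, j, v in ((3, 3, kt), (3, 9, -kt), (9, 3, -kt), (9, 9, kt)):
        k[i, j] += v
    # bending about z: dofs (uy1, rz1, uy2, rz2)
    kb = _bend_block(E * Iz, L)
    dz = [1, 5, 7, 11]
    for a in range(4):
        for b in range(4):
            k[dz[a], dz[b]] += kb[a, b]
    # bending about y: dofs (uz1, ry1, uz2, ry2) with ry = -dw/dx
    kb = _bend_block(E * Iy, L)
    S = np.diag([1.0, -1.0, 1.0, -1.0])
    kb = S @ kb @ S
    dy = [2, 4, 8, 10]
    for a in range(4):
        for b in range(4):
            k[dy[a], dy[b]] += kb[a, b]
    return k


def oracle_frame(p1, p2, ref=None) -> np.ndarray:
    d = np.asarray(p2, float) - np.asarray(p1, float)
    x = d / np.linalg.norm(d)
    if ref is None:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(x @ ref) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
    y = ref - (ref @ x) * x
    y = y / np.linalg.norm(y)
    return np.vstack([x, y, np.cross(x, y)])


def oracle_solve(nodes, beams, fixed, loads):
    """Dense direct solve of a space frame.

    nodes: (n, 3); beams: list of (a, b, E, G, A, Iy, Iz, J);
    fixed: list of (node, dof); loads: dict node -> 6-vector.
    Returns (n, 6) displacements.
    """
    nodes = np.asarray(nodes, float)
    n = len(nodes)
    K = np.zeros((6 * n, 6 * n))
    for a, b, E, G, A, Iy, Iz, J in beams:
        L = np.linalg.norm(nodes[b] - nodes[a])
        kl = oracle_local_stiffness(L, E, G, A, Iy, Iz, J)
        R = oracle_frame(nodes[a], nodes[b])
        T = np.kron(np.eye(4), R)
        kg = T.T @ kl @ T
        dofs = np.r_[6 * a : 6 * a + 6, 6 * b : 6 * b + 6]
        K[np.ix_(dofs, dofs)] += kg
    F = np.zeros(6 * n)
    for node, f in loads.items():
        F[6 * node : 6 * node + 6] += np.asarray(f, float)
    C = np.zeros((len(fixed), 6 * n))
    for r, (node, dof) in enumerate(fixed):
        C[r, 6 * node + dof] = 1.0
    kkt = np.block([[K, C.T], [C, np.zeros((len(fixed), len(fixed)))]])
    rhs = np.concatenate([F, np.zeros(len(fixed))])
    x = np.linalg.solve(kkt, rhs)
    return x[: 6 * n].reshape(n, 6)
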