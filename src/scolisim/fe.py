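"""Small-displacement 3D beam finite-element kernel.

Euler-Bernoulli two-node space-frame elements (12 DOF), rigid bodies by
exact master-slave kinematic condensation, translation-only kinematic
couplings and prescribed displacements as multipoint constraints enforced
with Lagrange multipliers, and a direct sparse symmetric-indefinite solve
of the resulting KKT system.  DOF order per node: ux, uy, uz, rx, ry, rz.

Units: mm, N, MPa (N/mm^2), so moments are N*mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Material",
    "BeamSection",
    "FEModel",
    "SolutionState",
    "SingularModelError",
    "solve",
    "outer_fiber_stress",
]


@dataclass(frozen=True)
class Material:
    """Linear elastic isotropic material (E in MPa)."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("elastic modulus must be positive")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (-1, 0.5)")

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass(frozen=True)
class BeamSection:
    """Cross-section constants: area (mm^2), bending second moments about
    the local y and z axes (mm^4), torsion constant (mm^4) and the outer
    fiber radius (mm) used for stress recovery."""

    area: float
    Iy: float
    Iz: float
    J: float
    outer_radius: float

    def __post_init__(self) -> None:
        for name in ("area", "Iy", "Iz", "J", "outer_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"section {name} must be positive")

    @classmethod
    def circular(cls, diameter: float) -> "BeamSection":
        r = diameter / 2.0
        I = np.pi * r**4 / 4.0
        return cls(area=np.pi * r**2, Iy=I, Iz=I, J=2.0 * I, outer_radius=r)

    @classmethod
    def elliptical(cls, a: float, b: float) -> "BeamSection":
        """Ellipse with semi-axis ``a`` along local y and ``b`` along local z."""
        return cls(
            area=np.pi * a * b,
            Iy=np.pi * a * b**3 / 4.0,  # integral of z^2 dA
            Iz=np.pi * a**3 * b / 4.0,
            J=np.pi * a**3 * b**3 / (a**2 + b**2),
            outer_radius=max(a, b),
        )


def _skew(r: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -r[2], r[1]], [r[2], 0.0, -r[0]], [-r[1], r[0], 0.0]])


def beam_stiffness_local(L, E, G, A, Iy, Iz, J) -> np.ndarray:
    """Batched 12x12 Euler-Bernoulli space-frame stiffness (local frame,
    x along the element)."""
    L, E, G, A, Iy, Iz, J = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(v, float)) for v in (L, E, G, A, Iy, Iz, J))
    )
    m = L.shape[0]
    k = np.zeros((m, 12, 12))
    ax = E * A / L
    to = G * J / L
    for i, j, v in ((0, 0, ax), (0, 6, -ax), (6, 6, ax), (3, 3, to), (3, 9, -to), (9, 9, to)):
        k[:, i, j] = v
    # bending in the x-y plane (about z, uses Iz): dofs uy(1,7), rz(5,11)
    b1, b2 = 12 * E * Iz / L**3, 6 * E * Iz / L**2
    b3, b4 = 4 * E * Iz / L, 2 * E * Iz / L
    for i, j, v in (
        (1, 1, b1), (1, 7, -b1), (7, 7, b1),
        (1, 5, b2), (1, 11, b2), (5, 7, -b2), (7, 11, -b2),
        (5, 5, b3), (11, 11, b3), (5, 11, b4),
    ):
        k[:, i, j] = v
    # bending in the x-z plane (about y, uses Iy): dofs uz(2,8), ry(4,10)
    c1, c2 = 12 * E * Iy / L**3, 6 * E * Iy / L**2
    c3, c4 = 4 * E * Iy / L, 2 * E * Iy / L
    for i, j, v in (
        (2, 2, c1), (2, 8, -c1), (8, 8, c1),
        (2, 4, -c2), (2, 10, -c2), (4, 8, c2), (8, 10, c2),
        (4, 4, c3), (10, 10, c3), (4, 10, c4),
    ):
        k[:, i, j] = v
    iu = np.triu_indices(12, 1)
    k[:, iu[1], iu[0]] = k[:, iu[0], iu[1]]
    return k


def element_frame(p1, p2, ref=None) -> np.ndarray:
    """3x3 frame with rows = local x, y, z axes in global components."""
    d = np.asarray(p2, float) - np.asarray(p1, float)
    L = np.linalg.norm(d)
    if L < 1e-9:
        raise ValueError("zero-length element")
    x = d / L
    if ref is None:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(x @ ref) > 0.99:
            ref = np.array([0.0, 1.0, 0.0])
    ref = np.asarray(ref, float)
    y = ref - (ref @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("degenerate reference axis for element frame")
    y = y / ny
    return np.vstack([x, y, np.cross(x, y)])


@dataclass
class _Beam:
    a: int
    b: int
    material: Material
    section: BeamSection
    ref: np.ndarray | None


class FEModel:
    """Beam-element system with rigid bodies, couplings and constraints."""

    def __init__(self) -> None:
        self._pos: list[np.ndarray] = []
        self.beams: list[_Beam] = []
        self.master_of: dict[int, int] = {}  # slave -> master
        self.couplings: list[tuple[int, int]] = []
        self.fixed: list[tuple[int, int]] = []  # (node, dof)
        self.prescribed: list[tuple[int, int, float]] = []  # (node, dof, value)
        # general MPC rows: (list of (node, dof, coeff), rhs)
        self.general: list[tuple[list[tuple[int, int, float]], float]] = []

    # -- construction ------------------------------------------------------
    def add_node(self, position) -> int:
        self._pos.append(np.asarray(position, float))
        return len(self._pos) - 1

    @property
    def n_nodes(self) -> int:
        return len(self._pos)

    @property
    def positions(self) -> np.ndarray:
        return np.array(self._pos)

    def add_beam(self, a: int, b: int, material: Material, section: BeamSection, ref=None) -> int:
        if np.linalg.norm(self._pos[b] - self._pos[a]) < 1e-9:
            raise ValueError("zero-length beam element")
        self.beams.append(
            _Beam(a, b, material, section, None if ref is None else np.asarray(ref, float))
        )
        return len(self.beams) - 1

    def add_rigid_body(self, master: int, slaves) -> None:
        for s in slaves:
            if s in self.master_of:
                raise ValueError(f"node {s} already belongs to a rigid body")
            if s == master:
                raise ValueError("master cannot be its own slave")
            self.master_of[s] = master

    def add_coupling(self, a: int, b: int) -> int:
        """Tie the three translations of node ``a`` to node ``b``
        (rotations stay free)."""
        for n in (a, b):
            if not 0 <= n < self.n_nodes:
                raise ValueError(f"coupling endpoint {n} does not exist")
        self.couplings.append((a, b))
        return len(self.couplings) - 1

    def fix(self, node: int, dofs=range(6)) -> None:
        for d in dofs:
            self.fixed.append((node, int(d)))

    def prescribe(self, node: int, dof: int, value: float) -> None:
        self.prescribed.append((node, int(dof), float(value)))

    def add_linear_constraint(self, entries, rhs: float = 0.0) -> None:
        """General multipoint constraint: sum(coeff * u[node, dof]) = rhs.

        The caller is responsible for supplying linearly independent rows.
        """
        self.general.append(([(int(n), int(d), float(c)) for n, d, c in entries], float(rhs)))

    # -- condensation helpers ---------------------------------------------
    def owner(self, node: int) -> int:
        return self.master_of.get(node, node)

    def node_block(self, node: int) -> tuple[int, np.ndarray]:
        """(owner, 6x6 B) with u_node = B @ u_owner."""
        m = self.owner(node)
        B = np.eye(6)
        if m != node:
            r = self._pos[node] - self._pos[m]
            B[:3, 3:] = -_skew(r)
        return m, B


@dataclass
class SolutionState:
    """Solved displacements, reactions, element end forces and coupling
    forces for one linear static analysis."""

    model: FEModel
    displacements: np.ndarray  # (n_nodes, 6), slaves expanded
    element_forces: np.ndarray  # (n_beams, 12), local end forces
    element_frames: np.ndarray  # (n_beams, 3, 3)
    element_k_local: np.ndarray  # (n_beams, 12, 12)
    element_u_local: np.ndarray  # (n_beams, 12)
    coupling_forces: np.ndarray  # (n_couplings, 3), force exerted on node b
    reactions: list[tuple[int, int, float]]  # (node, dof, value)
    residual: float
    general_multipliers: np.ndarray | None = None  # one per general MPC row
    _kuf: np.ndarray | None = None  # K u - F on reduced DOFs
    _node_dofs: np.ndarray | None = None

    def constraint_wrench(self, node: int) -> np.ndarray:
        """Total constraint force/moment delivered to a (non-slave) node's
        six DOFs, equal to -C^T lambda restricted to that node."""
        return self._kuf[self._node_dofs[node]]

    def element_strain_energy(self) -> np.ndarray:
        """Per-element elastic energy (N*mm)."""
        return 0.5 * np.einsum(
            "ei,eij,ej->e", self.element_u_local, self.element_k_local, self.element_u_local
        )

    def total_reaction(self) -> np.ndarray:
        """Sum of reaction forces (translational components) over supports."""
        out = np.zeros(3)
        for _, dof, val in self.reactions:
            if dof < 3:
                out[dof] += val
        return out


class SingularModelError(RuntimeError):
    """The constrained system is singular (under-constrained model)."""


def _assemble(model: FEModel):
    """Reduced stiffness, constraint matrix and bookkeeping (vectorized)."""
    n = model.n_nodes
    pos = np.array(model._pos) if n else np.zeros((0, 3))
    owners = np.arange(n)
    B = np.broadcast_to(np.eye(6), (n, 6, 6)).copy()
    for s, m in model.master_of.items():
        owners[s] = m
        r = pos[s] - pos[m]
        # translation block of the rigid link: u_s = u_m - [r]x theta_m
        B[s, 0, 4] = r[2]
        B[s, 0, 5] = -r[1]
        B[s, 1, 3] = -r[2]
        B[s, 1, 5] = r[0]
        B[s, 2, 3] = r[1]
        B[s, 2, 4] = -r[0]
    base = np.full(n, -1, dtype=int)
    slot = 0
    for node in range(n):
        if node not in model.master_of:
            base[node] = 6 * slot
            slot += 1
    nred = 6 * slot
    node_dofs = base[owners][:, None] + np.arange(6)[None, :]  # (n, 6)

    def owner_dofs(node: int):
        return node_dofs[node], B[node]

    m_el = len(model.beams)
    if m_el:
        ea = np.fromiter((bm.a for bm in model.beams), dtype=int, count=m_el)
        eb = np.fromiter((bm.b for bm in model.beams), dtype=int, count=m_el)
        props = np.array(
            [
                (
                    bm.material.E,
                    bm.material.G,
                    bm.section.area,
                    bm.section.Iy,
                    bm.section.Iz,
                    bm.section.J,
                )
                for bm in model.beams
            ]
        )
        d = pos[eb] - pos[ea]
        L = np.sqrt((d * d).sum(axis=1))
        if np.any(L < 1e-9):
            raise ValueError("zero-length beam element")
        x = d / L[:, None]
        ref = np.zeros((m_el, 3))
        has_ref = np.zeros(m_el, dtype=bool)
        for e, bm in enumerate(model.beams):
            if bm.ref is not None:
                has_ref[e] = True
                ref[e] = bm.ref
        default_x = ~has_ref & (np.abs(x[:, 0]) <= 0.99)
        ref[default_x] = (1.0, 0.0, 0.0)
        ref[~has_ref & ~default_x] = (0.0, 1.0, 0.0)
        y = ref - (ref * x).sum(axis=1)[:, None] * x
        ny = np.sqrt((y * y).sum(axis=1))
        if np.any(ny < 1e-9):
            raise ValueError("degenerate reference axis for element frame")
        y = y / ny[:, None]
        z = np.cross(x, y)
        frames = np.stack([x, y, z], axis=1)  # rows = local axes
        k_loc = beam_stiffness_local(L, *props.T)
        T = np.zeros((m_el, 12, 12))
        for blk in range(4):
            T[:, 3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = frames
        k_glob = np.matmul(np.matmul(T.transpose(0, 2, 1), k_loc), T)
        Gm = np.zeros((m_el, 12, 12))
        Gm[:, :6, :6] = B[ea]
        Gm[:, 6:, 6:] = B[eb]
        kr = np.matmul(np.matmul(Gm.transpose(0, 2, 1), k_glob), Gm)
        elem_dofs = np.concatenate([node_dofs[ea], node_dofs[eb]], axis=1)
        k_rows = np.repeat(elem_dofs, 12, axis=1).ravel()
        k_cols = np.tile(elem_dofs, (1, 12)).ravel()
        k_vals = kr.reshape(m_el, -1).ravel()
        K = sp.coo_matrix((k_vals, (k_rows, k_cols)), shape=(nred, nred)).tocsr()
    else:
        k_loc = np.zeros((0, 12, 12))
        T = np.zeros((0, 12, 12))
        elem_dofs = np.zeros((0, 12), dtype=int)
        Gm = np.zeros((0, 12, 12))
        K = sp.csr_matrix((nred, nred))

    ncoup = len(model.couplings)
    coupling_rows = list(range(0, 3 * ncoup, 3))
    if ncoup:
        ca = np.fromiter((c[0] for c in model.couplings), dtype=int, count=ncoup)
        cb = np.fromiter((c[1] for c in model.couplings), dtype=int, count=ncoup)
        rowidx = np.broadcast_to(
            (3 * np.arange(ncoup))[:, None, None] + np.arange(3)[None, :, None],
            (ncoup, 3, 6),
        )
        crows = [rowidx.ravel(), rowidx.ravel()]
        ccols = [
            np.broadcast_to(node_dofs[ca][:, None, :], (ncoup, 3, 6)).ravel(),
            np.broadcast_to(node_dofs[cb][:, None, :], (ncoup, 3, 6)).ravel(),
        ]
        cvals = [B[ca][:, :3, :].ravel(), -B[cb][:, :3, :].ravel()]
    else:
        crows, ccols, cvals = [], [], []
    ncon = 3 * ncoup
    d_rhs = [np.zeros(3 * ncoup)]
    constraint_meta = []
    extra_rows, extra_cols, extra_vals, extra_d = [], [], [], []
    for node, dof, value in [(nd, df, 0.0) for nd, df in model.fixed] + model.prescribed:
        constraint_meta.append((node, dof, ncon))
        Bn = B[node]
        nz = np.nonzero(Bn[dof])[0]
        extra_rows.extend([ncon] * len(nz))
        extra_cols.extend(node_dofs[node][nz])
        extra_vals.extend(Bn[dof, nz])
        extra_d.append(value)
        ncon += 1
    general_rows = []
    for entries, rhs in model.general:
        general_rows.append(ncon)
        for node, dof, coeff in entries:
            Bn = B[node]
            nz = np.nonzero(Bn[dof])[0]
            extra_rows.extend([ncon] * len(nz))
            extra_cols.extend(node_dofs[node][nz])
            extra_vals.extend(coeff * Bn[dof, nz])
        extra_d.append(rhs)
        ncon += 1
    if extra_rows:
        crows.append(np.array(extra_rows))
        ccols.append(np.array(extra_cols))
        cvals.append(np.array(extra_vals))
        d_rhs.append(np.array(extra_d))
    if crows:
        C = sp.coo_matrix(
            (np.concatenate(cvals), (np.concatenate(crows), np.concatenate(ccols))),
            shape=(ncon, nred),
        ).tocsr()
    else:
        C = sp.csr_matrix((ncon, nred))
    return {
        "nred": nred,
        "K": K,
        "C": C,
        "d": np.concatenate(d_rhs) if d_rhs else np.zeros(0),
        "k_loc": k_loc,
        "T": T,
        "elem_dofs": elem_dofs,
        "elem_G": Gm,
        "coupling_rows": coupling_rows,
        "constraint_meta": constraint_meta,
        "general_rows": general_rows,
        "owner_dofs": owner_dofs,
        "B": B,
        "node_dofs": node_dofs,
    }


def solve(model: FEModel, loads: dict[int, np.ndarray] | None = None) -> SolutionState:
    """Linear static solve under nodal loads (6-vectors per node).

    Loads applied at slave nodes are transferred to their rigid-body
    master (force + moment).  Raises :class:`SingularModelError` when the
    system is not constrained against rigid-body motion.
    """
    asm = _assemble(model)
    nred = asm["nred"]
    F = np.zeros(nred)
    if loads:
        for node, f in loads.items():
            dofs, B = asm["owner_dofs"](node)
            F[dofs] += B.T @ np.asarray(f, float)
    # scale the constraint rows to the stiffness magnitude so the KKT
    # system is well-conditioned and the multipliers are accurate
    scale = max(1.0, float(asm["K"].diagonal().max())) if nred else 1.0
    KKT = sp.bmat(
        [[asm["K"], scale * asm["C"].T], [scale * asm["C"], None]], format="csc"
    )
    rhs = np.concatenate([F, scale * asm["d"]])
    # symmetric (Jacobi-style) equilibration keeps the factorization
    # well-conditioned despite the mixed translation/rotation scales
    colmax = np.maximum(np.abs(KKT).max(axis=0).toarray().ravel(), 1e-30)
    S = sp.diags(1.0 / np.sqrt(colmax))
    KKT = (S @ KKT @ S).tocsc()
    rhs_s = S @ rhs
    try:
        lu = spla.splu(KKT)
        x = lu.solve(rhs_s)
        # iterative refinement with the residual evaluated in extended
        # precision recovers full double-precision forward accuracy, so
        # the equilibrium sums hold to the stated tolerances even for
        # heavily loaded, poorly conditioned constructs
        KKT_ld = KKT.astype(np.longdouble)
        rhs_ld = rhs_s.astype(np.longdouble)
        for _ in range(6):
            r = np.asarray(rhs_ld - KKT_ld @ x.astype(np.longdouble), dtype=float)
            dx = lu.solve(r)
            x = x + dx
            if np.linalg.norm(dx) <= 1e-14 * (np.linalg.norm(x) + 1.0):
                break
        x = S @ x  # undo the equilibration
    except RuntimeError as exc:  # exactly singular factorization
        raise SingularModelError(f"singular system: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SingularModelError("singular system: non-finite solution")
    resid = np.linalg.norm(KKT @ (x / S.diagonal()) - rhs_s) / (1.0 + np.linalg.norm(rhs_s))
    if resid > 1e-6:
        raise SingularModelError(f"ill-conditioned system: residual {resid:.2e}")
    u, lam = x[:nred], scale * x[nred:]

    disp = np.matmul(asm["B"], u[asm["node_dofs"]][..., None])[..., 0]
    m_el = len(model.beams)
    if m_el:
        u_elem = np.matmul(asm["elem_G"], u[asm["elem_dofs"]][..., None])[..., 0]
        u_local = np.matmul(asm["T"], u_elem[..., None])[..., 0]
        f_local = np.matmul(asm["k_loc"], u_local[..., None])[..., 0]
    else:
        u_local = np.zeros((0, 12))
        f_local = np.zeros((0, 12))
    coupling_forces = (
        lam[: 3 * len(model.couplings)].reshape(-1, 3)
        if model.couplings
        else np.zeros((0, 3))
    )
    reactions = [
        (node, dof, float(-lam[row])) for node, dof, row in asm["constraint_meta"]
    ]
    general_multipliers = np.array([lam[r] for r in asm["general_rows"]])
    kuf = asm["K"] @ u - F  # = -C^T lambda: constraint force on the structure
    return SolutionState(
        model=model,
        displacements=disp,
        element_forces=f_local,
        element_frames=asm["T"][:, :3, :3] if m_el else np.zeros((0, 3, 3)),
        element_k_local=asm["k_loc"],
        element_u_local=u_local,
        coupling_forces=coupling_forces,
        reactions=reactions,
        residual=float(resid),
        general_multipliers=general_multipliers,
        _kuf=kuf,
        _node_dofs=asm["node_dofs"],
    )


def outer_fiber_stress(
    end_forces: np.ndarray, section: BeamSection, von_mises: bool = False
) -> np.ndarray:
    """Outer-fiber stress (MPa) at both element ends.

    Combined normal stress sigma = |N|/A + sqrt(My^2 + Mz^2) * r / I; with
    ``von_mises=True`` the torsional shear tau = |T| * r / J is folded in
    as sqrt(sigma^2 + 3 tau^2).
    """
    f = np.asarray(end_forces, float)
    single = f.ndim == 1
    f = np.atleast_2d(f)
    out = np.empty(f.shape[:-1] + (2,))
    for e, sl in enumerate((slice(0, 6), slice(6, 12))):
        fe = f[..., sl]
        normal = (
            np.abs(fe[..., 0]) / section.area
            + np.hypot(fe[..., 4], fe[..., 5]) * section.outer_radius / section.Iy
        )
        if von_mises:
            tau = np.abs(fe[..., 3]) * section.outer_radius / section.J
            out[..., e] = np.sqrt(normal**2 + 3.0 * tau**2)
        else:
            out[..., e] = normal
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Spine + instrumentation model construction
# ---------------------------------------------------------------------------

#: Intervertebral disc bulk behaviour (MPa) and titanium rod properties.
DISC_MATERIAL = Material(E=6.0, nu=0.45)
ROD_MATERIAL = Material(E=110000.0, nu=0.3)
ROD_DIAMETER = 5.5  # mm


def disc_section(upper_v, lower_v) -> BeamSection:
    """Elliptical disc section from the mean of the adjacent endplate
    half-axes (local y = lateral half-width, local z = AP half-depth)."""
    a = 0.5 * (upper_v.half_width + lower_v.half_width)
    b = 0.5 * (upper_v.half_depth + lower_v.half_depth)
    return BeamSection.elliptical(a, b)


@dataclass
class SpineModelIndex:
    """Node/element bookkeeping for a spine + instrumentation model."""

    master: list[int]
    ped: dict[tuple[int, str], int]  # (vertebra index, side) -> node
    ep_sup: list[int]
    ep_inf: list[int]
    disc_elems: list[int]
    disc_sections: list[BeamSection]
    rod_nodes: dict[str, list[int]]
    rod_elems: dict[str, list[int]]
    rod_section: BeamSection | None
    uiv_idx: int | None
    liv_idx: int | None
    couplings: list[tuple[int, int, str, int]]  # (coupling id, level idx, side, poly idx)
    spin_pins: list[tuple[str, int, np.ndarray, int]] = None  # (side, node, axis, general row order)

    def rod_polyline_level(self, side: str, poly_idx: int, apex_idx: int) -> int:
        """Instrumented level owning a rod polyline node; midpoint nodes
        belong to the nearer of the two flanking levels, ties toward the
        apex."""
        base = self.uiv_idx + poly_idx // 2
        if poly_idx % 2 == 0:
            return base
        lo, hi = base, base + 1
        return lo if abs(lo - apex_idx) <= abs(hi - apex_idx) else hi


def build_model(
    geometry,
    plan=None,
    disc_material: Material = DISC_MATERIAL,
    rod_material: Material = ROD_MATERIAL,
    rod_diameter: float = ROD_DIAMETER,
    fix_sacrum: bool = True,
) -> FEModel:
    """FE model of a spine: one rigid body per vertebra (master at the body
    center; pedicle and endplate-center slaves), one disc beam per adjacent
    pair, the sacrum fixed; plus contoured bilateral rods and screw-rod
    couplings when an instrumentation plan is given.

    The resulting model carries a :class:`SpineModelIndex` as ``.index``.
    """
    model = FEModel()
    n = len(geometry.vertebrae)
    master, ep_sup, ep_inf = [], [], []
    ped: dict[tuple[int, str], int] = {}
    for i, v in enumerate(geometry.vertebrae):
        m = model.add_node(v.center)
        pl = model.add_node(v.ped_left)
        pr = model.add_node(v.ped_right)
        es = model.add_node(v.ep_sup)
        ei = model.add_node(v.ep_inf)
        model.add_rigid_body(m, [pl, pr, es, ei])
        master.append(m)
        ped[(i, "left")] = pl
        ped[(i, "right")] = pr
        ep_sup.append(es)
        ep_inf.append(ei)
    disc_elems, disc_sections = [], []
    for i in range(n - 1):
        vu, vl = geometry.vertebrae[i], geometry.vertebrae[i + 1]
        sec = disc_section(vu, vl)
        ref = vu.rotation.as_matrix()[:, 1]  # lateral axis of the upper vertebra
        try:
            e = model.add_beam(ep_inf[i], ep_sup[i + 1], disc_material, sec, ref=ref)
        except ValueError as exc:
            raise ValueError(f"disc {vu.level}-{vl.level}: {exc}") from exc
        disc_elems.append(e)
        disc_sections.append(sec)
    if fix_sacrum:
        model.fix(master[-1])  # sacrum/pelvis rigid body fully fixed

    rod_nodes: dict[str, list[int]] = {}
    rod_elems: dict[str, list[int]] = {}
    couplings = []
    spin_pins: list[tuple[str, int, np.ndarray, int]] = []
    rod_section = None
    uiv_idx = liv_idx = None
    if plan is not None:
        if plan.rod_left is None or plan.rod_right is None:
            raise ValueError("plan has no rod contours; attach with with_contours()")
        from .geometry import level_index as _li

        uiv_idx, liv_idx = _li(plan.uiv), _li(plan.liv)
        rod_section = BeamSection.circular(rod_diameter)
        for side, poly in (("left", plan.rod_left), ("right", plan.rod_right)):
            ids = [model.add_node(p) for p in poly]
            els = [
                model.add_beam(ids[j], ids[j + 1], rod_material, rod_section)
                for j in range(len(ids) - 1)
            ]
            rod_nodes[side] = ids
            rod_elems[side] = els
        pos_all = model.positions
        for pl_ in plan.placements:
            li = _li(pl_.level)
            pnode = ped[(li, pl_.side)]
            poly = pos_all[rod_nodes[pl_.side]]
            dist = np.linalg.norm(poly - pos_all[pnode], axis=1)
            j = int(np.argmin(dist))  # ties resolve to the cranial node
            cid = model.add_coupling(pnode, rod_nodes[pl_.side][j])
            couplings.append((cid, li, pl_.side, j))
        # A rod whose coupling points are (near-)collinear has a spin mode
        # about that line which translation-only couplings can resist only
        # through a sub-millimetre lever arm — numerically near-singular
        # and physically beyond what a polyaxial screw head transmits.
        # Pin the spin at one coupled node; the pin couple is recorded and
        # belongs to the rod free-body budget (it is exactly zero for a
        # truly collinear set, e.g. a two-coupling rod).
        for side in ("left", "right"):
            pts = np.array(
                sorted({tuple(pos_all[rod_nodes[side][pj]]) for _c, _l, s_, pj in couplings if s_ == side})
            )
            axis = pts[-1] - pts[0]
            axis = axis / np.linalg.norm(axis)
            offsets = pts - pts[0]
            lateral = offsets - np.outer(offsets @ axis, axis)
            if np.max(np.linalg.norm(lateral, axis=1)) < 1.0:  # mm
                node = next(
                    rod_nodes[side][pj] for _c, _l, s_, pj in couplings if s_ == side
                )
                spin_pins.append((side, node, axis.copy(), len(model.general)))
                model.add_linear_constraint(
                    [(node, 3 + d, axis[d]) for d in range(3) if axis[d] != 0.0]
                )

    model.index = SpineModelIndex(
        master=master,
        ped=ped,
        ep_sup=ep_sup,
        ep_inf=ep_inf,
        disc_elems=disc_elems,
        disc_sections=disc_sections,
        rod_nodes=rod_nodes,
        rod_elems=rod_elems,
        rod_section=rod_section,
        uiv_idx=uiv_idx,
        liv_idx=liv_idx,
        couplings=couplings,
        spin_pins=spin_pins,
    )
    return model


def dump_model(model: FEModel, path) -> None:
    """Debug dump: delimited node / element / constraint tables.

    Columns: ``node id x y z master`` / ``beam id a b E A Iy Iz J`` /
    ``constraint kind a b dof value``.
    """
    lines = ["node\tid\tx\ty\tz\tmaster"]
    for i, p in enumerate(model.positions):
        lines.append(
            f"node\t{i}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{model.master_of.get(i, '')}"
        )
    lines.append("beam\tid\ta\tb\tE\tA\tIy\tIz\tJ")
    for e, bm in enumerate(model.beams):
        lines.append(
            f"beam\t{e}\t{bm.a}\t{bm.b}\t{bm.material.E}\t{bm.section.area:.4f}"
            f"\t{bm.section.Iy:.4f}\t{bm.section.Iz:.4f}\t{bm.section.J:.4f}"
        )
    lines.append("constraint\tkind\ta\tb\tdof\tvalue")
    for a, b in model.couplings:
        lines.append(f"constraint\tcoupling\t{a}\t{b}\t\t")
    for nd, df in model.fixed:
        lines.append(f"constraint\tfixed\t{nd}\t\t{df}\t0.0")
    for nd, df, val in model.prescribed:
        lines.append(f"constraint\tprescribed\t{nd}\t\t{df}\t{val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
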