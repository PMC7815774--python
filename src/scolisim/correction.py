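"""Two-step simulation of posterior deformity correction.

Step 1 imposes the correction: the screw-bearing pedicle nodes are
displaced so that they coincide with their positions in the target
configuration, while all other vertebrae equilibrate through the discs
(the sacrum stays fixed).  Disc prestress for the pre-operative -> target
motion is evaluated with a finite-rotation deformation measure (relative
translation plus axis-angle relative rotation in the corotated element
frame), so a rigid motion of both vertebrae produces exactly zero force;
the held state is then obtained from one linear solve about the target
configuration with the prestress applied as release loads and the held
pedicle translations prescribed.

Step 2 releases the holding boundary conditions onto contoured bilateral
rods engaged through translation-only kinematic couplings (polyaxial
screw heads before locking): the held-state internal forces load the
coupled spine + rod system, again linearized about the target
configuration.  The elastic energy imposed in step 1 thereby determines
the strains and stresses in the instrumentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import fe, metrics, planning
from .fe import DISC_MATERIAL, ROD_DIAMETER, ROD_MATERIAL, Material
from .geometry import LEVELS, SpineGeometry, VertebraLandmarks, level_index

logger = logging.getLogger(__name__)

__all__ = [
    "DiscPrestress",
    "HeldState",
    "SimulationResult",
    "disc_prestress",
    "step1_deform",
    "step2_springback",
    "simulate_correction",
    "apply_springback",
]


# ---------------------------------------------------------------------------
# Disc prestress (pre-op -> target, finite-rotation measure)
# ---------------------------------------------------------------------------


@dataclass
class DiscPrestress:
    """Disc internal forces for the full pre-op -> target motion."""

    f_local: np.ndarray  # (17, 12) end forces in the corotated element frame
    frames: np.ndarray  # (17, 3, 3) corotated frames (rows = axes)
    frames0: np.ndarray  # (17, 3, 3) pre-operative element frames (rows = axes)
    g_global: np.ndarray  # (17, 2, 6) end forces in global coordinates
    energies: np.ndarray  # (17,) prestress elastic energy per disc, N*mm
    lengths: np.ndarray  # (17,) pre-operative disc lengths, mm
    k_aa_inv: np.ndarray  # (17, 6, 6) inverse of the cranial-end stiffness block
    disc_material: Material

    @property
    def energy_total(self) -> float:
        return float(self.energies.sum())


def _disc_kinematics(geometry: SpineGeometry, target: SpineGeometry, i: int):
    """Finite-rotation deformation of disc i (between vertebrae i, i+1)."""
    va, vb = geometry.vertebrae[i], geometry.vertebrae[i + 1]
    ta, tb = target.vertebrae[i], target.vertebrae[i + 1]
    p_a, p_b = va.ep_inf, vb.ep_sup
    F0 = fe.element_frame(p_a, p_b, ref=va.rotation.as_matrix()[:, 1])
    L0 = float(np.linalg.norm(p_b - p_a))
    Ra = ta.rotation.as_matrix() @ va.rotation.as_matrix().T
    Rb = tb.rotation.as_matrix() @ vb.rotation.as_matrix().T
    Fa = F0 @ Ra.T  # corotated element frame (rows = axes)
    d_loc = Fa @ (tb.ep_sup - ta.ep_inf) - np.array([L0, 0.0, 0.0])
    R_rel = Fa @ Rb @ F0.T
    phi = Rotation.from_matrix(R_rel).as_rotvec()
    return F0, Fa, L0, d_loc, phi


def disc_prestress(
    geometry: SpineGeometry,
    target_geometry: SpineGeometry,
    disc_material: Material = DISC_MATERIAL,
) -> DiscPrestress:
    """Evaluate every disc's internal force for the pre-op -> target
    relative motion of the adjacent vertebral frames."""
    n_disc = len(LEVELS) - 1
    f_local = np.zeros((n_disc, 12))
    frames = np.zeros((n_disc, 3, 3))
    frames0 = np.zeros((n_disc, 3, 3))
    g_global = np.zeros((n_disc, 2, 6))
    energies = np.zeros(n_disc)
    lengths = np.zeros(n_disc)
    k_aa_inv = np.zeros((n_disc, 6, 6))
    for i in range(n_disc):
        F0, Fa, L0, d_loc, phi = _disc_kinematics(geometry, target_geometry, i)
        sec = fe.disc_section(geometry.vertebrae[i], geometry.vertebrae[i + 1])
        k = fe.beam_stiffness_local(
            L0, disc_material.E, disc_material.G, sec.area, sec.Iy, sec.Iz, sec.J
        )[0]
        u = np.zeros(12)
        u[6:9] = d_loc
        u[9:12] = phi
        f = k @ u
        f_local[i] = f
        frames[i] = Fa
        frames0[i] = F0
        lengths[i] = L0
        k_aa_inv[i] = np.linalg.inv(k[:6, :6])
        energies[i] = 0.5 * u @ k @ u
        g_global[i, 0] = np.concatenate([Fa.T @ f[0:3], Fa.T @ f[3:6]])
        g_global[i, 1] = np.concatenate([Fa.T @ f[6:9], Fa.T @ f[9:12]])
    return DiscPrestress(
        f_local=f_local,
        frames=frames,
        frames0=frames0,
        g_global=g_global,
        energies=energies,
        lengths=lengths,
        k_aa_inv=k_aa_inv,
        disc_material=disc_material,
    )


# ---------------------------------------------------------------------------
# Step 1: held state
# ---------------------------------------------------------------------------


@dataclass
class HeldState:
    """Spine held by the screw-bearing pedicles at the target positions:
    disc internal force set and holding reactions."""

    loads: dict[tuple[int, str], np.ndarray]  # (vertebra idx, endplate attr) -> 6-vec
    reactions: dict[str, np.ndarray]  # level -> holding wrench at the body center
    energies: np.ndarray  # (17,) held-state elastic energy per disc
    master_disp: np.ndarray  # (18, 6) held-state motion of the vertebra masters
    f_inc: np.ndarray  # (17, 12) step-1 disc force increments, local frames
    disc_material: Material
    prestress: DiscPrestress

    @property
    def energy_total(self) -> float:
        return float(self.energies.sum())


def _held_pedicles(plan: planning.InstrumentationPlan | None):
    if plan is None:  # hold every pedicle of every vertebra
        return [(i, side) for i in range(len(LEVELS)) for side in ("left", "right")]
    return [(level_index(p.level), p.side) for p in plan.placements]


def step1_deform(
    geometry: SpineGeometry,
    target_geometry: SpineGeometry,
    plan: planning.InstrumentationPlan | None = None,
    disc_material: Material = DISC_MATERIAL,
    prestress: DiscPrestress | None = None,
) -> HeldState:
    """Displace the screw-bearing pedicle nodes to their target positions
    (all pedicles when no plan is given) and equilibrate the rest of the
    spine against the disc prestress."""
    if prestress is None:
        prestress = disc_prestress(geometry, target_geometry, disc_material)
    # The correction maneuver is self-contained: the spine + construct is
    # positioned by the held pedicles alone, so the pelvis is left free in
    # step 1 (the analysis is then invariant to where the target
    # configuration sits relative to the pelvis).
    model = fe.build_model(target_geometry, None, disc_material=disc_material, fix_sacrum=False)
    idx = model.index
    loads0: dict[int, np.ndarray] = {}
    for i in range(len(LEVELS) - 1):
        a, b = idx.ep_inf[i], idx.ep_sup[i + 1]
        loads0[a] = loads0.get(a, np.zeros(6)) - prestress.g_global[i, 0]
        loads0[b] = loads0.get(b, np.zeros(6)) - prestress.g_global[i, 1]
    # Irredundant holding constraints per vertebra: one held pedicle gives
    # its three translations; two held pedicles give the midpoint
    # translations plus the two rotation components perpendicular to the
    # pedicle-pedicle axis (spin about that axis stays free, as for real
    # point anchors).  The fully fixed sacrum needs no extra rows.
    by_vert: dict[int, list[str]] = {}
    for li, side in _held_pedicles(plan):
        by_vert.setdefault(li, []).append(side)
    held_levels: list[int] = []
    for li, sides in sorted(by_vert.items()):
        held_levels.append(li)
        pl, pr = idx.ped[(li, "left")], idx.ped[(li, "right")]
        if len(sides) == 1:
            node = pl if sides[0] == "left" else pr
            for dof in range(3):
                model.add_linear_constraint([(node, dof, 1.0)])
        else:
            for dof in range(3):
                model.add_linear_constraint([(pl, dof, 0.5), (pr, dof, 0.5)])
            v = target_geometry.vertebrae[li]
            axis = v.ped_left - v.ped_right
            axis = axis / np.linalg.norm(axis)
            b1 = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(b1) < 1e-6:
                b1 = np.cross(axis, [0.0, 0.0, 1.0])
            b1 /= np.linalg.norm(b1)
            b2 = np.cross(axis, b1)
            for b in (b1, b2):
                model.add_linear_constraint(
                    [(pl, dof, b[dof]) for dof in range(3) if b[dof] != 0.0]
                    + [(pr, dof, -b[dof]) for dof in range(3) if b[dof] != 0.0]
                )
    solution = fe.solve(model, loads0)

    # held-state internal forces: prestress + linear increment
    n_disc = len(LEVELS) - 1
    inc = solution.element_forces[idx.disc_elems]  # local model frames
    frames = solution.element_frames[idx.disc_elems]
    loads: dict[tuple[int, str], np.ndarray] = {}
    for i in range(n_disc):
        T3 = frames[i]
        g_a = prestress.g_global[i, 0] + np.concatenate([T3.T @ inc[i, 0:3], T3.T @ inc[i, 3:6]])
        g_b = prestress.g_global[i, 1] + np.concatenate([T3.T @ inc[i, 6:9], T3.T @ inc[i, 9:12]])
        loads[(i, "ep_inf")] = -g_a
        loads[(i + 1, "ep_sup")] = loads.get((i + 1, "ep_sup"), np.zeros(6)) - g_b
    # held-state energy per disc: prestress + cross term + increment
    e_inc = solution.element_strain_energy()[idx.disc_elems]
    energies = prestress.energies.copy()
    for i in range(n_disc):
        u_a = solution.displacements[idx.ep_inf[i]]
        u_b = solution.displacements[idx.ep_sup[i + 1]]
        energies[i] += (
            float(prestress.g_global[i, 0] @ u_a)
            + float(prestress.g_global[i, 1] @ u_b)
            + float(e_inc[i])
        )
    reactions = {
        LEVELS[li]: solution.constraint_wrench(idx.master[li]).copy()
        for li in held_levels
    }
    return HeldState(
        loads=loads,
        reactions=reactions,
        energies=energies,
        master_disp=solution.displacements[idx.master],
        f_inc=inc.copy(),
        disc_material=disc_material,
        prestress=prestress,
    )


# ---------------------------------------------------------------------------
# Step 2: spring-back onto the rods
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Outcome metrics of one (subject, target, plan) simulation."""

    max_rod_stress: float  # MPa
    stress_offset: int  # vertebra offset of the maximum from the apex (- = cranial)
    max_screw_force: float  # N
    force_offset: int
    residual_cobb: float  # deg, re-measured after spring-back
    residual_rotation: float  # deg
    achieved_d_tk: float  # deg, post-op TK minus pre-op TK
    achieved_d_ll: float
    feasible: bool = True
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feasible and (self.max_rod_stress < 0 or self.max_screw_force < 0):
            raise ValueError("stress and force magnitudes must be non-negative")


def step2_springback(
    held: HeldState,
    target_geometry: SpineGeometry,
    plan: planning.InstrumentationPlan,
    rod_material: Material = ROD_MATERIAL,
    rod_diameter: float = ROD_DIAMETER,
) -> tuple[fe.SolutionState, fe.FEModel]:
    """Release the holding constraints onto the coupled spine + rod system
    linearized about the target configuration."""
    model = fe.build_model(
        target_geometry,
        plan,
        disc_material=held.disc_material,
        rod_material=rod_material,
        rod_diameter=rod_diameter,
    )
    idx = model.index
    loads: dict[int, np.ndarray] = {}
    for (vi, attr), g in held.loads.items():
        node = idx.ep_inf[vi] if attr == "ep_inf" else idx.ep_sup[vi]
        loads[node] = loads.get(node, np.zeros(6)) + g
    solution = fe.solve(model, loads)
    return solution, model


def _rodrigues(v: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (exponential map)."""
    th = float(np.linalg.norm(v))
    K = np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]])
    if th < 1e-12:
        return np.eye(3) + K
    return np.eye(3) + np.sin(th) / th * K + (1.0 - np.cos(th)) / th**2 * (K @ K)


def _recon_cache(geometry: SpineGeometry):
    cached = getattr(geometry, "_recon_cache", None)
    if cached is None:
        R = np.array([v.rotation.as_matrix() for v in geometry.vertebrae])
        centers = geometry.centers
        off_sup = np.array([v.local_offset(v.ep_sup) for v in geometry.vertebrae])
        off_inf = np.array([v.local_offset(v.ep_inf) for v in geometry.vertebrae])
        cached = (R, centers, off_sup, off_inf)
        geometry._recon_cache = cached
    return cached


def _final_poses(
    geometry: SpineGeometry,
    prestress: DiscPrestress,
    f_inc1: np.ndarray,
    f_inc2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Post-operative vertebral poses reconstructed from the final disc
    internal forces.

    Each disc's final relative deformation (translation + rotation of its
    cranial end with the caudal end clamped) is recovered from its end
    forces through the element flexibility, and the vertebral chain is
    composed caudocranially with exact finite rotations, anchored at the
    pre-operative pelvis pose.  A fully relaxed disc thereby reproduces
    the pre-operative relative pose exactly, so accumulated linearization
    drift cannot push the measured deformity past its pre-operative value.
    """
    R_pre, centers_pre, off_sup, off_inf = _recon_cache(geometry)
    f_tot = prestress.f_local + f_inc1 + f_inc2
    u_a = np.einsum("dij,dj->di", prestress.k_aa_inv, f_tot[:, :6])
    n = len(LEVELS)
    R = np.empty((n, 3, 3))
    c = np.empty((n, 3))
    R[-1] = R_pre[-1]
    c[-1] = centers_pre[-1]
    for i in range(n - 2, -1, -1):
        W_b = R[i + 1] @ R_pre[i + 1].T
        Fb = prestress.frames0[i] @ W_b.T  # carried element frame (rows = axes)
        p_b = c[i + 1] + R[i + 1] @ off_sup[i + 1]
        local = np.array([-prestress.lengths[i], 0.0, 0.0]) + u_a[i, :3]
        p_a = p_b + Fb.T @ local
        R_a = _rodrigues(Fb.T @ u_a[i, 3:]) @ (W_b @ R_pre[i])
        c[i] = p_a - R_a @ off_inf[i]
        R[i] = R_a
    return c, R


def apply_springback(
    geometry: SpineGeometry,
    target_geometry: SpineGeometry,
    held: HeldState,
    solution: fe.SolutionState,
    model: fe.FEModel,
) -> SpineGeometry:
    """Post-operative geometry reconstructed from the final disc forces
    (see :func:`_final_poses`), anchored at the pre-operative pelvis."""
    idx = model.index
    inc2 = solution.element_forces[idx.disc_elems]
    c_new, R_new = _final_poses(geometry, held.prestress, held.f_inc, inc2)
    out = []
    for i, v in enumerate(geometry.vertebrae):
        R = Rotation.from_matrix(R_new[i])
        c = c_new[i]
        out.append(
            VertebraLandmarks(
                level=v.level,
                center=c,
                rotation=R,
                ped_left=c + R.apply(v.local_offset(v.ped_left)),
                ped_right=c + R.apply(v.local_offset(v.ped_right)),
                ep_sup=c + R.apply(v.local_offset(v.ep_sup)),
                ep_inf=c + R.apply(v.local_offset(v.ep_inf)),
                half_width=v.half_width,
                half_depth=v.half_depth,
            )
        )
    return SpineGeometry(out, geometry.pelvis_anchor, geometry.frame)


def _fast_residuals(
    geometry: SpineGeometry,
    prestress: DiscPrestress,
    f_inc1: np.ndarray,
    f_inc2: np.ndarray,
    major: metrics.CurveDescriptor,
) -> tuple[float, float, metrics.SagittalProfile]:
    """Residual Cobb/apical rotation and post-op sagittal profile from the
    sprung-back vertebral frames (same measurement conventions as the
    curve-metrics module, batched for the trial loop)."""
    _c, R_new = _final_poses(geometry, prestress, f_inc1, f_inc2)
    nrm = R_new[:, :, 2]
    alpha = np.degrees(np.arctan2(nrm[:, 1], nrm[:, 2]))
    iu, il = level_index(major.upper_end), level_index(major.lower_end)
    res_cobb = metrics._angle_between(alpha[iu], alpha[il])
    yax = R_new[level_index(major.apex), :, 1]
    res_rot = float(np.degrees(np.arctan2(-yax[0], yax[1])))
    beta = np.degrees(np.arctan2(nrm[:, 0], nrm[:, 2]))
    sag = metrics.SagittalProfile(
        tk=float(beta[level_index("T4")] - beta[level_index("T12")]),
        ll=float(beta[level_index("L5")] - beta[level_index("L1")]),
    )
    return float(res_cobb), res_rot, sag


def _energy_accounting(held: HeldState, solution: fe.SolutionState, model: fe.FEModel):
    """Imposed (held), residual-disc and rod elastic energies, consistent
    with the linearized spring-back functional."""
    idx = model.index
    energies = solution.element_strain_energy()
    e_rod = float(sum(energies[e] for side in idx.rod_elems for e in idx.rod_elems[side]))
    # cross term: held internal forces through the spring-back motion
    # (held.loads stores the *applied* release loads = minus the internal
    # forces, hence the sign flip)
    cross = 0.0
    for (vi, attr), g in held.loads.items():
        node = idx.ep_inf[vi] if attr == "ep_inf" else idx.ep_sup[vi]
        cross += float(np.dot(-g, solution.displacements[node]))
    d_disc = cross + float(sum(energies[e] for e in idx.disc_elems))
    return held.energy_total, held.energy_total + d_disc, e_rod


def _rod_coupling_forces(solution: fe.SolutionState, model: fe.FEModel) -> np.ndarray:
    """(n_couplings, 3) loads transmitted by the kinematic couplings,
    evaluated from the rod-side internal nodal forces (the force a coupled
    rod node receives from its adjacent rod elements)."""
    idx = model.index
    out = np.zeros((len(model.couplings), 3))
    for side, els in idx.rod_elems.items():
        if not els:
            continue
        frames = solution.element_frames[els]
        floc = solution.element_forces[els]
        # global end forces (as applied by the nodes to each element)
        g_a = np.einsum("eji,ej->ei", frames, floc[:, 0:3])
        g_b = np.einsum("eji,ej->ei", frames, floc[:, 6:9])
        nodal = np.zeros((len(idx.rod_nodes[side]), 3))
        for j in range(len(els)):
            nodal[j] += g_a[j]
            nodal[j + 1] += g_b[j]
        for cid, _li, cside, pj in idx.couplings:
            if cside == side:
                out[cid] = nodal[pj]
    return out


def _rod_equilibrium(solution: fe.SolutionState, model: fe.FEModel):
    """Force and moment residuals of each rod's free body under its
    coupling forces alone (N, N*mm)."""
    idx = model.index
    worst_f = worst_m = 0.0
    pos = model.positions
    cf = _rod_coupling_forces(solution, model)
    for side in idx.rod_nodes:
        pts, lams = [], []
        for cid, _li, cside, poly_j in idx.couplings:
            if cside != side:
                continue
            lams.append(cf[cid])
            pts.append(pos[idx.rod_nodes[side][poly_j]])
        if not lams:
            continue
        lams = np.array(lams)
        pts = np.array(pts)
        fsum = lams.sum(axis=0)
        # moments about the coupling centroid (equilibrium holds about any
        # point; the centroid avoids amplifying force round-off by a long
        # global lever arm); spin-pin couples are external actions on the
        # rod and belong to the budget
        msum = np.cross(pts - pts.mean(axis=0), lams).sum(axis=0)
        for pside, _node, axis, order in idx.spin_pins or ():
            if pside == side and solution.general_multipliers is not None:
                msum += -solution.general_multipliers[order] * axis
        worst_f = max(worst_f, float(np.max(np.abs(fsum))))
        worst_m = max(worst_m, float(np.max(np.abs(msum))))
    return worst_f, worst_m


def _select_max(candidates: list[tuple[float, int]]) -> tuple[float, int]:
    """(value, level offset) with the largest value; ties toward the apex
    (smallest |offset|, then cranial)."""
    return max(candidates, key=lambda c: (c[0], -abs(c[1]), -c[1]))


def simulate_correction(
    geometry: SpineGeometry,
    target: planning.TargetConfiguration,
    plan: planning.InstrumentationPlan,
    major: metrics.CurveDescriptor | None = None,
    rod_material: Material = ROD_MATERIAL,
    rod_diameter: float = ROD_DIAMETER,
    disc_material: Material = DISC_MATERIAL,
    von_mises: bool = False,
    target_geometry: SpineGeometry | None = None,
    prestress: DiscPrestress | None = None,
) -> SimulationResult:
    """Run target construction, step 1 and step 2 for one plan and extract
    the four outcome metrics plus residual deformity and diagnostics.

    ``target_geometry`` and ``prestress`` may be supplied to share work
    across the plans of one (subject, target) pair.
    """
    if major is None:
        curves = metrics.detect_curves(geometry)
        if not curves:
            raise ValueError("no scoliotic curve detected")
        major = max(curves, key=lambda c: c.cobb)
    apex_idx = level_index(major.apex)
    if target_geometry is None:
        target_geometry = planning.build_target_geometry(geometry, target)
    plan = plan.with_contours(target_geometry)
    held = step1_deform(geometry, target_geometry, plan, disc_material, prestress)
    solution, model = step2_springback(held, target_geometry, plan, rod_material, rod_diameter)
    idx = model.index

    stress_cands: list[tuple[float, int]] = []
    for side in idx.rod_elems:
        els = idx.rod_elems[side]
        if not els:
            continue
        sig = fe.outer_fiber_stress(
            solution.element_forces[els], idx.rod_section, von_mises=von_mises
        )
        for j, _e in enumerate(els):
            for end, poly_j in ((0, j), (1, j + 1)):
                lvl = idx.rod_polyline_level(side, poly_j, apex_idx)
                stress_cands.append((float(sig[j, end]), lvl - apex_idx))
    cf = _rod_coupling_forces(solution, model)
    force_cands: list[tuple[float, int]] = []
    for cid, li, _side, _poly in idx.couplings:
        force_cands.append((float(np.linalg.norm(cf[cid])), li - apex_idx))
    max_stress, stress_off = _select_max(stress_cands)
    max_force, force_off = _select_max(force_cands)

    res_cobb, res_rot, sag_post = _fast_residuals(
        geometry, held.prestress, held.f_inc, solution.element_forces[idx.disc_elems], major
    )
    sag_pre = metrics.measure_sagittal(geometry)

    e_imposed, e_disc_final, e_rod = _energy_accounting(held, solution, model)
    worst_f, worst_m = _rod_equilibrium(solution, model)
    applied = np.zeros(3)
    for _key, g in held.loads.items():
        applied += g[:3]
    reaction_resid = float(np.max(np.abs(applied + solution.total_reaction())))

    return SimulationResult(
        max_rod_stress=max_stress,
        stress_offset=int(stress_off),
        max_screw_force=max_force,
        force_offset=int(force_off),
        residual_cobb=float(res_cobb),
        residual_rotation=float(res_rot),
        achieved_d_tk=float(sag_post.tk - sag_pre.tk),
        achieved_d_ll=float(sag_post.ll - sag_pre.ll),
        diagnostics={
            "energy_imposed": e_imposed,
            "energy_disc_final": e_disc_final,
            "energy_rod": e_rod,
            "coupling_force_residual": worst_f,
            "coupling_moment_residual": worst_m,
            "reaction_residual": reaction_resid,
            "solver_residual": solution.residual,
        },
    )
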