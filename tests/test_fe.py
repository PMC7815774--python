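"""Beam FE kernel: closed-form solutions, patch test, rigid bodies,
couplings, and agreement with an independently derived dense oracle."""

import numpy as np
import pytest

from scolisim.fe import (
    BeamSection,
    FEModel,
    Material,
    SingularModelError,
    beam_stiffness_local,
    build_model,
    outer_fiber_stress,
    solve,
)

from _fe_oracle import oracle_local_stiffness, oracle_solve

STEEL = Material(E=200000.0, nu=0.3)
ROD = BeamSection.circular(10.0)


def _chain(n=5, length=100.0, section=ROD, material=STEEL):
    m = FEModel()
    ids = [m.add_node([i * length / (n - 1), 0.0, 0.0]) for i in range(n)]
    for i in range(n - 1):
        m.add_beam(ids[i], ids[i + 1], material, section)
    m.fix(ids[0])
    return m, ids


class TestClosedForms:
    def test_cantilever_tip_deflection(self):
        m, ids = _chain()
        P, L = 100.0, 100.0
        sol = solve(m, {ids[-1]: np.array([0, 0, -P, 0, 0, 0.0])})
        exact = P * L**3 / (3 * STEEL.E * ROD.Iy)
        assert sol.displacements[ids[-1], 2] == pytest.approx(-exact, rel=1e-6)

    def test_axial_bar_elongation(self):
        m, ids = _chain()
        P, L = 100.0, 100.0
        sol = solve(m, {ids[-1]: np.array([P, 0, 0, 0, 0, 0.0])})
        assert sol.displacements[ids[-1], 0] == pytest.approx(
            P * L / (STEEL.E * ROD.area), rel=1e-9
        )

    def test_torsion_twist(self):
        m, ids = _chain()
        T, L = 1000.0, 100.0
        sol = solve(m, {ids[-1]: np.array([0, 0, 0, T, 0, 0.0])})
        assert sol.displacements[ids[-1], 3] == pytest.approx(
            T * L / (STEEL.G * ROD.J), rel=1e-9
        )

    def test_patch_constant_curvature(self):
        """End moment on a three-element beam gives a constant bending
        moment along every element and the Euler-Bernoulli tip motion."""
        m, ids = _chain(n=4, length=99.0)
        M, L = 5000.0, 99.0
        sol = solve(m, {ids[-1]: np.array([0, 0, 0, 0, M, 0.0])})
        np.testing.assert_allclose(sol.element_forces[:, 4], -M, rtol=1e-9)
        np.testing.assert_allclose(sol.element_forces[:, 10], M, rtol=1e-9)
        EI = STEEL.E * ROD.Iy
        assert sol.displacements[ids[-1], 4] == pytest.approx(M * L / EI, rel=1e-9)
        assert sol.displacements[ids[-1], 2] == pytest.approx(
            -M * L**2 / (2 * EI), rel=1e-9
        )

    def test_equilibrium_of_reactions(self):
        m, ids = _chain()
        load = np.array([30.0, -20.0, 55.0, 0.0, 0.0, 0.0])
        sol = solve(m, {ids[-1]: load, ids[2]: load})
        np.testing.assert_allclose(sol.total_reaction(), -2 * load[:3], atol=1e-6)


class TestConstraints:
    def test_rigid_body_translation_is_strain_free(self):
        m = FEModel()
        c = m.add_node([0, 0, 0])
        s1 = m.add_node([10, 5, 0])
        s2 = m.add_node([-10, 5, 0])
        m.add_rigid_body(c, [s1, s2])
        g = m.add_node([0, -50, 0])
        m.add_beam(g, s1, STEEL, ROD)
        t = [1.0, 2.0, 3.0]
        for node in (c, g):
            for dof in range(6):
                m.prescribe(node, dof, t[dof] if dof < 3 else 0.0)
        sol = solve(m)
        assert np.max(np.abs(sol.element_forces)) < 1e-8

    def test_coupling_series_springs(self):
        """Axially coupled bars share load like springs in series."""
        m = FEModel()
        a0, a1 = m.add_node([0, 0, 0]), m.add_node([100.0, 0, 0])
        b0, b1 = m.add_node([100.0, 0, 1e-3]), m.add_node([200.0, 0, 1e-3])
        sA, sB = BeamSection.circular(8.0), BeamSection.circular(6.0)
        m.add_beam(a0, a1, STEEL, sA)
        m.add_beam(b0, b1, STEEL, sB)
        m.fix(a0)
        m.fix(b1)
        m.add_coupling(a1, b0)
        F = 500.0
        sol = solve(m, {a1: np.array([F, 0, 0, 0, 0, 0.0])})
        kA = STEEL.E * sA.area / 100.0
        kB = STEEL.E * sB.area / 100.0
        assert sol.displacements[a1, 0] == pytest.approx(F / (kA + kB), rel=1e-6)
        assert sol.coupling_forces[0][0] == pytest.approx(F * kB / (kA + kB), rel=1e-6)

    def test_under_constrained_model_raises(self):
        m = FEModel()
        a = m.add_node([0, 0, 0])
        b = m.add_node([100.0, 0, 0])
        m.add_beam(a, b, STEEL, ROD)
        with pytest.raises(SingularModelError):
            solve(m, {b: np.array([0, 0, -10.0, 0, 0, 0])})

    def test_zero_length_beam_rejected(self):
        m = FEModel()
        a = m.add_node([0, 0, 0])
        b = m.add_node([0, 0, 0])
        with pytest.raises(ValueError):
            m.add_beam(a, b, STEEL, ROD)


class TestOracleEquivalence:
    def test_local_stiffness_matches_integrated_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            L = rng.uniform(20, 300)
            E = rng.uniform(1e3, 2e5)
            G = E / 2.6
            A, Iy, Iz, J = rng.uniform(5, 500), rng.uniform(50, 5e4), rng.uniform(50, 5e4), rng.uniform(100, 1e5)
            k = beam_stiffness_local(L, E, G, A, Iy, Iz, J)[0]
            ko = oracle_local_stiffness(L, E, G, A, Iy, Iz, J)
            np.testing.assert_allclose(k, ko, rtol=1e-9, atol=1e-9 * np.abs(ko).max())

    def test_random_frames_match_dense_oracle(self):
        """50 random space frames vs brute-force dense assembly."""
        rng = np.random.default_rng(20)
        for trial in range(50):
            n = int(rng.integers(5, 15))
            nodes = rng.uniform(-200, 200, size=(n, 3))
            beams = []
            m = FEModel()
            for p in nodes:
                m.add_node(p)
            for b in range(1, n):
                a = int(rng.integers(0, b))
                if np.linalg.norm(nodes[b] - nodes[a]) < 1.0:
                    nodes[b] += 5.0
                E = float(rng.uniform(1e4, 2e5))
                sec = BeamSection.circular(float(rng.uniform(5, 20)))
                mat = Material(E=E, nu=0.3)
                m.add_beam(a, b, mat, sec)
                beams.append((a, b, E, mat.G, sec.area, sec.Iy, sec.Iz, sec.J))
            # a couple of extra bracing members
            for _ in range(2):
                a, b = rng.choice(n, size=2, replace=False)
                if np.linalg.norm(nodes[b] - nodes[a]) > 1.0:
                    mat = Material(E=1e5, nu=0.3)
                    sec = BeamSection.circular(8.0)
                    m.add_beam(int(a), int(b), mat, sec)
                    beams.append((int(a), int(b), 1e5, mat.G, sec.area, sec.Iy, sec.Iz, sec.J))
            m.fix(0)
            loads = {
                int(node): rng.uniform(-100, 100, size=6)
                for node in rng.choice(np.arange(1, n), size=min(3, n - 1), replace=False)
            }
            sol = solve(m, loads)
            ref = oracle_solve(nodes, beams, [(0, d) for d in range(6)], loads)
            scale = np.max(np.abs(ref)) + 1e-12
            assert np.max(np.abs(sol.displacements - ref)) / scale < 1e-8, f"frame {trial}"


class TestStressRecovery:
    def test_bending_closed_form(self):
        sec = BeamSection.circular(5.5)
        f = np.zeros(12)
        f[4] = 1000.0
        sigma = outer_fiber_stress(f, sec)
        assert sigma[0] == pytest.approx(32 * 1000.0 / (np.pi * 5.5**3), rel=1e-9)

    def test_axial_closed_form(self):
        sec = BeamSection.circular(5.5)
        f = np.zeros(12)
        f[0] = 100.0
        sigma = outer_fiber_stress(f, sec)
        assert sigma[0] == pytest.approx(100.0 / (np.pi * 5.5**2 / 4), rel=1e-9)
        assert sec.area == pytest.approx(23.758, abs=1e-3)

    def test_zero_forces_zero_stress(self):
        sec = BeamSection.circular(5.5)
        assert np.all(outer_fiber_stress(np.zeros(12), sec) == 0.0)

    def test_von_mises_includes_torsion(self):
        sec = BeamSection.circular(5.5)
        f = np.zeros(12)
        f[3] = 500.0  # pure torsion
        plain = outer_fiber_stress(f, sec)
        vm = outer_fiber_stress(f, sec, von_mises=True)
        assert plain[0] == 0.0
        tau = 500.0 * sec.outer_radius / sec.J
        assert vm[0] == pytest.approx(np.sqrt(3) * tau, rel=1e-9)


class TestSpineModel:
    def test_disc_count_without_plan(self, straight_spine):
        model = build_model(straight_spine)
        assert len(model.index.disc_elems) == 17
        assert len(model.beams) == 17

    def test_disc_material_applied(self, straight_spine):
        model = build_model(straight_spine)
        assert all(model.beams[e].material.E == 6.0 for e in model.index.disc_elems)
        assert all(model.beams[e].material.nu == 0.45 for e in model.index.disc_elems)

    def test_rod_section_area(self):
        sec = BeamSection.circular(5.5)
        assert sec.area == pytest.approx(np.pi * 5.5**2 / 4, rel=1e-12)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            Material(E=-1.0, nu=0.3)
        with pytest.raises(ValueError):
            Material(E=100.0, nu=0.6)
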