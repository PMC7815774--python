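"""Two-step correction: held state, spring-back, metrics, invariants."""

import numpy as np
import pytest

from scolisim import anatomy, correction, fe, metrics, planning
from scolisim.anatomy import CurveSpec, SpineSpec
from scolisim.fe import Material
from scolisim.geometry import SpineGeometry, VertebraLandmarks, mirror_geometry
from scolisim.metrics import CurveDescriptor
from scolisim.planning import TargetConfiguration, enumerate_plans


@pytest.fixture(scope="module")
def case(single_curve_case):
    spec, geom, major = single_curve_case
    target = TargetConfiguration(10.0, 10.0)
    tgt = planning.build_target_geometry(geom, target)
    plans = enumerate_plans(geom, major)
    return geom, major, target, tgt, plans


def _translated_copy(geometry, level, offset):
    verts = []
    for v in geometry.vertebrae:
        if v.level == level:
            verts.append(
                VertebraLandmarks(
                    v.level, v.center + offset, v.rotation,
                    v.ped_left + offset, v.ped_right + offset,
                    v.ep_sup + offset, v.ep_inf + offset,
                    v.half_width, v.half_depth,
                )
            )
        else:
            verts.append(v)
    return SpineGeometry(verts, geometry.pelvis_anchor)


class TestStep1:
    def test_no_deformation_no_forces(self, straight_spine):
        held = correction.step1_deform(straight_spine, straight_spine)
        assert held.energy_total == pytest.approx(0.0, abs=1e-12)
        assert max(np.abs(g).max() for g in held.loads.values()) < 1e-9
        assert all(np.abs(w).max() < 1e-9 for w in held.reactions.values())

    def test_single_disc_axial_closed_form(self, straight_spine):
        """Translating T1 along its disc axis produces the EA/L axial
        force of that disc."""
        delta = 0.5
        axis = straight_spine["T2"].ep_sup - straight_spine["T1"].ep_inf
        L0 = np.linalg.norm(axis)
        axis = axis / L0
        # moving T1 against the disc axis stretches the disc: tension
        tgt = _translated_copy(straight_spine, "T1", -delta * axis)
        pre = correction.disc_prestress(straight_spine, tgt)
        sec = fe.disc_section(straight_spine["T1"], straight_spine["T2"])
        assert pre.f_local[0, 6] == pytest.approx(
            6.0 * sec.area / L0 * delta, rel=1e-6
        )

    def test_reactions_linear_in_disc_modulus(self, case):
        geom, major, target, tgt, plans = case
        plan = plans[0].with_contours(tgt)
        h1 = correction.step1_deform(geom, tgt, plan)
        h2 = correction.step1_deform(
            geom, tgt, plan, disc_material=Material(12.0, 0.45)
        )
        for lv in h1.reactions:
            np.testing.assert_allclose(h2.reactions[lv], 2 * h1.reactions[lv], rtol=1e-6, atol=1e-9)


class TestStep2:
    def test_zero_held_state_zero_outputs(self, straight_spine):
        fake_major = CurveDescriptor("T5", "T12", "T9", 0.0, "dextro", 0.0)
        plan = enumerate_plans(
            straight_spine, CurveDescriptor("T5", "T12", "T9", 40.0, "dextro", 0.0)
        )[0]
        res = correction.simulate_correction(
            straight_spine, TargetConfiguration(0.0, 0.0), plan, major=fake_major
        )
        assert res.max_rod_stress == pytest.approx(0.0, abs=1e-8)
        assert res.max_screw_force == pytest.approx(0.0, abs=1e-8)
        assert res.residual_cobb == pytest.approx(0.0, abs=1e-8)

    def test_rod_free_body_equilibrium(self, case):
        geom, major, target, tgt, plans = case
        res = correction.simulate_correction(
            geom, target, plans[0], major=major, target_geometry=tgt
        )
        assert res.diagnostics["coupling_force_residual"] < 1e-6
        assert res.diagnostics["coupling_moment_residual"] < 1e-6

    def test_energy_release_inequality(self, case):
        geom, major, target, tgt, plans = case
        for plan in plans[::9]:
            res = correction.simulate_correction(
                geom, target, plan, major=major, target_geometry=tgt
            )
            d = res.diagnostics
            assert d["energy_disc_final"] + d["energy_rod"] <= d["energy_imposed"] * (
                1 + 1e-6
            )

    def test_mirror_symmetry(self, case):
        geom, major, target, tgt, plans = case
        res = correction.simulate_correction(geom, target, plans[0], major=major)
        gm = mirror_geometry(geom)
        majm = max(metrics.detect_curves(gm), key=lambda c: c.cobb)
        resm = correction.simulate_correction(
            gm, target, enumerate_plans(gm, majm)[0], major=majm
        )
        assert res.max_rod_stress == pytest.approx(resm.max_rod_stress, abs=1e-6)
        assert res.max_screw_force == pytest.approx(resm.max_screw_force, abs=1e-6)
        assert res.residual_cobb == pytest.approx(resm.residual_cobb, abs=1e-6)

    def test_stiffer_rods_reduce_residual(self, case):
        geom, major, target, tgt, plans = case
        base = correction.simulate_correction(
            geom, target, plans[0], major=major, target_geometry=tgt
        )
        stiff = correction.simulate_correction(
            geom, target, plans[0], major=major, target_geometry=tgt,
            rod_material=Material(1.1e6, 0.3),
        )
        assert stiff.residual_cobb <= base.residual_cobb + 1e-9

    def test_residual_within_preop_for_coronal_correction(self):
        """Pure coronal corrections never leave more deformity than the
        pre-operative curve (100 random cases at the baseline target).

        The three-anchor apical-key-vertebrae construct is granted a small
        junctional margin: holding the apex straight while the unanchored
        neighbours spring back can tilt the (unanchored) end vertebrae
        slightly past their pre-operative inclination — a junctional
        angulation effect, not over-correction."""
        from scolisim.geometry import LEVELS

        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            apex = LEVELS[int(rng.integers(6, 12))]
            spec = SpineSpec(
                curves=(
                    CurveSpec(
                        apex,
                        float(rng.uniform(36.8, 84.6)),
                        "dextro" if rng.uniform() < 0.5 else "levo",
                        float(rng.uniform(0.0, 30.0)),
                        int(rng.integers(8, 11)),
                    ),
                ),
                tk=float(rng.uniform(5.0, 50.0)),
                ll=float(rng.uniform(20.0, 60.0)),
            )
            geom = anatomy.generate_spine(spec)
            curves = metrics.detect_curves(geom)
            if not curves:
                continue
            major = max(curves, key=lambda c: c.cobb)
            plans = enumerate_plans(geom, major)
            if not plans:
                continue
            plan = plans[int(rng.integers(0, len(plans)))]
            res = correction.simulate_correction(
                geom, TargetConfiguration(0.0, 0.0), plan, major=major
            )
            margin = 3.0 if plan.pattern == "apical_key_vertebrae" else 1e-6
            assert 0.0 <= res.residual_cobb <= major.cobb + margin, (
                f"{apex} {plan.pattern} {res.residual_cobb} vs {major.cobb}"
            )
            checked += 1

    def test_offsets_stay_within_instrumentation(self, case):
        geom, major, target, tgt, plans = case
        from scolisim.geometry import level_index

        ia = level_index(major.apex)
        for plan in plans[::7]:
            res = correction.simulate_correction(
                geom, target, plan, major=major, target_geometry=tgt
            )
            lo = level_index(plan.uiv) - ia
            hi = level_index(plan.liv) - ia
            assert lo <= res.stress_offset <= hi
            assert lo <= res.force_offset <= hi
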