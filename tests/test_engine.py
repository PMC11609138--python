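"""Equilibrium solve, remodeling loop and staged protocol."""

import copy

import numpy as np
import pytest

import alignersim as asim
from alignersim import engine as eng
from alignersim.aligner import apply_staging
from alignersim.dentition import PdlSampleField
from alignersim.fixtures import one_tooth_scene
from alignersim.rigid import apply_pose


def fresh_state(design="con"):
    scenario = asim.Scenario(design=asim.TrimDesign.parse(design))
    state, base = eng.prepare_state(scenario)
    return scenario, state, base


class TestSolveEquilibrium:
    def test_stress_free_build_stays_put_without_loads(self):
        _, state, _ = fresh_state()
        state.traction = None
        res = eng.solve_equilibrium(state)
        for rec in res.teeth.values():
            assert np.abs(rec.twist_total).max() < 1e-10

    def test_one_tooth_springs_in_series_closed_form(self):
        sc = one_tooth_scene(k_pdl_area=10.0, k_socket=500.0, delta=0.1)
        res = eng.solve_equilibrium(sc["state"])
        twist = res.teeth[1].twist_total
        assert twist[1] == pytest.approx(sc["expected_displacement"], rel=1e-9)
        assert np.abs(np.delete(twist, 1)).max() < 1e-12

    def test_no_active_wall_in_tension_and_residual_small(self):
        scenario, state, base = fresh_state("smhw")
        state.aligner = apply_staging(base, scenario.staging, 1)
        res = eng.solve_equilibrium(state)
        assert res.residual_linear < 1e-5
        for rec in res.teeth.values():
            if rec.active_wall == "mesial":
                # mesial wall only pushes distally (negative local md force)
                assert rec.wall_force_md <= 1e-12
            elif rec.active_wall == "distal":
                assert rec.wall_force_md >= -1e-12

    def test_global_equilibrium_in_symmetric_subspace(self):
        scenario, state, base = fresh_state("con")
        state.aligner = apply_staging(base, scenario.staging, 1)
        res = eng.solve_equilibrium(state)
        # PDL reactions balance the TAD traction in the frame's DOF:
        # in-plane forces and the moment about the lateral axis
        assert np.abs(res.force_balance_sym).max() < 1e-6

    def test_singular_system_reported(self):
        sc = one_tooth_scene()
        # collapse the PDL to a single point spring: rotations about it are
        # unconstrained and the socket only holds one translation
        sc["state"]._body_samples[1] = PdlSampleField(
            points=np.array([[0.0, 0.0, 4.0]]),
            normals=np.array([[0.0, 1.0, 0.0]]),
            areas=np.array([1.0]))
        with pytest.raises(eng.SingularSystemError):
            eng.solve_equilibrium(sc["state"])

    def test_solve_is_idempotent_without_remodel(self):
        scenario, state, base = fresh_state("con")
        state.aligner = apply_staging(base, scenario.staging, 1)
        eng.solve_equilibrium(state)
        poses_a = {t.position: t.current_pose.copy()
                   for t in state.dentition.teeth}
        eng.solve_equilibrium(state)
        for t in state.dentition.teeth:
            assert np.allclose(t.current_pose, poses_a[t.position],
                               atol=1e-12)


class TestRemodel:
    def test_zero_load_remodel_then_solve_is_identity(self):
        _, state, _ = fresh_state()
        state.traction = None
        eng.solve_equilibrium(state)
        eng.remodel(state)
        res = eng.solve_equilibrium(state)
        assert res.max_strain_fraction < 1e-12

    def test_two_remodels_without_load_change_second_is_identity(self):
        scenario, state, base = fresh_state("con")
        state.aligner = apply_staging(base, scenario.staging, 1)
        eng.solve_equilibrium(state)
        eng.remodel(state)
        frozen = {t.position: t.stress_free_pose.copy()
                  for t in state.dentition.teeth}
        eng.remodel(state)
        for t in state.dentition.teeth:
            assert np.array_equal(t.stress_free_pose, frozen[t.position])

    @pytest.mark.parametrize("design", ["con", "smhw", "mhw"])
    def test_strain_decreases_monotonically_over_iterations(self, design):
        strains = asim.convergence_probe(
            asim.Scenario(design=asim.TrimDesign.parse(design)), iterations=3)
        assert strains[0] > strains[1] > strains[2]

    def test_displacement_increment_shrinks_after_remodel(self):
        scenario, state, base = fresh_state("mhw")
        state.aligner = apply_staging(base, scenario.staging, 1)
        res1 = eng.solve_equilibrium(state)
        inc1 = max(np.abs(r.twist_increment).max() for r in res1.teeth.values())
        eng.remodel(state)
        res2 = eng.solve_equilibrium(state)
        inc2 = max(np.abs(r.twist_increment).max() for r in res2.teeth.values())
        assert inc2 < inc1


class TestProtocol:
    def test_trajectory_shape_and_gap_monotone(self, staged_runs):
        for traj in staged_runs.values():
            assert len(traj.steps) >= 10
            gaps = traj.gap_series()
            assert all(b <= a + 1e-6 for a, b in zip(gaps, gaps[1:]))
            assert traj.space_closed_step is not None

    def test_molar_anchorage_ordering_matches_mechanism(self, staged_runs):
        md6 = {d: asim.records_from_trajectory(t)[6].md_displacement
               for d, t in staged_runs.items()}
        assert md6["smhw"] > md6["con"] > md6["mhw"] > 0

    def test_incisor_labial_ordering_matches_mechanism(self, staged_runs):
        bl1 = {d: asim.records_from_trajectory(t)[1].bl_displacement
               for d, t in staged_runs.items()}
        # labial is negative; magnitude ordering MHW > SMHW > CON
        assert bl1["mhw"] < bl1["smhw"] < bl1["con"] < 0

    def test_mhw_molar_walls_never_push_mesially(self, staged_runs):
        for rec in staged_runs["mhw"].steps:
            for it in rec.iterations:
                for p in (6, 7):
                    assert it.wall_force_md[p] <= 1e-12

    def test_protocol_is_bit_exact_for_fixed_seed(self):
        sc = asim.Scenario(design=asim.TrimDesign.CON, seed=4)
        a = asim.run_protocol(sc)
        b = asim.run_protocol(sc)
        assert a.space_closed_step == b.space_closed_step
        for p, pose in a.final_step.tooth_poses.items():
            assert np.array_equal(pose, b.final_step.tooth_poses[p])

    def test_trajectory_frame_layout(self, staged_runs):
        df = staged_runs["con"].to_frame()
        assert {"step", "iteration", "tooth", "ux", "wy", "max_strain",
                "wall_force_md", "gap_5_6"} <= set(df.columns)
        assert df["tooth"].nunique() == 7

    def test_space_never_closes_raises_with_final_gap(self):
        sc = asim.Scenario(
            design=asim.TrimDesign.MHW,
            staging=asim.StagingPlan(n_steps=2),
            engine=asim.EngineConfig(max_extension_steps=1))
        with pytest.raises(eng.SpaceNotClosedError) as err:
            asim.run_protocol(sc)
        assert err.value.final_gap > 0


class TestSpaceClosed:
    def test_fresh_state_open(self):
        _, state, _ = fresh_state()
        assert not eng.detect_space_closed(state)
        assert state.gap_5_6() == pytest.approx(2.0, abs=0.01)

    def test_gap_within_tolerance_closed(self):
        _, state, _ = fresh_state()
        assert eng.detect_space_closed(state, tol=2.5)

    def test_premolar_translated_distally_closes_space(self):
        _, state, _ = fresh_state()
        t5 = state.dentition.tooth(5)
        distal = -t5.md_axis
        pose = np.eye(4)
        pose[:3, 3] = 2.0 * distal
        t5.current_pose = pose @ t5.current_pose
        assert eng.detect_space_closed(state, tol=0.05)


class TestTractionConfig:
    def test_gram_force_conversion(self):
        t = eng.TractionConfig(magnitude_gf=150.0, from_point=np.zeros(3),
                               to_point=np.array([1.0, 0.0, 0.0]))
        assert t.magnitude_newton == pytest.approx(1.4710, abs=1e-4)
        assert np.allclose(t.force_vector(), [1.4709975, 0.0, 0.0])

    def test_invalid_magnitude_and_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            eng.TractionConfig(magnitude_gf=0.0)
        t = eng.TractionConfig(from_point=np.zeros(3), to_point=np.zeros(3))
        with pytest.raises(ValueError):
            t.force_vector()


def test_scene_mirror_symmetry_of_equilibrium():
    """Reflecting a fixed-frame scene in the median plane mirrors the
    equilibrium twist exactly (translations flip x, rotations flip y, z)."""
    import dataclasses

    sc = one_tooth_scene()
    sock = sc["state"].aligner.sockets[0]
    # give the rest offset an off-plane component so the mirror is non-trivial
    rest = np.eye(4)
    rest[:3, 3] = [0.06, 0.1, 0.0]
    sock_a = dataclasses.replace(
        sock, rest_pose_in_aligner=rest,
        reference_point=sc["tooth"].centroid + rest[:3, 3],
        wrap_stiffness=np.array([300.0, 500.0, 0.0, 0.0, 0.0, 0.0]))
    state_a = sc["state"]
    state_a.aligner = asim.Aligner(sockets=[sock_a], design=asim.TrimDesign.CON)
    res_a = eng.solve_equilibrium(state_a)

    mirror = np.diag([-1.0, 1.0, 1.0])
    sc_b = one_tooth_scene()
    samples = sc_b["state"]._body_samples[1]
    sc_b["state"]._body_samples[1] = PdlSampleField(
        points=samples.points @ mirror, normals=samples.normals @ mirror,
        areas=samples.areas)
    rest_b = np.eye(4)
    rest_b[:3, 3] = mirror @ rest[:3, 3]
    sock_b = dataclasses.replace(
        sock, rest_pose_in_aligner=rest_b,
        reference_point=mirror @ (sc["tooth"].centroid + rest[:3, 3]),
        wrap_stiffness=np.array([300.0, 500.0, 0.0, 0.0, 0.0, 0.0]))
    state_b = sc_b["state"]
    state_b.dentition.teeth[0].centroid = mirror @ sc["tooth"].centroid
    state_b.aligner = asim.Aligner(sockets=[sock_b], design=asim.TrimDesign.CON)
    res_b = eng.solve_equilibrium(state_b)

    ya, yb = res_a.teeth[1].twist_total, res_b.teeth[1].twist_total
    flip = np.array([-1.0, 1.0, 1.0, 1.0, -1.0, -1.0])
    assert np.allclose(yb, flip * ya, atol=1e-12)
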