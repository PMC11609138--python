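"""Aligner model: trim designs, staging, TCM bookkeeping, socket walls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import alignersim as asim
from alignersim.aligner import MD, apply_staging, socket_span
from alignersim.rigid import twist_to_pose


@pytest.fixture(scope="module")
def aligners(dentition):
    return {d: asim.build_aligner(dentition, d) for d in ("con", "smhw", "mhw")}


class TestBuild:
    def test_conventional_design_has_all_fourteen_walls(self, aligners):
        a = aligners["con"]
        assert all(s.has_mesial_wall and s.has_distal_wall for s in a.sockets)
        assert all(s.stiffness_scale == 1.0 for s in a.sockets)

    def test_second_molar_half_wrap(self, aligners):
        a = aligners["smhw"]
        assert not a.socket(7).has_distal_wall
        assert a.socket(7).stiffness_scale == 0.5
        for p in range(1, 7):
            assert a.socket(p).has_distal_wall
            assert a.socket(p).stiffness_scale == 1.0

    def test_all_molar_half_wrap(self, aligners):
        a = aligners["mhw"]
        for p in (6, 7):
            assert not a.socket(p).has_distal_wall
            assert a.socket(p).stiffness_scale == 0.5
        for p in range(1, 6):
            assert a.socket(p).has_distal_wall

    def test_unknown_design_rejected(self, dentition):
        with pytest.raises(ValueError):
            asim.build_aligner(dentition, "halfwrap")

    def test_rest_poses_equal_crown_poses_at_build(self, dentition, aligners):
        for tooth in dentition.teeth:
            sock = aligners["con"].socket(tooth.position)
            assert np.array_equal(sock.rest_pose_in_aligner, tooth.current_pose)

    def test_attachments_increase_rotational_grip(self, dentition):
        a = asim.build_aligner(dentition, "con")
        # canine (no attachment) vs first premolar (attachment, grip 1.5)
        canine, premolar = a.socket(3), a.socket(4)
        base3 = asim.aligner.default_socket_stiffness(
            dentition.tooth(3).crown_height, dentition.tooth(3).crown_bl_width)
        base4 = asim.aligner.default_socket_stiffness(
            dentition.tooth(4).crown_height, dentition.tooth(4).crown_bl_width)
        assert canine.wrap_stiffness[3] == pytest.approx(base3[3])
        assert premolar.wrap_stiffness[3] == pytest.approx(1.5 * base4[3])


class TestStaging:
    def test_single_step_span_changes(self, aligners):
        plan = asim.StagingPlan()
        base = aligners["con"]
        staged = apply_staging(base, plan, 1)
        d56 = socket_span(staged, (5, 6)) - socket_span(base, (5, 6))
        d34 = socket_span(staged, (3, 4)) - socket_span(base, (3, 4))
        # spans are chord projections; the staged translation follows each
        # socket's own arch tangent, so curvature costs about 1 %
        assert d56 == pytest.approx(-0.20, abs=5e-3)
        assert d34 == pytest.approx(+0.20, abs=5e-3)

    def test_ten_steps_accumulate_two_mm(self, aligners):
        plan = asim.StagingPlan()
        base = aligners["con"]
        staged = apply_staging(base, plan, 10)
        assert socket_span(staged, (5, 6)) - socket_span(base, (5, 6)) == \
            pytest.approx(-2.0, abs=0.05)
        assert socket_span(staged, (3, 4)) - socket_span(base, (3, 4)) == \
            pytest.approx(+2.0, abs=0.05)

    def test_purely_mesiodistal_no_vertical_or_bl_component(self, aligners):
        plan = asim.StagingPlan()
        base = aligners["con"]
        staged = apply_staging(base, plan, 5)
        for p in (4, 5):
            shift = (staged.socket(p).rest_pose_in_aligner[:3, 3]
                     - base.socket(p).rest_pose_in_aligner[:3, 3])
            mesial = base.socket(p).local_axes[:, 0]
            along = np.dot(shift, mesial)
            assert along == pytest.approx(-1.0, abs=1e-12)
            assert np.linalg.norm(shift - along * mesial) < 1e-12

    def test_step_zero_is_identity(self, aligners):
        staged = apply_staging(aligners["con"], asim.StagingPlan(), 0)
        for s, s0 in zip(staged.sockets, aligners["con"].sockets):
            assert np.array_equal(s.rest_pose_in_aligner, s0.rest_pose_in_aligner)

    def test_negative_step_rejected(self, aligners):
        with pytest.raises(ValueError):
            apply_staging(aligners["con"], asim.StagingPlan(), -1)

    def test_staging_composes_incrementally(self, aligners):
        plan = asim.StagingPlan()
        base = aligners["con"]
        direct = apply_staging(base, plan, 7)
        via = apply_staging(apply_staging(base, plan, 3), plan, 7)
        for p in range(1, 8):
            assert np.allclose(direct.socket(p).rest_pose_in_aligner,
                               via.socket(p).rest_pose_in_aligner,
                               atol=1e-12)

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            asim.StagingPlan(shortened_span=(4, 5))
        with pytest.raises(ValueError):
            asim.StagingPlan(step_increment=0.0)


class TestTcm:
    def test_no_remaining_deformation_means_no_temperature_change(self):
        assert asim.tcm_temperature(asim.TCMParameters(U=0.4, Delta=0.4)) == 0.0

    def test_worked_example(self):
        t = asim.tcm_temperature(asim.TCMParameters(U=0.2, k=0.01, Delta=0.0, d=2.0))
        assert t == pytest.approx(10.0)
        # cross-check: k * d * t recovers the imposed deformation
        assert 0.01 * 2.0 * t == pytest.approx(0.2)

    def test_contraction_gives_negative_temperature(self):
        assert asim.tcm_temperature(asim.TCMParameters(U=0.1, Delta=0.3)) < 0

    @given(u=st.floats(-1, 1), delta=st.floats(-1, 1),
           k=st.floats(1e-3, 1), d=st.floats(0.5, 5))
    def test_temperature_always_recovers_deformation(self, u, delta, k, d):
        params = asim.TCMParameters(U=u, Delta=delta, k=k, d=d)
        t = asim.tcm_temperature(params)
        assert k * d * t == pytest.approx(u - delta, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            asim.TCMParameters(U=0.2, k=0.0)


def _offset_socket(socket, offset_world):
    import dataclasses

    rest = socket.rest_pose_in_aligner.copy()
    rest[:3, 3] += offset_world
    return dataclasses.replace(socket, rest_pose_in_aligner=rest,
                               reference_point=socket.reference_point
                               + offset_world)


class TestSocketWrench:
    def test_zero_wrench_at_rest(self, dentition, aligners):
        for tooth in dentition.teeth:
            out = asim.socket_wrench(aligners["con"].socket(tooth.position),
                                     tooth.current_pose, np.eye(4))
            assert np.abs(out["wrench_on_tooth"]).max() < 1e-9

    def test_distal_wall_pushes_mesially(self, dentition, aligners):
        # socket rest 0.1 mm mesial of the tooth -> the tooth sits distal of
        # its socket, the distal wall is in compression and pushes mesially
        tooth = dentition.tooth(5)
        sock = _offset_socket(aligners["con"].socket(5), 0.1 * tooth.md_axis)
        k_wall = sock.wrap_stiffness[MD]
        out = asim.socket_wrench(sock, tooth.current_pose, np.eye(4))
        force_md = np.dot(out["wrench_on_tooth"][:3], tooth.md_axis)
        assert out["active_wall"] == "distal"
        assert force_md == pytest.approx(0.1 * k_wall, rel=1e-9)

    def test_absent_distal_wall_transmits_nothing(self, dentition, aligners):
        tooth = dentition.tooth(6)
        sock = _offset_socket(aligners["mhw"].socket(6), 0.1 * tooth.md_axis)
        out = asim.socket_wrench(sock, tooth.current_pose, np.eye(4))
        force_md = np.dot(out["wrench_on_tooth"][:3], tooth.md_axis)
        assert out["active_wall"] is None
        assert force_md == pytest.approx(0.0, abs=1e-12)

    def test_action_reaction_exact_for_random_configurations(self, dentition,
                                                             aligners):
        rng = np.random.default_rng(3)
        for design in ("con", "smhw", "mhw"):
            for tooth in dentition.teeth:
                sock = aligners[design].socket(tooth.position)
                twist = rng.normal(0.0, 0.05, 6)
                pose = twist_to_pose(twist, tooth.centroid) @ tooth.current_pose
                frame = twist_to_pose(rng.normal(0.0, 0.02, 6), np.zeros(3))
                out = asim.socket_wrench(sock, pose, frame)
                assert np.array_equal(out["wrench_on_tooth"],
                                      -out["wrench_on_aligner"])

    def test_walls_never_report_tension(self, dentition, aligners):
        rng = np.random.default_rng(5)
        for design in ("con", "smhw", "mhw"):
            for tooth in dentition.teeth:
                sock = aligners[design].socket(tooth.position)
                for _ in range(10):
                    pose = twist_to_pose(rng.normal(0.0, 0.1, 6),
                                         tooth.centroid) @ tooth.current_pose
                    out = asim.socket_wrench(sock, pose, np.eye(4))
                    mismatch_md = out["mismatch_local"][MD]
                    force_md = -sock.wrap_stiffness[MD] * mismatch_md \
                        if out["active_wall"] else 0.0
                    if out["active_wall"] == "mesial":
                        assert mismatch_md >= 0 and force_md <= 0
                    elif out["active_wall"] == "distal":
                        assert mismatch_md <= 0 and force_md >= 0
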