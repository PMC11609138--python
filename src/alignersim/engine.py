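"""Quasi-static equilibrium and the staged remodeling protocol.

One *solve* balances every tooth (6 DOF each, supported by its PDL
foundation) against its aligner socket, and the rigid aligner frame (3 DOF:
the motions invariant under reflection in the median sagittal plane —
translations within the plane and rotation about its normal) against the
socket reactions plus the elastic traction from the canine region to the
mini-implant (TAD).  Unilateral mesial/distal walls are handled by
active-set sweeps: solve with the current wall set, drop any wall that
would have to pull, re-solve until the set is stable.

A *remodeling iteration* then moves each tooth's stress-free pose to its
equilibrium pose and regenerates the PDL there, which is how prolonged
wear of one staging step is simulated; the staged protocol runs ten 0.2 mm
steps (plus identical extension steps until the premolar-molar space
closes) with a fixed number of remodeling iterations per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import rigid
from .aligner import (MD, Aligner, Socket, StagingPlan, TCMParameters,
                      TrimDesign, apply_staging, build_aligner,
                      tcm_temperature)
from .dentition import (Dentition, DentitionConfig, PdlSampleField,
                        generate_quadrant, sample_root_surface)
from .pdl import (FoundationModuli, assemble_stiffness, default_pdl_moduli,
                  strain_and_traction)

GRAM_FORCE_TO_NEWTON = 9.80665e-3


class ActiveSetError(RuntimeError):
    """The unilateral wall set failed to stabilize."""

    def __init__(self, oscillating):
        self.oscillating = sorted(oscillating)
        super().__init__(
            f"active wall set did not converge; oscillating sockets: {self.oscillating}")


class SingularSystemError(np.linalg.LinAlgError):
    def __init__(self, detail: str):
        super().__init__(f"equilibrium system is singular: {detail}")


class SpaceNotClosedError(RuntimeError):
    def __init__(self, gap: float, steps: int):
        self.final_gap = gap
        super().__init__(
            f"premolar-molar space still open ({gap:.3f} mm) after {steps} steps")


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class TractionConfig:
    """Elastic traction from the aligner's canine hook to the TAD."""

    magnitude_gf: float = 150.0
    from_point: np.ndarray | None = None   # on the aligner (canine buccal-mesial cervical)
    to_point: np.ndarray | None = None     # TAD location

    def __post_init__(self):
        if self.magnitude_gf <= 0:
            raise ValueError("traction magnitude must be positive")

    @property
    def magnitude_newton(self) -> float:
        return self.magnitude_gf * GRAM_FORCE_TO_NEWTON

    def force_vector(self) -> np.ndarray:
        d = np.asarray(self.to_point, float) - np.asarray(self.from_point, float)
        norm = np.linalg.norm(d)
        if norm <= 0:
            raise ValueError("traction endpoints coincide")
        return self.magnitude_newton * d / norm


@dataclass(frozen=True)
class EngineConfig:
    iterations_per_step: int = 2
    residual_force_tol: float = 1e-6       # N
    residual_moment_tol: float = 1e-5      # N*mm
    max_active_set_sweeps: int = 50
    space_closed_tolerance: float = 0.01   # mm
    max_extension_steps: int = 8
    pdl_samples_per_tooth: int = 400
    fix_aligner_frame: bool = False        # used by reduced test scenes

    def __post_init__(self):
        if min(self.iterations_per_step, self.max_active_set_sweeps,
               self.max_extension_steps, self.pdl_samples_per_tooth) < 1:
            raise ValueError("engine counters must be positive")
        if min(self.residual_force_tol, self.residual_moment_tol,
               self.space_closed_tolerance) <= 0:
            raise ValueError("engine tolerances must be positive")


@dataclass
class SimulationState:
    dentition: Dentition
    aligner: Aligner
    traction: TractionConfig | None = None
    config: EngineConfig = field(default_factory=EngineConfig)
    moduli: FoundationModuli | None = None
    step_index: int = 0
    iteration_index: int = 0
    active_wall_set: dict = field(default_factory=dict)
    history: list = field(default_factory=list)
    _body_samples: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.moduli is None:
            self.moduli = default_pdl_moduli(self.dentition.config.pdl_thickness)

    def body_samples(self, position: int) -> PdlSampleField:
        if position not in self._body_samples:
            self._body_samples[position] = sample_root_surface(
                self.dentition.tooth(position),
                self.config.pdl_samples_per_tooth, frame="body")
        return self._body_samples[position]

    def gap_5_6(self) -> float:
        return self.dentition.gap_5_6()


def make_state(dentition: Dentition, aligner: Aligner,
               traction: TractionConfig | None = None,
               config: EngineConfig | None = None) -> SimulationState:
    config = config or EngineConfig()
    if traction is None and dentition.tad is not None and \
            aligner.traction_attachment_point is not None:
        traction = TractionConfig(
            from_point=aligner.traction_attachment_point,
            to_point=dentition.tad.location)
    return SimulationState(dentition=dentition, aligner=aligner,
                           traction=traction, config=config)


# ---------------------------------------------------------------------------
# equilibrium solve

def _frame_map(reference: np.ndarray) -> np.ndarray:
    """6x3 map from the aligner frame DOF (u_y, u_z, w_x) to a world twist
    about ``reference`` (the frame DOF are twists about the origin)."""
    c = np.asarray(reference, float)
    a = np.zeros((6, 3))
    a[1, 0] = 1.0
    a[2, 1] = 1.0
    a[:3, 2] = np.cross([1.0, 0.0, 0.0], c)  # u at ref = w x (ref - origin)
    a[3, 2] = 1.0
    return a


@dataclass
class ToothSolveRecord:
    position: int
    reference_point: np.ndarray
    twist_total: np.ndarray          # from stress-free pose, about reference
    twist_increment: np.ndarray      # from pre-solve current pose
    max_strain_fraction: float
    strains: np.ndarray
    socket_wrench_on_tooth: np.ndarray | None
    active_wall: str | None
    wall_force_md: float             # local mesio-distal force on tooth (mesial +)
    mismatch_local: np.ndarray | None
    pdl_wrench: np.ndarray           # -K y, reaction of the foundation


@dataclass
class SolveResult:
    teeth: dict                      # position -> ToothSolveRecord
    frame_dof: np.ndarray            # (u_y, u_z, w_x)
    traction_force: np.ndarray | None
    sweeps: int
    residual_linear: float
    force_balance_sym: np.ndarray    # (Fy, Fz, Mx) total — should vanish
    max_strain_fraction: float


def _tooth_assembly(state: SimulationState, tooth):
    """Geometry-dependent pieces for one tooth at its stress-free pose."""
    pose0 = tooth.stress_free_pose
    ref = rigid.apply_pose(pose0, tooth.centroid)
    samples = state.body_samples(tooth.position).transformed(pose0)
    kp = assemble_stiffness(samples, state.moduli, ref)
    x0 = rigid.pose_to_twist(tooth.current_pose @ rigid.invert(pose0), ref)
    return ref, samples, kp, x0


def _socket_coupling(socket: Socket, ref: np.ndarray, pose0: np.ndarray):
    """Socket rest mismatch and the twist shift from the tooth reference to
    the socket reference (both about world frames at identity aligner pose)."""
    g = rigid.pose_to_twist(socket.rest_pose_in_aligner @ rigid.invert(pose0), ref)
    shift = np.eye(6)
    shift[:3, 3:] = rigid.skew(socket.reference_point - ref)  # twist@ref -> twist@socket
    return g, shift


def solve_equilibrium(state: SimulationState,
                      config: EngineConfig | None = None) -> SolveResult:
    """Solve the coupled tooth/aligner equilibrium and update current poses.

    Linear small-displacement solve about the stress-free configuration,
    wrapped in deterministic active-set sweeps (sockets in position order,
    mesial wall checked before distal) for the unilateral walls.
    """
    config = config or state.config
    teeth = state.dentition.teeth
    n = len(teeth)
    moduli = state.moduli

    pre = [_tooth_assembly(state, tooth) for tooth in teeth]
    sockets = []
    for tooth, (ref, _, _, _) in zip(teeth, pre):
        try:
            sockets.append(state.aligner.socket(tooth.position))
        except KeyError:
            sockets.append(None)

    free_frame = not config.fix_aligner_frame
    nq = 3 if free_frame else 0
    size = 6 * n + nq
    qs = slice(6 * n, size)

    couplings = []
    for tooth, sock, (ref, _, _, _) in zip(teeth, sockets, pre):
        if sock is None:
            couplings.append(None)
        else:
            g, shift = _socket_coupling(sock, ref, tooth.stress_free_pose)
            a = _frame_map(ref) if free_frame else np.zeros((6, 0))
            couplings.append((g, shift, a))

    traction_force = None
    q_force = np.zeros(nq)
    if free_frame and state.traction is not None:
        traction_force = state.traction.force_vector()
        p = np.asarray(state.traction.from_point, float)
        moment = np.cross(p, traction_force)
        q_force = np.array([traction_force[1], traction_force[2], moment[0]])

    # deterministic active-set sweeps
    md_active = {s.position: (s.has_mesial_wall or s.has_distal_wall)
                 for s in sockets if s is not None}
    seen_states = []
    solution = None
    sweeps = 0
    for sweeps in range(1, config.max_active_set_sweeps + 1):
        m = np.zeros((size, size))
        rhs = np.zeros(size)
        for i, (tooth, sock, (ref, _, kp, _)) in enumerate(zip(teeth, sockets, pre)):
            sl = slice(6 * i, 6 * i + 6)
            m[sl, sl] += kp.matrix
            if sock is None:
                continue
            g, shift, a = couplings[i]
            ks = shift.T @ sock.stiffness_world(md_active[sock.position]) @ shift
            m[sl, sl] += ks
            rhs[sl] += ks @ g
            if free_frame:
                m[sl, qs] += -ks @ a
                m[qs, sl] += -(ks @ a).T
                m[qs, qs] += a.T @ ks @ a
                rhs[qs] += -(a.T @ (ks @ g))
        if free_frame:
            rhs[qs] += q_force

        try:
            solution = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(m)
            bad = vecs[:, vals < 1e-9 * max(vals.max(), 1.0)]
            raise SingularSystemError(
                f"unconstrained DOF subspace:\n{np.array_str(bad, precision=3)}"
            ) from None

        q = solution[qs] if free_frame else np.zeros(0)
        new_active = dict(md_active)
        walls = {}
        for i, (tooth, sock) in enumerate(zip(teeth, sockets)):
            if sock is None:
                continue
            g, shift, a = couplings[i]
            y = solution[6 * i:6 * i + 6]
            delta = shift @ (y - (a @ q if free_frame else 0.0) - g)
            delta_loc = sock.rotation6().T @ delta
            wall = sock.wall_for_mismatch(delta_loc[MD])
            walls[sock.position] = (wall, delta_loc)
            new_active[sock.position] = wall is not None
        if new_active == md_active:
            break
        key = tuple(sorted(new_active.items()))
        if key in seen_states:
            changed = [p for p in md_active if new_active[p] != md_active[p]]
            raise ActiveSetError(changed)
        seen_states.append(tuple(sorted(md_active.items())))
        md_active = new_active
    else:
        raise ActiveSetError([p for p in md_active])

    # unpack, update poses, collect diagnostics
    q = solution[qs] if free_frame else np.zeros(3)
    records = {}
    total_force = np.zeros(3)
    total_moment = np.zeros(3)
    max_strain = 0.0
    residual = float(np.linalg.norm(m @ solution - rhs))
    for i, (tooth, sock, (ref, samples, kp, x0)) in enumerate(
            zip(teeth, sockets, pre)):
        y = solution[6 * i:6 * i + 6]
        st = strain_and_traction(samples, y, ref, moduli)
        pdl_wrench = -kp.matrix @ y
        wrench = None
        wall = None
        wall_force = 0.0
        mismatch = None
        if sock is not None:
            wall, delta_loc = walls[sock.position]
            mismatch = delta_loc
            k_eff = sock.wrap_stiffness.copy()
            if wall is None:
                k_eff[MD] = 0.0
            w_loc = -k_eff * delta_loc
            wall_force = float(w_loc[MD])
            g, shift, a = couplings[i]
            wrench = shift.T @ (sock.rotation6() @ w_loc)  # about tooth ref
        tooth.current_pose = rigid.twist_to_pose(y, ref) @ tooth.stress_free_pose
        records[tooth.position] = ToothSolveRecord(
            position=tooth.position, reference_point=ref,
            twist_total=y, twist_increment=y - x0,
            max_strain_fraction=st.max_strain_fraction, strains=st.strains,
            socket_wrench_on_tooth=wrench, active_wall=wall,
            wall_force_md=wall_force, mismatch_local=mismatch,
            pdl_wrench=pdl_wrench)
        total_force += pdl_wrench[:3]
        total_moment += pdl_wrench[3:] + np.cross(ref, pdl_wrench[:3])
        max_strain = max(max_strain, st.max_strain_fraction)

    if traction_force is not None:
        total_force += traction_force
        total_moment += np.cross(np.asarray(state.traction.from_point, float),
                                 traction_force)
    balance = np.array([total_force[1], total_force[2], total_moment[0]])

    if free_frame:
        frame_twist = np.array([0.0, q[0], q[1], q[2], 0.0, 0.0])
        state.aligner.frame_pose = rigid.twist_to_pose(frame_twist, np.zeros(3))
    state.active_wall_set = {p: r.active_wall for p, r in records.items()}

    result = SolveResult(
        teeth=records, frame_dof=q,
        traction_force=traction_force, sweeps=sweeps,
        residual_linear=residual, force_balance_sym=balance,
        max_strain_fraction=max_strain)
    if residual > max(config.residual_force_tol, config.residual_moment_tol) * 1e3:
        raise SingularSystemError(f"linear residual too large: {residual:.2e}")
    return result


def remodel(state: SimulationState) -> SimulationState:
    """Bone-remodeling update: the stress-free pose of every tooth becomes
    its current equilibrium pose and the PDL is regenerated there (the
    sample field rides rigidly with the tooth, so tributary areas are
    untouched).  The aligner is unchanged."""
    for tooth in state.dentition.teeth:
        tooth.stress_free_pose = tooth.current_pose.copy()
    return state


def detect_space_closed(state: SimulationState, tol: float | None = None) -> bool:
    """True iff the signed mesio-distal distance from tooth 5's distal
    contact point to tooth 6's mesial contact point is within tolerance."""
    tol = state.config.space_closed_tolerance if tol is None else tol
    return state.gap_5_6() <= tol


# ---------------------------------------------------------------------------
# staged protocol

@dataclass
class IterationRecord:
    step: int
    iteration: int
    max_strain_fraction: float
    strain_by_tooth: dict
    wall_force_md: dict
    active_wall: dict
    frame_dof: np.ndarray
    force_balance_sym: np.ndarray
    twist_increments: dict


@dataclass
class StepRecord:
    step: int
    gap_5_6: float
    closed: bool
    tooth_poses: dict                 # position -> 4x4 current pose (copy)
    iterations: list
    tcm: dict                         # span -> {"U", "Delta", "t"}


@dataclass
class Trajectory:
    design: TrimDesign
    scenario: "Scenario"
    dentition: Dentition
    initial_poses: dict
    steps: list
    space_closed_step: int | None

    @property
    def final_step(self) -> StepRecord:
        return self.steps[-1]

    def step_record(self, step: int) -> StepRecord:
        for rec in self.steps:
            if rec.step == step:
                return rec
        raise KeyError(step)

    def gap_series(self) -> list:
        return [rec.gap_5_6 for rec in self.steps]

    def to_frame(self):
        """Long-format per-iteration table (step, iteration, tooth, twist
        about the tooth's solve reference, strain, wall force, gap)."""
        import pandas as pd

        rows = []
        for rec in self.steps:
            for it in rec.iterations:
                for pos, twist in it.twist_increments.items():
                    rows.append({
                        "step": rec.step, "iteration": it.iteration,
                        "tooth": pos,
                        **{k: twist[j] for j, k in enumerate(
                            ["ux", "uy", "uz", "wx", "wy", "wz"])},
                        "max_strain": it.strain_by_tooth[pos],
                        "wall_force_md": it.wall_force_md[pos],
                        "active_wall": it.active_wall[pos],
                        "gap_5_6": rec.gap_5_6,
                    })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Scenario:
    """Everything needed to reproduce one staged run."""

    design: TrimDesign = TrimDesign.CON
    dentition_config: DentitionConfig = field(default_factory=DentitionConfig)
    staging: StagingPlan = field(default_factory=StagingPlan)
    traction_gf: float = 150.0
    engine: EngineConfig = field(default_factory=EngineConfig)
    seed: int = 0

    def with_design(self, design) -> "Scenario":
        return replace(self, design=TrimDesign.parse(design))


def _tcm_log(plan: StagingPlan, step: int) -> dict:
    u = plan.step_increment * step
    delta = plan.step_increment * (step - 1)
    out = {}
    for span, sign in ((plan.shortened_span, -1.0), (plan.lengthened_span, 1.0)):
        params = TCMParameters(U=sign * u, Delta=sign * delta)
        out[f"{span[0]}-{span[1]}"] = {
            "U": params.U, "Delta": params.Delta,
            "t": tcm_temperature(params)}
    return out


def prepare_state(scenario: Scenario) -> tuple:
    """Generate the dentition, build the aligner and initialize the state."""
    dconf = replace(scenario.dentition_config, seed=scenario.seed)
    dentition = generate_quadrant(dconf)
    aligner = build_aligner(dentition, scenario.design)
    traction = TractionConfig(
        magnitude_gf=scenario.traction_gf,
        from_point=aligner.traction_attachment_point,
        to_point=dentition.tad.location)
    state = SimulationState(dentition=dentition, aligner=aligner,
                            traction=traction, config=scenario.engine)
    return state, aligner


def run_protocol(scenario: Scenario) -> Trajectory:
    """Run the staged protocol: for each 0.2 mm step, seat the staged
    aligner, solve equilibrium and remodel (``iterations_per_step`` times);
    after the prescribed steps, continue identical extension steps until
    the premolar-molar space is closed."""
    state, base_aligner = prepare_state(scenario)
    plan = scenario.staging
    initial_poses = {t.position: t.current_pose.copy()
                     for t in state.dentition.teeth}
    steps = []
    space_closed_step = None
    limit = plan.n_steps + scenario.engine.max_extension_steps
    for s in range(1, limit + 1):
        state.aligner = apply_staging(base_aligner, plan, s)
        state.step_index = s
        iter_records = []
        for it in range(1, scenario.engine.iterations_per_step + 1):
            state.iteration_index = it
            res = solve_equilibrium(state)
            iter_records.append(IterationRecord(
                step=s, iteration=it,
                max_strain_fraction=res.max_strain_fraction,
                strain_by_tooth={p: r.max_strain_fraction
                                 for p, r in res.teeth.items()},
                wall_force_md={p: r.wall_force_md for p, r in res.teeth.items()},
                active_wall={p: r.active_wall for p, r in res.teeth.items()},
                frame_dof=res.frame_dof.copy(),
                force_balance_sym=res.force_balance_sym.copy(),
                twist_increments={p: r.twist_increment.copy()
                                  for p, r in res.teeth.items()}))
            remodel(state)
        gap = state.gap_5_6()
        closed = detect_space_closed(state)
        steps.append(StepRecord(
            step=s, gap_5_6=gap, closed=closed,
            tooth_poses={t.position: t.current_pose.copy()
                         for t in state.dentition.teeth},
            iterations=iter_records, tcm=_tcm_log(plan, s)))
        if closed and space_closed_step is None:
            space_closed_step = s
        if closed and s >= plan.n_steps:
            break
    else:
        raise SpaceNotClosedError(state.gap_5_6(), limit)
    return Trajectory(design=scenario.design, scenario=scenario,
                      dentition=state.dentition, initial_poses=initial_poses,
                      steps=steps, space_closed_step=space_closed_step)


def convergence_probe(scenario: Scenario, step: int = 1,
                      iterations: int = 3) -> list:
    """Diagnostic for remodeling convergence: stage one step, then record
    the maximum PDL strain fraction of each of ``iterations`` consecutive
    solve+remodel iterations (the extra iterations do not advance any
    caller-visible protocol state — a fresh model is built here)."""
    state, base_aligner = prepare_state(scenario)
    state.aligner = apply_staging(base_aligner, scenario.staging, step)
    strains = []
    for _ in range(iterations):
        res = solve_equilibrium(state)
        strains.append(res.max_strain_fraction)
        remodel(state)
    return strains
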