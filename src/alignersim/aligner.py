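"""Clear-aligner model: rigid frame, per-tooth sockets, trim designs, staging.

The 0.7 mm thermoformed shell is reduced to a single rigid frame carrying
one socket per tooth.  A socket holds the crown's rest pose in the aligner
frame plus a diagonal stiffness in the tooth's local directions; the
mesio-distal component is carried by a pair of unilateral *walls* (mesial
and distal) that can only push, never pull.  The three trimline designs
differ exactly in which walls exist:

* ``CON``  — conventional full wrap: both walls on every tooth;
* ``SMHW`` — second-molar half wrap: no distal wall on tooth 7;
* ``MHW``  — all-molar half wrap: no distal wall on teeth 6 and 7.

A half-wrapped socket also engages only half the crown surface, so its
remaining stiffness is halved.  Staging moves the premolar sockets (4 and 5)
distally by 0.2 mm per step along their local mesio-distal direction, which
shortens the aligner span between teeth 5 and 6 and lengthens the span
between 3 and 4 by the same amount — the geometry change the
temperature-changing method (TCM) realizes in the source workflow; the TCM
temperature itself is kept as bookkeeping (:func:`tcm_temperature`).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import rigid
from .dentition import Dentition
from .pdl import ALIGNER_MATERIAL, ALIGNER_SHELL_THICKNESS, MaterialProperties


class TrimDesign(str, enum.Enum):
    CON = "con"
    SMHW = "smhw"
    MHW = "mhw"

    @classmethod
    def parse(cls, value) -> "TrimDesign":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown trim design {value!r}; expected one of "
                f"{[d.value for d in cls]}") from None


# local twist component order used for socket stiffness vectors
# (md translation, bl translation, vertical translation, rot about md,
#  rot about bl, rot about vertical)
MD, BL, VERT, ROT_MD, ROT_BL, ROT_VERT = range(6)


@dataclass
class Socket:
    """One crown socket of the aligner.

    ``wrap_stiffness`` is the effective diagonal stiffness in the socket's
    local frame, with design scale and attachment grip already applied:
    entries (N/mm, N/mm, N/mm, N*mm/rad x3).  The mesio-distal entry is the
    *wall* stiffness; whether it acts depends on the wall flags and the sign
    of the mesio-distal mismatch.
    """

    position: int
    rest_pose_in_aligner: np.ndarray      # 4x4, aligner frame == world at build
    reference_point: np.ndarray           # crown centroid at build (world)
    local_axes: np.ndarray                # 3x3, columns = md (mesial+), bl (lingual+), vertical
    wrap_stiffness: np.ndarray            # 6-vector, see above
    has_mesial_wall: bool = True
    has_distal_wall: bool = True
    stiffness_scale: float = 1.0

    def __post_init__(self):
        if np.any(self.wrap_stiffness < 0):
            raise ValueError("socket stiffnesses must be non-negative")
        if not np.any(self.wrap_stiffness > 0):
            raise ValueError("socket needs at least one retention component")

    def rotation6(self) -> np.ndarray:
        """6x6 block rotation taking local twist components to world."""
        r = np.zeros((6, 6))
        r[:3, :3] = self.local_axes
        r[3:, 3:] = self.local_axes
        return r

    def stiffness_world(self, md_active: bool = True) -> np.ndarray:
        """6x6 socket stiffness in world coordinates about the reference
        point, with the mesio-distal wall on or off."""
        k = self.wrap_stiffness.copy()
        if not md_active or not (self.has_mesial_wall or self.has_distal_wall):
            k[MD] = 0.0
        r6 = self.rotation6()
        return r6 @ np.diag(k) @ r6.T

    def wall_for_mismatch(self, delta_md: float) -> str | None:
        """Which wall carries a given mesio-distal mismatch (tooth minus
        socket rest, mesial positive), honouring unilaterality."""
        if delta_md > 0.0:
            return "mesial" if self.has_mesial_wall else None
        if delta_md < 0.0:
            return "distal" if self.has_distal_wall else None
        return "mesial" if self.has_mesial_wall else (
            "distal" if self.has_distal_wall else None)


@dataclass
class Aligner:
    sockets: list                         # Socket, ordered positions 1..7
    design: TrimDesign
    frame_pose: np.ndarray = field(default_factory=rigid.identity_pose)
    traction_attachment_point: np.ndarray | None = None
    shell_thickness: float = ALIGNER_SHELL_THICKNESS
    material: MaterialProperties = ALIGNER_MATERIAL
    staging_step: int = 0

    def __post_init__(self):
        if [s.position for s in self.sockets] != sorted(
                {s.position for s in self.sockets}):
            raise ValueError("sockets must be ordered and unique by position")

    def socket(self, position: int) -> Socket:
        for s in self.sockets:
            if s.position == position:
                return s
        raise KeyError(position)

    def to_json(self) -> str:
        payload = {
            "design": self.design.value,
            "staging_step": self.staging_step,
            "shell_thickness": self.shell_thickness,
            "frame_pose": self.frame_pose.tolist(),
            "traction_attachment_point":
                None if self.traction_attachment_point is None
                else self.traction_attachment_point.tolist(),
            "sockets": [{
                "position": s.position,
                "rest_pose": s.rest_pose_in_aligner.tolist(),
                "reference_point": s.reference_point.tolist(),
                "local_axes": s.local_axes.tolist(),
                "wrap_stiffness": s.wrap_stiffness.tolist(),
                "has_mesial_wall": s.has_mesial_wall,
                "has_distal_wall": s.has_distal_wall,
                "stiffness_scale": s.stiffness_scale,
            } for s in self.sockets],
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# build

def _design_table(design: TrimDesign) -> dict:
    """position -> (has_mesial_wall, has_distal_wall, stiffness_scale)"""
    table = {p: (True, True, 1.0) for p in range(1, 8)}
    if design is TrimDesign.SMHW:
        table[7] = (True, False, 0.5)
    elif design is TrimDesign.MHW:
        table[6] = (True, False, 0.5)
        table[7] = (True, False, 0.5)
    return table


def default_socket_stiffness(crown_height: float, crown_bl_width: float,
                             material: MaterialProperties = ALIGNER_MATERIAL,
                             shell_thickness: float = ALIGNER_SHELL_THICKNESS
                             ) -> np.ndarray:
    """Heuristic socket stiffness from shell material and crown size.

    The walls act as through-thickness compression of the shell over the
    engaged crown face plus the adjoining shell panels that shear along
    with it (the socket is a closed pocket, not a free flat wall):
    ``k_wall = E * A_wall / t_shell`` with ``A_wall = 2 * h_crown * w_bl``.
    This makes the aligner much stiffer than
    the PDL (the plastic is ~2000x stiffer than the ligament), which is
    what lets the staged geometry be transferred to the teeth within a
    couple of remodeling iterations — the convergence behaviour the
    remodeling loop is predicated on.  Bucco-lingual and vertical retention
    get half the wall stiffness; rotations engage several crown faces at
    once, with squared lever arms of order the crown half-dimensions:
    ``k_rot = k_wall * (h_crown^2 + w_bl^2) / 4``.  These are calibration
    parameters (config-exposed): the continuum shell they condense has no
    single recoverable value.
    """
    a_wall = 2.0 * crown_height * crown_bl_width
    k_wall = material.elastic_modulus * a_wall / shell_thickness
    k_lin = 0.5 * k_wall
    k_rot = k_wall * (crown_height ** 2 + crown_bl_width ** 2) / 4.0
    return np.array([k_wall, k_lin, k_lin, k_rot, k_rot, k_rot])


def build_aligner(dentition: Dentition, design,
                  material: MaterialProperties = ALIGNER_MATERIAL,
                  shell_thickness: float = ALIGNER_SHELL_THICKNESS) -> Aligner:
    """Build the aligner in stress-free fit over the current crowns.

    Socket rest poses equal the crowns' current poses, so a freshly built
    aligner exerts no force.  Wall flags and stiffness scale follow the trim
    design; attachments multiply vertical and rotational stiffness by their
    grip factor.
    """
    design = TrimDesign.parse(design)
    if len(dentition.teeth) != 7:
        raise ValueError("aligner build requires all 7 teeth")
    table = _design_table(design)
    sockets = []
    for tooth in dentition.teeth:
        mesial_wall, distal_wall, scale = table[tooth.position]
        k = default_socket_stiffness(tooth.crown_height, tooth.crown_bl_width,
                                     material, shell_thickness) * scale
        att = dentition.attachments.get(tooth.position)
        if att is not None:
            k[VERT] *= att.grip_multiplier
            k[ROT_MD:] *= att.grip_multiplier
        axes = np.column_stack([
            tooth.md_axis, tooth.bl_axis, np.array([0.0, 0.0, 1.0])])
        sockets.append(Socket(
            position=tooth.position,
            rest_pose_in_aligner=tooth.current_pose.copy(),
            reference_point=rigid.apply_pose(tooth.current_pose, tooth.centroid),
            local_axes=axes,
            wrap_stiffness=k,
            has_mesial_wall=mesial_wall,
            has_distal_wall=distal_wall,
            stiffness_scale=scale,
        ))
    canine = dentition.tooth(3)
    buccal = -canine.bl_axis
    attachment_point = (canine.cervix_center
                        + 0.5 * canine.crown_bl_width * buccal
                        + 0.25 * canine.crown_width * canine.md_axis)
    return Aligner(sockets=sockets, design=design,
                   traction_attachment_point=attachment_point,
                   shell_thickness=shell_thickness, material=material)


# ---------------------------------------------------------------------------
# staging

@dataclass(frozen=True)
class StagingPlan:
    """Prescribed aligner geometry change per step (all spans mesio-distal)."""

    n_steps: int = 10
    step_increment: float = 0.2           # mm per step
    shortened_span: tuple = (5, 6)
    lengthened_span: tuple = (3, 4)
    direction: str = "mesio-distal"

    def __post_init__(self):
        if self.n_steps < 1 or self.step_increment <= 0:
            raise ValueError("staging plan needs n_steps >= 1 and a positive increment")
        if tuple(self.shortened_span) != (5, 6) or tuple(self.lengthened_span) != (3, 4):
            raise ValueError("the premolar-distalization scenario stages spans (5,6) and (3,4)")
        if self.direction != "mesio-distal":
            raise ValueError("staging deformation is restricted to the mesio-distal direction")

    @property
    def prescribed_total(self) -> float:
        return self.n_steps * self.step_increment


def apply_staging(aligner: Aligner, plan: StagingPlan, step: int) -> Aligner:
    """Aligner rest geometry at an absolute staging step.

    Sockets 4 and 5 are translated distally by ``step * increment`` relative
    to the built geometry, purely along each socket's local mesio-distal
    axis; no bucco-lingual or vertical component is introduced.  The
    operation is incremental from the aligner's current staging step, so
    staging to ``a`` and then to ``b`` equals staging directly to ``b``.
    """
    if step < 0:
        raise ValueError("staging step must be non-negative")
    delta = (step - aligner.staging_step) * plan.step_increment
    sockets = []
    for s in aligner.sockets:
        if s.position in (4, 5) and delta != 0.0:
            mesial = s.local_axes[:, 0]
            shift = -delta * mesial  # distal translation
            rest = s.rest_pose_in_aligner.copy()
            rest[:3, 3] += shift
            sockets.append(replace(
                s, rest_pose_in_aligner=rest,
                reference_point=s.reference_point + shift))
        else:
            sockets.append(replace(s))
    return Aligner(sockets=sockets, design=aligner.design,
                   frame_pose=aligner.frame_pose.copy(),
                   traction_attachment_point=aligner.traction_attachment_point,
                   shell_thickness=aligner.shell_thickness,
                   material=aligner.material, staging_step=step)


def socket_span(aligner: Aligner, span: Sequence[int]) -> float:
    """Rest-geometry distance between two sockets projected on the
    mesio-distal direction midway between them (distal positive)."""
    a, b = aligner.socket(span[0]), aligner.socket(span[1])
    d = -(a.local_axes[:, 0] + b.local_axes[:, 0])
    d /= np.linalg.norm(d)
    return float(np.dot(b.rest_pose_in_aligner[:3, 3]
                        - a.rest_pose_in_aligner[:3, 3], d))


# ---------------------------------------------------------------------------
# temperature-changing-method bookkeeping

@dataclass(frozen=True)
class TCMParameters:
    """Symbols of the thermal-expansion trick used to deform the aligner:
    U preset deformation (mm), k linear expansion coefficient (1/degC),
    Delta deformation already accumulated (mm), d width of the deformation
    zone (mm); the output t is the temperature change (degC)."""

    U: float
    k: float = 0.01
    Delta: float = 0.0
    d: float = 2.0

    def __post_init__(self):
        if self.k <= 0 or self.d <= 0:
            raise ValueError("k and d must be positive")


def tcm_temperature(params: TCMParameters) -> float:
    """Temperature change imposing the remaining deformation ``U - Delta``
    on a zone of width d: ``t = (U - Delta) / (k d)``, so that k*d*t equals
    the rest-length change the staging engine consumes directly."""
    return (params.U - params.Delta) / (params.k * params.d)


# ---------------------------------------------------------------------------
# socket force transfer

def socket_mismatch(socket: Socket, tooth_pose: np.ndarray,
                    aligner_frame_pose: np.ndarray) -> np.ndarray:
    """Tooth pose relative to the socket rest pose, as a 6-twist at the
    socket reference point in *local* components (mesial, lingual, apical)."""
    rest_world = aligner_frame_pose @ socket.rest_pose_in_aligner
    rel = tooth_pose @ rigid.invert(rest_world)
    ref = rigid.apply_pose(aligner_frame_pose, socket.reference_point)
    delta_world = rigid.pose_to_twist(rel, ref)
    return socket.rotation6().T @ delta_world


def socket_wrench(socket: Socket, tooth_pose: np.ndarray,
                  aligner_frame_pose: np.ndarray) -> dict:
    """Unilateral socket force transfer between tooth and aligner.

    Bucco-lingual, vertical and rotational components are bilinear springs.
    The mesio-distal component is unilateral: the mesial wall only pushes
    the tooth distally (active when the tooth sits mesial of its socket),
    the distal wall only pushes mesially; an absent wall transmits nothing.
    Returns world wrenches about the socket reference point; the wrench on
    the aligner is the exact reaction.
    """
    delta = socket_mismatch(socket, tooth_pose, aligner_frame_pose)
    w_local = -socket.wrap_stiffness * delta
    wall = socket.wall_for_mismatch(delta[MD])
    if wall is None:
        w_local[MD] = 0.0
    wrench_on_tooth = socket.rotation6() @ w_local
    return {
        "wrench_on_tooth": wrench_on_tooth,
        "wrench_on_aligner": -wrench_on_tooth,
        "active_wall": wall,
        "mismatch_local": delta,
    }
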