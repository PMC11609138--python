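"""Landmarks, local coordinate frames and signed motion decomposition.

Each tooth's motion is reported as six signed quantities in a per-tooth
local frame: X mesio-distal (mesial +), Y bucco-lingual (lingual +, built
as Z x X), Z occluso-gingival aligned with the global axis (gingival +).
Displacements are those of the crown point (CP); rotations are the
components of the rotation vector of the relative rigid motion, expressed
in the local frame and converted to degrees:

* bucco-lingual torque  = X component (buccal -, lingual +),
* mesio-distal tipping  = Y component (mesial -, distal +),
* axial rotation        = Z component (mesial rotation +, distal -).

The rotation-vector decomposition is used instead of an Euler sequence: at
the few degrees of rotation that occur here the two agree to well below
0.01 degrees, and the rotation vector needs no axis-order convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rigid
from .dentition import ArchCurve, ToothModel

MAX_DECOMPOSE_ANGLE_DEG = 30.0


@dataclass(frozen=True)
class ToothLandmarks:
    cp: np.ndarray        # crown point: occlusal midpoint / incisal edge midpoint
    rp: np.ndarray        # root point: apex, or midpoint of apexes (multirooted)
    rc: np.ndarray        # resistance-center landmark (1/3 root level, or
                          # 1 mm apical of the furcation)
    la: np.ndarray        # unit long axis, CP -> RP


def tooth_landmarks(tooth: ToothModel) -> ToothLandmarks:
    """Anatomical landmark set of one tooth, in the tooth body frame."""
    cp = np.asarray(tooth.cp, float)
    if tooth.root_count == 1:
        frustum = tooth.root_surfaces[0]
        rp = np.asarray(frustum.tip_center, float)
        axis = rp - np.asarray(frustum.base_center, float)
        rc = np.asarray(frustum.base_center, float) + axis / 3.0
    else:
        if tooth.furcation_point is None:
            raise ValueError(
                f"multirooted tooth {tooth.position} lacks a furcation point")
        apexes = np.array([f.tip_center for f in tooth.root_surfaces[1:]])
        rp = apexes.mean(axis=0)
        rc = np.asarray(tooth.furcation_point, float) + np.array([0.0, 0.0, 1.0])
    la = rp - cp
    norm = np.linalg.norm(la)
    if norm <= 0:
        raise ValueError("degenerate long axis (CP coincides with RP)")
    return ToothLandmarks(cp=cp, rp=rp, rc=rc, la=la / norm)


@dataclass(frozen=True)
class LocalFrame:
    origin: np.ndarray
    x: np.ndarray   # unit mesio-distal, mesial positive
    y: np.ndarray   # unit bucco-lingual, lingual positive
    z: np.ndarray   # unit occluso-gingival, gingival (apical) positive

    def __post_init__(self):
        m = np.column_stack([self.x, self.y, self.z])
        if not np.allclose(m.T @ m, np.eye(3), atol=1e-9):
            raise ValueError("local frame must be orthonormal")
        if abs(np.linalg.det(m) - 1.0) > 1e-9:
            raise ValueError("local frame must be right-handed")

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


def build_local_frame(tooth: ToothModel, arch: ArchCurve) -> LocalFrame:
    """Local frame from the arch tangent at the tooth: Z is the global
    occluso-gingival axis, X the occlusal-plane projection of the mesial
    tangent, Y = Z x X."""
    z = np.array([0.0, 0.0, 1.0])
    x = np.asarray(arch.mesial_direction(tooth.arch_s), float)
    x = x - np.dot(x, z) * z
    norm = np.linalg.norm(x)
    if norm < 1e-12:
        raise ValueError("degenerate arch tangent at this tooth")
    x = x / norm
    y = np.cross(z, x)
    return LocalFrame(origin=np.asarray(tooth.cp, float), x=x, y=y, z=z)


@dataclass(frozen=True)
class DisplacementRecord:
    """Signed kinematic record of one tooth (mm and degrees)."""

    md_displacement: float    # mesial +, distal -
    bl_displacement: float    # buccal -, lingual +
    axial_displacement: float  # gingival +, occlusal -
    bl_torque: float          # buccal -, lingual +
    md_tipping: float         # mesial -, distal +
    axial_rotation: float     # mesial rotation +, distal -

    def as_dict(self) -> dict:
        return {
            "md_displacement": self.md_displacement,
            "bl_displacement": self.bl_displacement,
            "axial_displacement": self.axial_displacement,
            "bl_torque": self.bl_torque,
            "md_tipping": self.md_tipping,
            "axial_rotation": self.axial_rotation,
        }

    def __neg__(self) -> "DisplacementRecord":
        return DisplacementRecord(*(-v for v in (
            self.md_displacement, self.bl_displacement,
            self.axial_displacement, self.bl_torque, self.md_tipping,
            self.axial_rotation)))


QUANTITIES = ("md_displacement", "bl_displacement", "axial_displacement",
              "bl_torque", "md_tipping", "axial_rotation")


def decompose_motion(pose_before: np.ndarray, pose_after: np.ndarray,
                     frame: LocalFrame, landmarks: ToothLandmarks
                     ) -> DisplacementRecord:
    """Decompose a rigid motion into the six signed local quantities.

    CP displacement is projected on the local axes; the rotation vector of
    the relative motion supplies the three angles.  Rotations beyond 30
    degrees are outside the decomposition's intended range and rejected.
    """
    for pose in (pose_before, pose_after):
        if not rigid.is_rigid(pose):
            raise ValueError("poses must be proper rigid transforms")
    rel = rigid.relative_pose(pose_before, pose_after)
    w = rigid.matrix_to_rotvec(rel[:3, :3])
    angle_deg = np.degrees(np.linalg.norm(w))
    if angle_deg > MAX_DECOMPOSE_ANGLE_DEG:
        raise ValueError(
            f"rotation of {angle_deg:.1f} deg exceeds the small-angle "
            f"decomposition range ({MAX_DECOMPOSE_ANGLE_DEG} deg)")
    d = (rigid.apply_pose(pose_after, landmarks.cp)
         - rigid.apply_pose(pose_before, landmarks.cp))
    w_local = frame.matrix.T @ w
    return DisplacementRecord(
        md_displacement=float(np.dot(d, frame.x)),
        bl_displacement=float(np.dot(d, frame.y)),
        axial_displacement=float(np.dot(d, frame.z)),
        bl_torque=float(np.degrees(w_local[0])),
        md_tipping=float(np.degrees(w_local[1])),
        axial_rotation=float(np.degrees(w_local[2])),
    )


def recompose_motion(record: DisplacementRecord, frame: LocalFrame,
                     cp_before: np.ndarray) -> np.ndarray:
    """Rigid motion with the given CP displacement and local rotation
    vector — the exact inverse of :func:`decompose_motion` (as the relative
    world transform)."""
    w_local = np.radians([record.bl_torque, record.md_tipping,
                          record.axial_rotation])
    w = frame.matrix @ w_local
    d = (record.md_displacement * frame.x
         + record.bl_displacement * frame.y
         + record.axial_displacement * frame.z)
    r = rigid.rotvec_to_matrix(w)
    cp = np.asarray(cp_before, float)
    return rigid.make_pose(r, cp + d - r @ cp)
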