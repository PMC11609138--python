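"""Small helpers for proper rigid transforms (4x4, row-major) and twists.

Conventions used across the package: lengths in mm, right-handed global
frame with the occlusal plane at Z = 0 and the apical (gingival) direction
along +Z, the median sagittal plane at X = 0 and the anterior direction
along +Y.  A *twist* is a 6-vector ``(ux, uy, uz, wx, wy, wz)`` — a small
translation plus a rotation vector — taken about a stated reference point.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def identity_pose() -> np.ndarray:
    return np.eye(4)


def make_pose(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    pose = np.eye(4)
    pose[:3, :3] = rotation
    pose[:3, 3] = translation
    return pose


def is_rigid(pose: np.ndarray, tol: float = 1e-8) -> bool:
    if pose.shape != (4, 4):
        return False
    r = pose[:3, :3]
    return (
        np.allclose(r @ r.T, np.eye(3), atol=tol)
        and abs(np.linalg.det(r) - 1.0) < tol
        and np.allclose(pose[3], [0, 0, 0, 1], atol=tol)
    )


def apply_pose(pose: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to one point or an (N, 3) array of points."""
    points = np.asarray(points, dtype=float)
    return points @ pose[:3, :3].T + pose[:3, 3]


def rotate_only(pose: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    return np.asarray(vectors, dtype=float) @ pose[:3, :3].T


def compose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pose that applies ``b`` first, then ``a``."""
    return a @ b


def invert(pose: np.ndarray) -> np.ndarray:
    r = pose[:3, :3]
    out = np.eye(4)
    out[:3, :3] = r.T
    out[:3, 3] = -r.T @ pose[:3, 3]
    return out


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotvec_to_matrix(w: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(w, dtype=float)).as_matrix()


def matrix_to_rotvec(r: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(np.asarray(r, dtype=float)).as_rotvec()


def twist_to_pose(twist: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Finite rigid motion realizing a twist about ``reference``.

    The rotation acts about the reference point, the translation is added on
    top, so a point p maps to ``R (p - ref) + ref + u``.
    """
    u, w = np.asarray(twist[:3], float), np.asarray(twist[3:], float)
    r = rotvec_to_matrix(w)
    ref = np.asarray(reference, dtype=float)
    return make_pose(r, ref + u - r @ ref)


def pose_to_twist(pose: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Inverse of :func:`twist_to_pose` (exact, not small-angle)."""
    w = matrix_to_rotvec(pose[:3, :3])
    ref = np.asarray(reference, dtype=float)
    u = apply_pose(pose, ref) - ref
    return np.concatenate([u, w])


def relative_pose(pose_before: np.ndarray, pose_after: np.ndarray) -> np.ndarray:
    """World-frame motion taking the body from ``pose_before`` to ``pose_after``."""
    return pose_after @ invert(pose_before)


def point_velocity_map(point: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """3x6 map from a twist about ``reference`` to the displacement of ``point``."""
    j = np.zeros((3, 6))
    j[:, :3] = np.eye(3)
    j[:, 3:] = -skew(np.asarray(point, float) - np.asarray(reference, float))
    return j


def shift_twist_reference(twist: np.ndarray, old_ref: np.ndarray,
                          new_ref: np.ndarray) -> np.ndarray:
    """Re-express a small twist about a different reference point."""
    u, w = np.asarray(twist[:3], float), np.asarray(twist[3:], float)
    u_new = u + np.cross(w, np.asarray(new_ref, float) - np.asarray(old_ref, float))
    return np.concatenate([u_new, w])
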