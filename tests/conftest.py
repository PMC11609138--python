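"""Shared fixtures: default quadrant, axisymmetric oracle tooth, staged runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import alignersim as asim
from alignersim.dentition import RootFrustum, ToothModel

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def make_cone_tooth(root_length: float = 13.0, cervical_radius: float = 3.0,
                    tip_radius: float = 0.0) -> ToothModel:
    """Single-cone tooth on the global Z axis (axisymmetric PDL support)."""
    cervix = np.array([0.0, 0.0, 8.0])
    apex = cervix + np.array([0.0, 0.0, root_length])
    return ToothModel(
        position=4, crown_width=7.0, crown_bl_width=9.0, crown_height=8.0,
        root_surfaces=[RootFrustum(cervix, apex, cervical_radius,
                                   tip_radius)],
        root_count=1,
        centroid=np.array([0.0, 0.0, 4.0]),
        cp=np.zeros(3),
        cervix_center=cervix,
        mesial_contact_point=np.array([3.5, 0.0, 3.5]),
        distal_contact_point=np.array([-3.5, 0.0, 3.5]),
        md_axis=np.array([1.0, 0.0, 0.0]),
        bl_axis=np.array([0.0, 1.0, 0.0]),
        arch_s=0.0)


def finite_rotation_energy(samples, twist, reference, moduli) -> float:
    """Independent spring-field energy with *exact* finite rotations, used
    to cross-check the assembled stiffness via numerical differentiation."""
    from scipy.spatial.transform import Rotation

    u = np.asarray(twist[:3], float)
    w = np.asarray(twist[3:], float)
    r = Rotation.from_rotvec(w).as_matrix()
    ref = np.asarray(reference, float)
    moved = (samples.points - ref) @ r.T + ref + u
    d = moved - samples.points
    d_n = np.einsum("ni,ni->n", d, samples.normals)
    d_sq = np.einsum("ni,ni->n", d, d)
    e = 0.5 * samples.areas * (moduli.k_tangential * d_sq
                               + (moduli.k_normal - moduli.k_tangential)
                               * d_n ** 2)
    return float(e.sum())


def energy_hessian(samples, reference, moduli, h: float = 1e-3) -> np.ndarray:
    """Central-difference Hessian of the finite-rotation energy at zero."""
    def e(t):
        return finite_rotation_energy(samples, t, reference, moduli)

    hess = np.zeros((6, 6))
    e0 = e(np.zeros(6))
    for i in range(6):
        ei = np.zeros(6)
        ei[i] = h
        hess[i, i] = (e(ei) + e(-ei) - 2.0 * e0) / h ** 2
        for j in range(i + 1, 6):
            ej = np.zeros(6)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                e(ei + ej) - e(ei - ej) - e(-ei + ej) + e(-ei - ej)
            ) / (4.0 * h ** 2)
    return hess


@pytest.fixture(scope="session")
def dentition():
    return asim.generate_quadrant(asim.DentitionConfig())


@pytest.fixture(scope="session")
def cone_tooth():
    return make_cone_tooth()


@pytest.fixture(scope="session")
def staged_runs():
    """One staged run per trim design on the default synthetic arch."""
    return {d: asim.run_protocol(asim.Scenario(design=asim.TrimDesign.parse(d)))
            for d in ("con", "smhw", "mhw")}


@pytest.fixture(scope="session")
def joint_report(staged_runs):
    return asim.build_report(staged_runs)
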