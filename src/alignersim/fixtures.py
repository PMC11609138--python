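"""Deterministic small fixtures used by the test suite and the CLI.

``table3`` transcribes the published space-closed-step displacement and
rotation table of the three-design premolar-distalization study (signs per
its footnote: mesial/lingual/gingival/distal-tipping positive, etc.).  It
exercises the reporting and metric arithmetic on known values; it is not
produced by this package's simulation.

``one_tooth`` is a minimal synthetic scene whose equilibrium has the exact
springs-in-series closed form, used as an engine oracle.

``default_arch`` is simply the default synthetic quadrant.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .aligner import Aligner, Socket, TrimDesign
from .dentition import (Dentition, DentitionConfig, PdlSampleField,
                        RootFrustum, ToothModel, export_scene,
                        generate_quadrant)
from .engine import EngineConfig, SimulationState
from .measurement import QUANTITIES
from .pdl import default_pdl_moduli

# Published space-closed-step kinematics (mm / degrees), teeth 1-7.
_TABLE3 = {
    "md_displacement": {
        "con":  (0.11, 0.35, 0.73, -1.69, -1.70, 0.41, 0.41),
        "smhw": (0.14, 0.44, 0.92, -1.50, -1.51, 0.60, 0.11),
        "mhw":  (0.18, 0.57, 1.19, -1.91, -1.93, 0.17, 0.02),
    },
    "bl_displacement": {
        "con":  (-0.66, -0.66, -0.35, 0.16, 0.16, -0.02, -0.01),
        "smhw": (-0.83, -0.83, -0.43, 0.15, 0.14, -0.11, -0.04),
        "mhw":  (-1.08, -1.06, -0.51, 0.13, 0.14, -0.02, -0.01),
    },
    "axial_displacement": {
        "con":  (0.03, 0.02, -0.07, 0.22, 0.29, 0.17, 0.17),
        "smhw": (0.05, 0.02, -0.07, 0.20, 0.24, 0.21, 0.06),
        "mhw":  (0.06, 0.02, -0.08, 0.19, 0.23, 0.13, 0.01),
    },
    "bl_torque": {
        "con":  (-1.82, -1.44, -1.27, 1.73, 1.71, 0.44, 0.88),
        "smhw": (-2.38, -1.68, -1.39, 1.51, 1.22, 0.20, 0.19),
        "mhw":  (-3.19, -2.81, -1.48, 1.40, 1.12, 0.06, 0.02),
    },
    "md_tipping": {
        "con":  (-0.18, -0.38, -2.15, 4.10, 4.55, -1.78, -1.93),
        "smhw": (-0.19, -0.59, -2.31, 3.65, 4.18, -2.02, -0.80),
        "mhw":  (-0.22, -0.73, -2.62, 5.49, 5.08, -1.52, -0.20),
    },
    "axial_rotation": {
        "con":  (0.53, 0.59, 0.63, 1.23, 2.13, 0.16, 0.20),
        "smhw": (0.42, 0.37, 0.44, 1.07, 1.95, 0.22, 0.12),
        "mhw":  (0.53, 0.38, 0.38, 1.11, 1.92, 0.14, 0.04),
    },
}

TABLE3_SPACE_CLOSED_STEP = {"con": 11, "smhw": 12, "mhw": 13}


def table3_frame() -> pd.DataFrame:
    """Long-format published kinematics: design, tooth, six quantity columns."""
    rows = []
    for design in ("con", "smhw", "mhw"):
        for tooth in range(1, 8):
            rows.append({
                "design": design, "tooth": tooth,
                **{q: _TABLE3[q][design][tooth - 1] for q in QUANTITIES}})
    return pd.DataFrame(rows)


def one_tooth_scene(k_pdl_area: float = 10.0, k_socket: float = 500.0,
                    delta: float = 0.1) -> dict:
    """Single tooth, isotropic symmetric spring field, one bilateral
    bucco-lingual socket DOF with rest offset ``delta`` along +y, aligner
    frame grounded.  The equilibrium displacement has the springs-in-series
    closed form ``delta * k_socket / (k_pdl + k_socket)``.
    """
    cervix = np.array([0.0, 0.0, 8.0])
    tooth = ToothModel(
        position=1, crown_width=8.0, crown_bl_width=8.0, crown_height=8.0,
        root_surfaces=[RootFrustum(cervix, cervix + [0.0, 0.0, 12.0], 3.0, 0.75)],
        root_count=1,
        centroid=np.array([0.0, 0.0, 4.0]),
        cp=np.zeros(3), cervix_center=cervix,
        mesial_contact_point=np.array([4.0, 0.0, 3.5]),
        distal_contact_point=np.array([-4.0, 0.0, 3.5]),
        md_axis=np.array([1.0, 0.0, 0.0]),
        bl_axis=np.array([0.0, 1.0, 0.0]),
        arch_s=0.0)
    # six unit-area samples symmetric about the centroid: diagonal support,
    # no translation-rotation coupling
    c = tooth.centroid
    offsets = np.vstack([np.eye(3), -np.eye(3)]) * 5.0
    normals = np.vstack([np.eye(3), -np.eye(3)])
    samples = PdlSampleField(points=c + offsets, normals=normals,
                             areas=np.full(6, float(k_pdl_area)))
    moduli = default_pdl_moduli()
    # translational y-stiffness of this field (2 normal + 4 tangential springs)
    k_pdl_y = k_pdl_area * (2.0 * moduli.k_normal + 4.0 * moduli.k_tangential)

    rest = np.eye(4)
    rest[:3, 3] = [0.0, delta, 0.0]
    socket = Socket(
        position=1, rest_pose_in_aligner=rest,
        reference_point=c + np.array([0.0, delta, 0.0]),
        local_axes=np.eye(3),
        wrap_stiffness=np.array([0.0, k_socket, 0.0, 0.0, 0.0, 0.0]),
        has_mesial_wall=True, has_distal_wall=True)
    aligner = Aligner(sockets=[socket], design=TrimDesign.CON)

    dentition = Dentition(config=DentitionConfig(), arch=None, teeth=[tooth],
                          attachments={})
    config = EngineConfig(fix_aligner_frame=True, pdl_samples_per_tooth=20)
    state = SimulationState(dentition=dentition, aligner=aligner,
                            traction=None, config=config, moduli=moduli)
    state._body_samples[1] = samples
    expected = delta * k_socket / (k_pdl_y + k_socket)
    return {"state": state, "tooth": tooth, "samples": samples,
            "k_pdl_y": k_pdl_y, "k_socket": k_socket, "delta": delta,
            "expected_displacement": expected}


_FIXTURES = ("table3", "one_tooth", "default_arch")


def make_fixture(name: str, outdir: str | Path | None = None):
    """Build a named fixture; optionally write its file form under outdir."""
    if name == "table3":
        frame = table3_frame()
        if outdir is not None:
            path = Path(outdir) / "table3.csv"
            path.parent.mkdir(parents=True, exist_ok=True)
            frame.to_csv(path, index=False, lineterminator="\n")
        return frame
    if name == "one_tooth":
        return one_tooth_scene()
    if name == "default_arch":
        dentition = generate_quadrant(DentitionConfig())
        if outdir is not None:
            export_scene(dentition, outdir)
        return dentition
    raise ValueError(
        f"unknown fixture {name!r}; available fixtures: {list(_FIXTURES)}")
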