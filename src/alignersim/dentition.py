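"""Parametric right maxillary quadrant generator.

Builds the post-molar-distalization starting configuration used throughout
the package: seven rigid teeth (FDI quadrant 1, positions 1-7 = central
incisor ... second molar) placed along a quartic arch curve in the occlusal
plane, with a configurable gap (default 2.0 mm) between the second premolar
and the first molar, tapered-cone root surfaces carrying a 0.30 mm
periodontal-ligament (PDL) layer, rectangular attachments and a buccal
inter-radicular mini-implant (TAD) anchor.

Global frame: right-handed, lengths in mm.  Occlusal plane = Z = 0 with the
apical (gingival) direction along +Z; median sagittal plane = X = 0 with the
quadrant on X >= 0; anterior = +Y.  Each tooth also carries its local
mesio-distal axis (unit vector pointing mesially, i.e. toward the midline
along the arch) and bucco-lingual axis (Z x mesial, so lingual is positive),
which the measurement module turns into the local reporting frames.

Root geometry is deliberately simple — frusta of cones — but the cervical
radii are chosen so each tooth's lateral root area matches mean human root
surface areas reported in the periodontal literature (roughly 204, 179, 273,
234, 220, 433, 431 mm^2 for positions 1-7).  The root surface area is what
sets the stiffness of the elastic PDL foundation, so it is the feature worth
matching; the cross-sectional shape is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import rigid

# ---------------------------------------------------------------------------
# configuration

_DEFAULT_CROWN_WIDTHS = (8.5, 6.5, 7.5, 7.0, 7.0, 10.0, 9.5)  # mesio-distal
_DEFAULT_CROWN_HEIGHTS = (10.5, 9.5, 10.0, 8.5, 8.0, 7.5, 7.0)
_DEFAULT_CROWN_BL_WIDTHS = (7.0, 6.5, 8.0, 9.0, 9.0, 11.0, 10.5)
_DEFAULT_ROOT_LENGTHS = (13.0, 13.0, 16.0, 14.0, 14.0, 12.0, 11.0)
_DEFAULT_ROOT_COUNTS = (1, 1, 1, 1, 1, 3, 3)
# cervical (or trunk) radii tuned to anatomical root surface areas, see module docstring
_DEFAULT_CERVICAL_RADII = (4.0, 3.5, 4.35, 4.25, 4.0, 4.5, 4.5)
_DEFAULT_BRANCH_RADII = {6: 3.2, 7: 3.5}  # molar root-branch cervical radii
_ROOT_TAPER = 0.25          # apex radius as a fraction of the cervical radius
_FURCATION_DEPTH = 3.0      # mm apical of the cervix, molars
_BRANCH_SPREAD = 2.5        # horizontal apex offset of molar root branches, mm
_CONTACT_HEIGHT = 3.5       # Z of inter-proximal contact points, mm


@dataclass(frozen=True)
class DentitionConfig:
    """Generator configuration; all lengths in mm."""

    arch_depth: float = 42.0
    arch_width: float = 60.0
    crown_widths: tuple = _DEFAULT_CROWN_WIDTHS
    crown_heights: tuple = _DEFAULT_CROWN_HEIGHTS
    crown_bl_widths: tuple = _DEFAULT_CROWN_BL_WIDTHS
    root_lengths: tuple = _DEFAULT_ROOT_LENGTHS
    root_counts: tuple = _DEFAULT_ROOT_COUNTS
    cervical_radii: tuple = _DEFAULT_CERVICAL_RADII
    gap_premolar2_molar1: float = 2.0
    gap_span: tuple = (5, 6)
    pdl_thickness: float = 0.30
    alveolar_crest_level: float = 10.0  # mm below (apical of) the occlusal plane
    attachment_positions: tuple = (4, 5, 6, 7)
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("crown_widths", "crown_heights", "crown_bl_widths",
                     "root_lengths", "root_counts", "cervical_radii"):
            vals = getattr(self, name)
            if len(vals) != 7:
                raise ValueError(f"{name} must configure exactly 7 teeth, got {len(vals)}")
            if any(v <= 0 for v in vals):
                raise ValueError(f"{name} entries must be positive")
        if self.arch_depth <= 0 or self.arch_width <= 0:
            raise ValueError("arch dimensions must be positive")
        if self.gap_premolar2_molar1 < 0:
            raise ValueError("gap must be non-negative")
        if tuple(self.gap_span) != (5, 6):
            raise ValueError("the distalization gap is fixed between positions 5 and 6")
        if self.pdl_thickness <= 0 or self.alveolar_crest_level <= 0:
            raise ValueError("pdl_thickness and alveolar_crest_level must be positive")
        if any(c not in (1, 2, 3) for c in self.root_counts):
            raise ValueError("root counts must be 1, 2 or 3")


# ---------------------------------------------------------------------------
# arch curve

class ArchCurve:
    """Quartic arch form ``y(x) = depth * (1 - (2x / width)^4)`` for x >= 0.

    Parameterized by arc length s measured from the midline (x = 0); s
    increases distally.  A dense precomputed table supplies point, tangent
    and inverse lookups; everything is deterministic.
    """

    def __init__(self, depth: float, width: float, x_max: float = 45.0, n: int = 9001):
        self.depth = float(depth)
        self.width = float(width)
        x = np.linspace(0.0, x_max, n)
        y = self._y(x)
        seg = np.hypot(np.diff(x), np.diff(y))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        self._x, self._y_tab, self._s = x, y, s

    def _y(self, x):
        return self.depth * (1.0 - (2.0 * np.asarray(x) / self.width) ** 4)

    def _dydx(self, x):
        return -self.depth * 8.0 / self.width * (2.0 * np.asarray(x) / self.width) ** 3

    @property
    def total_length(self) -> float:
        return float(self._s[-1])

    def point_at(self, s):
        """Occlusal-plane point (x, y, 0) at arc length ``s``."""
        x = np.interp(s, self._s, self._x)
        return np.array([x, float(self._y(x)), 0.0]) if np.isscalar(s) else \
            np.column_stack([x, self._y(x), np.zeros_like(x)])

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent in the direction of increasing s (mesial -> distal)."""
        x = float(np.interp(s, self._s, self._x))
        t = np.array([1.0, float(self._dydx(x)), 0.0])
        return t / np.linalg.norm(t)

    def mesial_direction(self, s) -> np.ndarray:
        """Unit vector pointing mesially (toward the midline) at arc length s."""
        return -self.tangent_at(s)


# ---------------------------------------------------------------------------
# tooth geometry

@dataclass(frozen=True)
class RootFrustum:
    """Tapered-cone root segment in the tooth body frame."""

    base_center: np.ndarray   # cervical (or furcation) end
    tip_center: np.ndarray    # apical end
    base_radius: float
    tip_radius: float

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.tip_center - self.base_center))

    @property
    def lateral_area(self) -> float:
        """Closed-form lateral surface area of the frustum."""
        slant = np.hypot(self.length, self.base_radius - self.tip_radius)
        return float(np.pi * (self.base_radius + self.tip_radius) * slant)


@dataclass
class PdlSampleField:
    """Discretized PDL interface: surface points, outward normals, areas.

    Stored in the tooth body frame; areas are pose-invariant by construction
    (a rigid pose update only rotates points and normals).
    """

    points: np.ndarray    # (N, 3)
    normals: np.ndarray   # (N, 3), unit, outward (root -> PDL)
    areas: np.ndarray     # (N,), mm^2

    def transformed(self, pose: np.ndarray) -> "PdlSampleField":
        return PdlSampleField(
            points=rigid.apply_pose(pose, self.points),
            normals=rigid.rotate_only(pose, self.normals),
            areas=self.areas,
        )

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())


@dataclass
class ToothModel:
    """Rigid tooth: parametric crown box + frustum roots + landmarks.

    Landmark points are stored in the body frame, which coincides with the
    world frame at generation time (``stress_free_pose`` and ``current_pose``
    start as the identity).
    """

    position: int                      # 1-7 (FDI 11-17)
    crown_width: float                 # mesio-distal, mm
    crown_bl_width: float
    crown_height: float
    root_surfaces: list                # list[RootFrustum]
    root_count: int
    centroid: np.ndarray               # crown centroid, body frame
    cp: np.ndarray                     # crown point (occlusal midpoint)
    cervix_center: np.ndarray
    mesial_contact_point: np.ndarray
    distal_contact_point: np.ndarray
    md_axis: np.ndarray                # unit, points mesially
    bl_axis: np.ndarray                # unit, points lingually (Z x md)
    arch_s: float                      # arc-length coordinate of the tooth center
    furcation_point: np.ndarray | None = None
    stress_free_pose: np.ndarray = field(default_factory=rigid.identity_pose)
    current_pose: np.ndarray = field(default_factory=rigid.identity_pose)

    def __post_init__(self):
        if not (1 <= self.position <= 7):
            raise ValueError("tooth position must be 1..7")
        for pose in (self.stress_free_pose, self.current_pose):
            if not rigid.is_rigid(pose):
                raise ValueError("tooth poses must be proper rigid transforms")

    @property
    def root_axis_point(self) -> np.ndarray:
        return self.cervix_center

    def crown_mesh(self):
        """Crown as a trimesh box in the tooth's local frame (for export)."""
        import trimesh

        z = np.array([0.0, 0.0, 1.0])
        x = -self.md_axis  # distal, so the frame below is right-handed
        y = np.cross(z, x)
        frame = np.eye(4)
        frame[:3, 0], frame[:3, 1], frame[:3, 2] = x, y, z
        frame[:3, 3] = self.centroid
        box = trimesh.creation.box(
            extents=(self.crown_width, self.crown_bl_width, self.crown_height),
            transform=self.current_pose @ frame,
        )
        return box


# ---------------------------------------------------------------------------
# attachments / TAD

@dataclass(frozen=True)
class AttachmentSpec:
    """Conventional rectangular attachment on the buccal crown face."""

    position: int
    shape: tuple = (3.0, 2.0, 1.0)   # mm, occluso-gingival x mesio-distal x prominence
    face: str = "buccal"
    grip_multiplier: float = 1.5

    def __post_init__(self):
        if self.grip_multiplier < 1.0:
            raise ValueError("grip_multiplier must be >= 1")


@dataclass(frozen=True)
class TadAnchor:
    """Buccal inter-radicular mini-implant between positions 6 and 7."""

    location: np.ndarray
    description: str = "inter-radicular, buccal, between positions 6 and 7"


# ---------------------------------------------------------------------------
# dentition container

@dataclass
class Dentition:
    config: DentitionConfig
    arch: ArchCurve
    teeth: list                      # list[ToothModel], positions 1..7
    attachments: dict                # position -> AttachmentSpec
    tad: TadAnchor | None = None

    def tooth(self, position: int) -> ToothModel:
        return self.teeth[position - 1]

    @property
    def crest_plane_z(self) -> float:
        return self.config.alveolar_crest_level

    def gap_5_6(self) -> float:
        """Signed mesio-distal gap between the distal contact of tooth 5 and
        the mesial contact of tooth 6, under current poses (positive = open)."""
        t5, t6 = self.tooth(5), self.tooth(6)
        p5 = rigid.apply_pose(t5.current_pose, t5.distal_contact_point)
        p6 = rigid.apply_pose(t6.current_pose, t6.mesial_contact_point)
        # distal direction midway between the two teeth
        d = 0.5 * (-t5.md_axis - t6.md_axis)
        d /= np.linalg.norm(d)
        return float(np.dot(p6 - p5, d))


# ---------------------------------------------------------------------------
# generation

def _build_roots(position: int, config: DentitionConfig, cervix: np.ndarray,
                 md_axis: np.ndarray, bl_axis: np.ndarray) -> tuple:
    """Return (root_surfaces, furcation_point, apexes) in the body frame."""
    i = position - 1
    length = config.root_lengths[i]
    r0 = config.cervical_radii[i]
    z = np.array([0.0, 0.0, 1.0])
    if config.root_counts[i] == 1:
        apex = cervix + length * z
        roots = [RootFrustum(cervix, apex, r0, _ROOT_TAPER * r0)]
        return roots, None, [apex]
    # multirooted: cylindrical trunk to the furcation, then tapered branches
    if length <= _FURCATION_DEPTH:
        raise ValueError("molar root length must exceed the furcation depth")
    furcation = cervix + _FURCATION_DEPTH * z
    trunk = RootFrustum(cervix, furcation, r0, r0)
    branch_len = length - _FURCATION_DEPTH
    rb = _DEFAULT_BRANCH_RADII.get(position, 0.75 * r0)
    buccal = -bl_axis
    offsets = {
        2: [0.5 * (md_axis + buccal), 0.5 * (-md_axis - buccal)],
        3: [md_axis * 0.5 + buccal * 0.87, -md_axis * 0.5 + buccal * 0.87, -buccal],
    }[config.root_counts[i]]
    roots, apexes = [trunk], []
    for off in offsets:
        apex = furcation + branch_len * z + _BRANCH_SPREAD * np.asarray(off)
        roots.append(RootFrustum(furcation, apex, rb, _ROOT_TAPER * rb))
        apexes.append(apex)
    return roots, furcation, apexes


def generate_quadrant(config: DentitionConfig | None = None) -> Dentition:
    """Generate the parametric right quadrant in its starting configuration.

    Teeth are placed by arc length along the arch curve: adjacent crowns
    share their inter-proximal contact point, except for the prescribed gap
    between positions 5 and 6.  Deterministic for a fixed seed.
    """
    config = config or DentitionConfig()
    arch = ArchCurve(config.arch_depth, config.arch_width)
    rng = np.random.default_rng(config.seed)

    # arc-length span of each crown; the gap sits between teeth 5 and 6
    starts, s = [], 0.0
    for i in range(7):
        if i == 5:
            s += config.gap_premolar2_molar1
        starts.append(s)
        s += config.crown_widths[i]
    if s > arch.total_length:
        raise ValueError("arch curve too short for the configured crowns")

    teeth = []
    for i in range(7):
        w = config.crown_widths[i]
        s_mesial, s_distal = starts[i], starts[i] + w
        s_center = starts[i] + 0.5 * w
        center_occl = arch.point_at(s_center)
        if config.jitter_sigma > 0:
            center_occl = center_occl + np.append(
                rng.normal(0.0, config.jitter_sigma, 2), 0.0)
        md_axis = arch.mesial_direction(s_center)
        bl_axis = np.cross([0.0, 0.0, 1.0], md_axis)  # lingual positive
        h = config.crown_heights[i]
        centroid = center_occl + np.array([0.0, 0.0, 0.5 * h])
        cervix = center_occl + np.array([0.0, 0.0, h])
        roots, furcation, _ = _build_roots(i + 1, config, cervix, md_axis, bl_axis)
        contact_z = np.array([0.0, 0.0, _CONTACT_HEIGHT])
        teeth.append(ToothModel(
            position=i + 1,
            crown_width=w,
            crown_bl_width=config.crown_bl_widths[i],
            crown_height=h,
            root_surfaces=roots,
            root_count=config.root_counts[i],
            centroid=centroid,
            cp=center_occl,
            cervix_center=cervix,
            mesial_contact_point=arch.point_at(s_mesial) + contact_z,
            distal_contact_point=arch.point_at(s_distal) + contact_z,
            md_axis=md_axis,
            bl_axis=bl_axis,
            arch_s=s_center,
            furcation_point=furcation,
        ))

    attachments = {p: AttachmentSpec(position=p) for p in config.attachment_positions}
    dentition = Dentition(config=config, arch=arch, teeth=teeth,
                          attachments=attachments)
    dentition.tad = place_tad(dentition)
    return dentition


def place_tad(dentition: Dentition) -> TadAnchor:
    """Buccal inter-radicular TAD, 4.0 mm apical of the alveolar crest plane,
    mesio-distally between the root axes of teeth 6 and 7."""
    t6, t7 = dentition.tooth(6), dentition.tooth(7)
    s_mid = 0.5 * (t6.arch_s + t7.arch_s)
    base = dentition.arch.point_at(s_mid)
    lingual = np.cross([0.0, 0.0, 1.0], dentition.arch.mesial_direction(s_mid))
    buccal = -lingual / np.linalg.norm(lingual)
    # buccal of the arch by half a molar width plus clearance
    offset = 0.5 * max(t6.crown_bl_width, t7.crown_bl_width) + 1.0
    z = dentition.crest_plane_z + 4.0
    location = base + offset * buccal + np.array([0.0, 0.0, z])
    return TadAnchor(location=location)


# ---------------------------------------------------------------------------
# PDL interface sampling

def _sample_frustum(frustum: RootFrustum, n_s: int, n_theta: int) -> PdlSampleField:
    base = np.asarray(frustum.base_center, float)
    tip = np.asarray(frustum.tip_center, float)
    axis = tip - base
    length = np.linalg.norm(axis)
    if length <= 0:
        raise ValueError("degenerate (zero-length) root segment")
    a_hat = axis / length
    # deterministic orthonormal frame around the axis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_vec, a_hat)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a_hat, seed_vec)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a_hat, e1)

    u = (np.arange(n_s) + 0.5) / n_s
    theta = (np.arange(n_theta) + 0.5) * (2.0 * np.pi / n_theta)
    uu, tt = np.meshgrid(u, theta, indexing="ij")
    uu, tt = uu.ravel(), tt.ravel()
    r = frustum.base_radius + (frustum.tip_radius - frustum.base_radius) * uu
    radial = np.outer(np.cos(tt), e1) + np.outer(np.sin(tt), e2)
    points = base + np.outer(uu * length, a_hat) + radial * r[:, None]
    # surface tangents d/du and d/dtheta of P(u, theta)
    dr = frustum.tip_radius - frustum.base_radius
    du = length * a_hat + dr * radial
    dtheta = (np.outer(-np.sin(tt), e1) + np.outer(np.cos(tt), e2)) * r[:, None]
    cross = np.cross(du, dtheta)
    mag = np.linalg.norm(cross, axis=1)
    normals = -cross / mag[:, None]   # oriented outward (away from the axis)
    areas = mag * (1.0 / n_s) * (2.0 * np.pi / n_theta)
    return PdlSampleField(points=points, normals=normals, areas=areas)


def sample_root_surface(tooth: ToothModel, target_count: int = 400,
                        frame: str = "body") -> PdlSampleField:
    """Discretize the tooth's root (PDL interface) into surface springs.

    The per-sample tributary areas use the exact surface element of each
    frustum, so their sum converges to the closed-form lateral area.  With
    ``frame="world"`` the samples are returned under the current pose; areas
    are identical in either frame.
    """
    if target_count < 20:
        raise ValueError("target_count must be >= 20")
    total_area = sum(f.lateral_area for f in tooth.root_surfaces)
    fields = []
    for frustum in tooth.root_surfaces:
        share = max(12, int(round(target_count * frustum.lateral_area / total_area)))
        n_theta = max(6, int(round(np.sqrt(share))))
        n_s = max(2, int(round(share / n_theta)))
        fields.append(_sample_frustum(frustum, n_s, n_theta))
    merged = PdlSampleField(
        points=np.vstack([f.points for f in fields]),
        normals=np.vstack([f.normals for f in fields]),
        areas=np.concatenate([f.areas for f in fields]),
    )
    if frame == "world":
        return merged.transformed(tooth.current_pose)
    if frame != "body":
        raise ValueError("frame must be 'body' or 'world'")
    return merged


# ---------------------------------------------------------------------------
# scene export

def export_scene(dentition: Dentition, outdir: str | Path) -> Path:
    """Write per-tooth crown meshes (PLY) and a landmark/pose JSON file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landmarks = {}
    for tooth in dentition.teeth:
        mesh = tooth.crown_mesh()
        mesh.export(outdir / f"tooth_{tooth.position}.ply", file_type="ply",
                    encoding="ascii")
        landmarks[str(tooth.position)] = {
            "position": tooth.position,
            "CP": tooth.cp.tolist(),
            "RP_region": [f.tip_center.tolist() for f in tooth.root_surfaces],
            "cervix": tooth.cervix_center.tolist(),
            "mesial_contact": tooth.mesial_contact_point.tolist(),
            "distal_contact": tooth.distal_contact_point.tolist(),
            "stress_free_pose": tooth.stress_free_pose.tolist(),
            "current_pose": tooth.current_pose.tolist(),
        }
    payload = {
        "teeth": landmarks,
        "tad": dentition.tad.location.tolist() if dentition.tad else None,
        "crest_plane_z": dentition.crest_plane_z,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(dentition.config).items()},
    }
    path = outdir / "scene.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def default_config(**overrides) -> DentitionConfig:
    """Convenience: the default study configuration with keyword overrides."""
    return replace(DentitionConfig(), **overrides) if overrides else DentitionConfig()
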