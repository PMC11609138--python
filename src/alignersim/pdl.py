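"""Periodontal ligament as a linear elastic spring foundation.

The 0.30 mm PDL layer between root and alveolar bone is reduced to a
Winkler-type foundation on the sampled root surface: each surface sample
carries a normal spring with the confined (oedometric) modulus of the layer
and tangential springs with its shear modulus, each divided by the layer
thickness.  Summing the per-spring stiffnesses through the rigid-body
point-velocity map gives the 6x6 support stiffness of the tooth about any
reference point; the bone side of the layer is taken as rigid ground.

Units: N, mm, N/mm^3 for foundation moduli, so stiffness blocks come out in
N/mm, N and N*mm as usual for 6-DOF rigid supports.  Twists are
``(ux, uy, uz, wx, wy, wz)`` about the stated reference point; rotations in
radians.  Small-displacement kinematics within a solve — finite motion is
recovered across remodeling iterations, not inside one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dentition import PdlSampleField
from .rigid import skew

# Table of elastic constants used by the study scenario (MPa, dimensionless).
PDL_ELASTIC_MODULUS = 0.67
PDL_POISSON_RATIO = 0.45
ALIGNER_ELASTIC_MODULUS = 1500.0
ALIGNER_POISSON_RATIO = 0.30
ATTACHMENT_ELASTIC_MODULUS = 20000.0
ATTACHMENT_POISSON_RATIO = 0.30
PDL_THICKNESS = 0.30  # mm
ALIGNER_SHELL_THICKNESS = 0.70  # mm


@dataclass(frozen=True)
class MaterialProperties:
    """Isotropic linear elastic material (E in MPa)."""

    elastic_modulus: float
    poisson_ratio: float

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson ratio must lie in [0, 0.5)")


PDL_MATERIAL = MaterialProperties(PDL_ELASTIC_MODULUS, PDL_POISSON_RATIO)
ALIGNER_MATERIAL = MaterialProperties(ALIGNER_ELASTIC_MODULUS, ALIGNER_POISSON_RATIO)
ATTACHMENT_MATERIAL = MaterialProperties(ATTACHMENT_ELASTIC_MODULUS,
                                         ATTACHMENT_POISSON_RATIO)


@dataclass(frozen=True)
class FoundationModuli:
    """Per-area foundation stiffnesses of the thin PDL layer (N/mm^3)."""

    k_normal: float
    k_tangential: float
    thickness: float

    def __post_init__(self):
        if self.k_normal <= 0 or self.k_tangential <= 0:
            raise ValueError("foundation moduli must be positive")
        if self.k_normal < self.k_tangential:
            raise ValueError("k_normal must be >= k_tangential")


def foundation_moduli(mat: MaterialProperties, thickness: float) -> FoundationModuli:
    """Thin-layer (Winkler) reduction of an elastic layer of given thickness.

    Normal direction uses the confined modulus ``E (1 - nu) / ((1 + nu)(1 - 2 nu))``
    (the layer cannot spread laterally under the root), tangential directions
    use the shear modulus ``E / (2 (1 + nu))``; both divided by the thickness.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    e, nu = mat.elastic_modulus, mat.poisson_ratio
    if nu >= 0.5:
        raise ValueError("incompressible limit (nu = 0.5) diverges")
    k_n = e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * thickness)
    k_t = e / (2.0 * (1.0 + nu) * thickness)
    return FoundationModuli(k_normal=k_n, k_tangential=k_t, thickness=thickness)


def default_pdl_moduli(thickness: float = PDL_THICKNESS) -> FoundationModuli:
    return foundation_moduli(PDL_MATERIAL, thickness)


# ---------------------------------------------------------------------------
# stiffness assembly

@dataclass
class SupportStiffness:
    """6x6 symmetric support operator of one tooth about ``reference_point``."""

    matrix: np.ndarray
    reference_point: np.ndarray
    sample_field: PdlSampleField
    moduli: FoundationModuli

    def shifted(self, new_reference: np.ndarray) -> "SupportStiffness":
        """Same support expressed about a different reference point
        (exact congruence transform)."""
        t = reference_shift_transform(self.reference_point, new_reference)
        return SupportStiffness(
            matrix=t.T @ self.matrix @ t,
            reference_point=np.asarray(new_reference, float),
            sample_field=self.sample_field,
            moduli=self.moduli,
        )


def reference_shift_transform(old_ref: np.ndarray, new_ref: np.ndarray) -> np.ndarray:
    """6x6 map taking a twist about ``new_ref`` to the same motion about
    ``old_ref``: K_new = T^T K_old T."""
    t = np.eye(6)
    t[:3, 3:] = skew(np.asarray(new_ref, float) - np.asarray(old_ref, float))
    return t


def _spring_matrices(samples: PdlSampleField, moduli: FoundationModuli) -> np.ndarray:
    """(N, 3, 3) per-sample spring stiffness a_i (k_t I + (k_n - k_t) n n^T)."""
    n = samples.normals
    a = samples.areas
    eye = np.eye(3)
    nnt = np.einsum("ni,nj->nij", n, n)
    return a[:, None, None] * (moduli.k_tangential * eye
                               + (moduli.k_normal - moduli.k_tangential) * nnt)


def _point_jacobians(samples: PdlSampleField, reference_point) -> np.ndarray:
    """(N, 3, 6) rigid-body point-velocity maps [I, -skew(p - ref)]."""
    r = samples.points - np.asarray(reference_point, float)
    n = len(r)
    j = np.zeros((n, 3, 6))
    j[:, :, :3] = np.eye(3)
    j[:, 0, 4], j[:, 0, 5] = r[:, 2], -r[:, 1]
    j[:, 1, 3], j[:, 1, 5] = -r[:, 2], r[:, 0]
    j[:, 2, 3], j[:, 2, 4] = r[:, 1], -r[:, 0]
    return j


def assemble_stiffness(samples: PdlSampleField, moduli: FoundationModuli,
                       reference_point) -> SupportStiffness:
    """Assemble K = sum_i J_i^T k_i J_i over the spring field (symmetric PSD)."""
    if len(samples.areas) < 1:
        raise ValueError("need at least one PDL sample")
    if np.any(samples.areas <= 0):
        raise ValueError("PDL sample areas must be positive")
    k = _spring_matrices(samples, moduli)
    j = _point_jacobians(samples, reference_point)
    matrix = np.einsum("nij,nik,nkl->jl", j, k, j, optimize=True)
    matrix = 0.5 * (matrix + matrix.T)
    return SupportStiffness(matrix=matrix,
                            reference_point=np.asarray(reference_point, float),
                            sample_field=samples, moduli=moduli)


# ---------------------------------------------------------------------------
# resistance center

class RankDeficientSupportError(np.linalg.LinAlgError):
    """Raised when the support stiffness does not constrain all 6 DOF."""

    def __init__(self, null_modes: np.ndarray):
        self.null_modes = null_modes
        super().__init__(
            "support stiffness is rank deficient; unconstrained twist "
            f"subspace (columns):\n{np.array_str(null_modes, precision=4)}")


def _check_full_rank(matrix: np.ndarray, rel_tol: float = 1e-10) -> None:
    vals, vecs = np.linalg.eigh(matrix)
    bad = vals < rel_tol * max(vals.max(), 1.0)
    if np.any(bad):
        raise RankDeficientSupportError(vecs[:, bad])


def resistance_center(support: SupportStiffness) -> np.ndarray:
    """Point where the translation-rotation coupling of the support is
    (Frobenius-)minimal: the center of resistance of the tooth.

    Shifting the reference by c turns the coupling block C into
    ``A skew(c) + C``; the minimizer solves a 3x3 linear system.  For an
    axisymmetric support the residual coupling at the optimum vanishes and
    the point lies on the symmetry axis.
    """
    _check_full_rank(support.matrix)
    a = support.matrix[:3, :3]
    c_block = support.matrix[:3, 3:]
    basis = [a @ skew(e) for e in np.eye(3)]
    g = np.array([[np.tensordot(mi, mj) for mj in basis] for mi in basis])
    b = np.array([np.tensordot(mi, c_block) for mi in basis])
    shift = np.linalg.solve(g, -b)
    return support.reference_point + shift


# ---------------------------------------------------------------------------
# response, strain and traction

def respond(support: SupportStiffness, wrench: np.ndarray) -> np.ndarray:
    """Quasi-static small-displacement response: twist = K^-1 wrench.

    The wrench is ``(Fx, Fy, Fz, Mx, My, Mz)`` about the support's reference
    point.  A singular support raises rather than being silently regularized.
    """
    _check_full_rank(support.matrix)
    return np.linalg.solve(support.matrix, np.asarray(wrench, float))


@dataclass
class StrainTractionResult:
    strains: np.ndarray            # per-sample engineering strain (fraction)
    max_strain_fraction: float
    traction_vectors: np.ndarray   # (N, 3), N/mm^2
    normal_traction: np.ndarray    # (N,), compression positive


def sample_displacements(samples: PdlSampleField, twist: np.ndarray,
                         reference_point) -> np.ndarray:
    """Spring elongation vectors at every sample for a rigid twist."""
    u, w = np.asarray(twist[:3], float), np.asarray(twist[3:], float)
    r = samples.points - np.asarray(reference_point, float)
    return u + np.cross(w, r)


def strain_and_traction(samples: PdlSampleField, twist: np.ndarray,
                        reference_point, moduli: FoundationModuli
                        ) -> StrainTractionResult:
    """PDL engineering strain (elongation over thickness) and surface traction.

    Normal traction is positive in compression: the outward surface normal
    points from root into the PDL, so a displacement along +n squeezes the
    layer.
    """
    d = sample_displacements(samples, twist, reference_point)
    n = samples.normals
    d_n = np.einsum("ni,ni->n", d, n)
    d_t = d - d_n[:, None] * n
    strains = np.linalg.norm(d, axis=1) / moduli.thickness
    traction = moduli.k_normal * d_n[:, None] * n + moduli.k_tangential * d_t
    return StrainTractionResult(
        strains=strains,
        max_strain_fraction=float(strains.max()) if len(strains) else 0.0,
        traction_vectors=traction,
        normal_traction=moduli.k_normal * d_n,
    )


def spring_energy(samples: PdlSampleField, twist: np.ndarray, reference_point,
                  moduli: FoundationModuli) -> float:
    """Total elastic energy of the spring field under a small twist
    (sum of per-spring energies; equals 1/2 twist^T K twist)."""
    d = sample_displacements(samples, twist, reference_point)
    d_n = np.einsum("ni,ni->n", d, samples.normals)
    d_sq = np.einsum("ni,ni->n", d, d)
    per_spring = 0.5 * samples.areas * (
        moduli.k_tangential * d_sq
        + (moduli.k_normal - moduli.k_tangential) * d_n ** 2)
    return float(per_spring.sum())


# ---------------------------------------------------------------------------
# spring-field CSV round trip (debugging / oracle tests)

def export_spring_field(samples: PdlSampleField, path) -> None:
    data = np.column_stack([samples.points, samples.normals, samples.areas])
    np.savetxt(path, data, delimiter=",",
               header="px,py,pz,nx,ny,nz,area", comments="")


def import_spring_field(path) -> PdlSampleField:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return PdlSampleField(points=data[:, 0:3], normals=data[:, 3:6],
                          areas=data[:, 6])
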