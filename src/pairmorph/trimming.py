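"""Anatomical-axis alignment, iterative trim-and-register, cut-plane exclusion.

The femur and tibia are analysed only near the joint: both meshes are aligned
to a global frame (proximal-distal = +Z, medial-lateral = +X), trimmed to a
height equal to the bone's medial-lateral range (or the available height minus
5 mm for short models), and re-registered after each cut so the final cut is
straight and symmetrical.  Correspondence points within a 2.0 mm margin of a
cut plane are excluded from all statistics, absorbing residual trimming
differences.  The patella is analysed whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh

from .mesh_core import MeshValidationError, TriangleMesh
from .registration import CpdParams, RigidTransform, apply_rigid, rigid_cpd

logger = logging.getLogger(__name__)

#: extent ratio (first/second principal axis) below which principal-axes
#: alignment is considered ambiguous and a reference model is required
AMBIGUITY_RATIO = 1.3

#: exclusion margin around cut planes (mm); matches the element size so
#: clipped boundary triangles cannot contribute spurious asymmetry
DEFAULT_MARGIN = 2.0

#: shortfall subtracted from the available height for short bones (mm)
SHORT_BONE_SHORTFALL = 5.0


class TrimmingError(RuntimeError):
    pass


@dataclass
class AlignmentResult:
    """Rigid transform into the global frame, and how it was obtained."""

    transform: RigidTransform
    method: str  # "principal-axes" | "reference-model"

    def to_dict(self) -> dict:
        return {"transform": self.transform.to_dict(), "method": self.method}


@dataclass
class TrimSpec:
    """Where and whether to cut a bone in the global frame."""

    bone: str
    keep_end: str  # "distal" | "proximal" | "none"
    target_height: float
    cut_plane_z: float | None
    short_bone: bool = False

    def __post_init__(self) -> None:
        if self.keep_end not in ("distal", "proximal", "none"):
            raise ValueError(f"invalid keep_end {self.keep_end!r}")
        if self.keep_end != "none" and self.target_height <= 0:
            raise ValueError("target_height must be positive")
        if self.keep_end == "none" and self.cut_plane_z is not None:
            raise ValueError("untrimmed bones have no cut plane")

    @property
    def cut_planes(self) -> list[float]:
        return [] if self.cut_plane_z is None else [self.cut_plane_z]

    def to_dict(self) -> dict:
        return {
            "bone": self.bone,
            "keep_end": self.keep_end,
            "target_height": self.target_height,
            "cut_plane_z": self.cut_plane_z,
            "short_bone": self.short_bone,
        }


@dataclass
class ExclusionMask:
    """Per-vertex inclusion flags after the cut-plane margin rule."""

    include: np.ndarray
    margin: float
    cut_planes: list[float]

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, dtype=bool)

    @property
    def n_included(self) -> int:
        return int(self.include.sum())


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _principal_frame(mesh: TriangleMesh):
    """Area-weighted principal axes; returns (centroid, axes sorted by
    decreasing extent, extents along those axes)."""
    areas = mesh.face_areas()
    face_centers = mesh.vertices[mesh.faces].mean(axis=1)
    w = areas / areas.sum()
    centroid = (w[:, None] * face_centers).sum(axis=0)
    centered = face_centers - centroid
    cov = (centered * w[:, None]).T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1]  # eigenvectors by decreasing eigenvalue
    proj = (mesh.vertices - centroid) @ axes.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]
    return centroid, axes[order], extents[order]


def _end_width(vertices: np.ndarray, frac: float, top: bool) -> float:
    """Cross-sectional spread (mm) of the slab at one z end."""
    z = vertices[:, 2]
    zmin, zmax = z.min(), z.max()
    h = (zmax - zmin) * frac
    sel = z >= zmax - h if top else z <= zmin + h
    xy = vertices[sel][:, :2]
    if len(xy) < 3:
        return 0.0
    return float(np.ptp(xy[:, 0]) + np.ptp(xy[:, 1]))


def align_to_global(
    mesh: TriangleMesh,
    bone: str,
    reference: TriangleMesh | None = None,
    params: CpdParams | None = None,
) -> tuple[TriangleMesh, AlignmentResult]:
    """Map a bone mesh into the global frame (proximal-distal = +Z).

    Long bones use area-weighted principal axes: centroid to the origin,
    longest axis to Z, with the Z sign chosen so the joint end (the wider end
    by cross-sectional extent) follows the bone convention — femur joint end
    distal at -Z, tibia joint end proximal at +Z.  Compact bones (extent ratio
    < 1.3, e.g. the patella) are instead rigidly registered onto a pre-aligned
    reference model.
    """
    centroid, axes, extents = _principal_frame(mesh)
    ratio = extents[0] / max(extents[1], 1e-12)

    if ratio < AMBIGUITY_RATIO:
        if reference is None:
            raise TrimmingError(
                f"principal axes ambiguous (extent ratio {ratio:.2f} < "
                f"{AMBIGUITY_RATIO}); supply a pre-aligned reference model"
            )
        transform, _ = rigid_cpd(mesh.vertices, reference.vertices, params)
        aligned = TriangleMesh(
            apply_rigid(mesh.vertices, transform), mesh.faces.copy(), mesh.scalars
        )
        return aligned, AlignmentResult(transform, "reference-model")

    z_axis = axes[0]
    x_axis = axes[1]
    y_axis = np.cross(z_axis, x_axis)
    R = np.vstack([x_axis, y_axis, z_axis])
    if np.linalg.det(R) < 0:
        y_axis = -y_axis
        R = np.vstack([x_axis, y_axis, z_axis])
    t = -R @ centroid
    v = mesh.vertices @ R.T + t

    wide_top = _end_width(v, 0.15, top=True) > _end_width(v, 0.15, top=False)
    joint_at_top = {"femur": False, "tibia": True}.get(bone, True)
    if wide_top != joint_at_top:
        # rotate 180 degrees about X: flips Z (and Y), keeps the frame proper
        flip = np.diag([1.0, -1.0, -1.0])
        R = flip @ R
        t = flip @ t
        v = mesh.vertices @ R.T + t

    transform = RigidTransform(R, t)
    aligned = TriangleMesh(v, mesh.faces.copy(), mesh.scalars)
    return aligned, AlignmentResult(transform, "principal-axes")


# ---------------------------------------------------------------------------
# trim specification
# ---------------------------------------------------------------------------


def compute_trim_spec(aligned_mesh: TriangleMesh, bone: str) -> TrimSpec:
    """Derive the trim height and cut plane from an aligned mesh.

    Target height is the medial-lateral (X) range; if the available
    proximal-distal extent is smaller, the maximum available height minus
    5 mm is used instead (short-bone rule).  The kept portion starts at the
    joint end: distal for the femur, proximal for the tibia.  The patella is
    never trimmed.
    """
    if bone == "patella":
        return TrimSpec(bone=bone, keep_end="none", target_height=float(
            aligned_mesh.extents()[2]
        ), cut_plane_z=None)

    v = aligned_mesh.vertices
    x_extent = float(np.ptp(v[:, 0]))
    z_min, z_max = float(v[:, 2].min()), float(v[:, 2].max())
    z_extent = z_max - z_min

    target = x_extent
    short = False
    # strict shortfall required: a mesh cut exactly at the target height must
    # not re-trigger the short-bone rule through float round-off
    if z_extent < target - 1e-6:
        if z_extent <= SHORT_BONE_SHORTFALL:
            raise MeshValidationError(
                f"available height {z_extent:.1f} mm is not trimmable"
            )
        target = z_extent - SHORT_BONE_SHORTFALL
        short = True

    if bone == "femur":  # joint end distal, at -Z
        cut_z = z_min + target
    elif bone == "tibia":  # joint end proximal, at +Z
        cut_z = z_max - target
    else:
        raise ValueError(f"unknown bone {bone!r}")
    return TrimSpec(
        bone=bone,
        keep_end="distal" if bone == "femur" else "proximal",
        target_height=target,
        cut_plane_z=cut_z,
        short_bone=short,
    )


def cut_at_plane(mesh: TriangleMesh, spec: TrimSpec) -> TriangleMesh:
    """Cut a mesh at the spec's global plane, clipping crossing triangles.

    Triangles crossing the plane are clipped by edge-plane intersection
    rather than deleted whole, keeping the cut straight.
    """
    if spec.cut_plane_z is None:
        return mesh
    normal = (
        np.array([0.0, 0.0, -1.0])
        if spec.keep_end == "distal"
        else np.array([0.0, 0.0, 1.0])
    )
    origin = np.array([0.0, 0.0, spec.cut_plane_z])
    tm = mesh.to_trimesh()
    sliced = trimesh.intersections.slice_mesh_plane(
        tm, plane_normal=normal, plane_origin=origin, cap=False
    )
    if sliced is None or len(sliced.faces) == 0:
        raise TrimmingError("cut removed the entire mesh; suspect misalignment")
    out = TriangleMesh.from_arrays(
        np.asarray(sliced.vertices), np.asarray(sliced.faces)
    )
    if out.area() < 0.25 * mesh.area():
        raise TrimmingError(
            "trimming removed more than 75% of the mesh; suspect misalignment"
        )
    return out


# ---------------------------------------------------------------------------
# iterative trim + register
# ---------------------------------------------------------------------------


def iterative_trim_register(
    left_mirrored: TriangleMesh,
    right: TriangleMesh,
    bone: str,
    params: CpdParams | None = None,
    n_iterations: int = 2,
) -> tuple[TriangleMesh, TriangleMesh, TrimSpec, RigidTransform]:
    """Trim both meshes at a shared global plane, re-registering in between.

    Preconditions: both meshes are aligned to the global frame and the
    mirrored left is already rigidly pre-registered onto the right.  The
    right (fixed) mesh defines the trim spec; because it never moves, the cut
    plane is stationary and iteration serves to let the rigid registration
    settle on joint-only geometry.  Each iteration cuts both originals at the
    plane with the current cumulative registration applied to the left, then
    re-registers trimmed left onto trimmed right.  The patella passes through
    unchanged.

    Returns the final trimmed meshes, the trim spec, and the cumulative rigid
    correction applied to the left mesh (beyond its input pose).
    """
    if bone == "patella":
        spec = compute_trim_spec(right, bone)
        return left_mirrored, right, spec, RigidTransform.identity()

    spec = compute_trim_spec(right, bone)
    right_trimmed = cut_at_plane(right, spec)
    total = RigidTransform.identity()
    left_trimmed = None
    for _ in range(n_iterations):
        left_posed = TriangleMesh(
            apply_rigid(left_mirrored.vertices, total), left_mirrored.faces.copy()
        )
        left_trimmed = cut_at_plane(left_posed, spec)
        correction, _ = rigid_cpd(left_trimmed.vertices, right_trimmed.vertices, params)
        total = correction.compose(total)
        left_trimmed = TriangleMesh(
            apply_rigid(left_trimmed.vertices, correction), left_trimmed.faces.copy()
        )
    logger.info(
        "iterative_trim_register(%s): target height %.1f mm (short=%s), "
        "residual correction %.3f deg / %.3f mm",
        bone,
        spec.target_height,
        spec.short_bone,
        total.rotation_angle_deg(),
        float(np.linalg.norm(total.t)),
    )
    return left_trimmed, right_trimmed, spec, total


# ---------------------------------------------------------------------------
# exclusion mask
# ---------------------------------------------------------------------------


def exclusion_mask(
    mesh: TriangleMesh, spec: TrimSpec, margin: float = DEFAULT_MARGIN
) -> ExclusionMask:
    """Include vertices at least ``margin`` (inclusive) from every cut plane."""
    include = np.ones(mesh.n_vertices, dtype=bool)
    for plane_z in spec.cut_planes:
        dist = np.abs(mesh.vertices[:, 2] - plane_z)
        include &= dist >= margin
    if include.sum() < 0.5 * mesh.n_vertices:
        raise TrimmingError(
            f"exclusion mask would retain only {include.sum()} of "
            f"{mesh.n_vertices} vertices"
        )
    return ExclusionMask(include=include, margin=margin, cut_planes=spec.cut_planes)
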