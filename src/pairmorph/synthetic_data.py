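"""Paired bone-surrogate meshes with known ground-truth asymmetry.

Real inputs are CT-derived surface models of the distal femur, patella and
proximal tibia; patient data cannot ship with the package, so every pipeline
stage is exercised on parametric surrogates instead.  Surrogates are smooth unions of
implicit primitives (capsule shaft plus condylar spheres for the femur, shaft
plus flattened plateau for the tibia, ridged ellipsoid for the patella),
surfaced by marching cubes and remeshed to the pipeline's 2.0 mm element size.

``make_pair`` turns one surrogate into a left/right pair with controllable
asymmetry: Gaussian bumps displacing the right surface along vertex normals
(ground truth recorded before noise), a rigid misalignment of the left side,
per-vertex surface noise, and optionally a small detached fragment emulating a
loose patellar bone fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .mesh_core import (
    TriangleMesh,
    largest_component,
    mirror_sagittal,
    remesh_isotropic,
    write_mesh,
)
from .registration import RigidTransform

BONES = ("femur", "patella", "tibia")

#: fixture-cohort group labels in increasing injected-asymmetry order
GROUPS = ("no", "low-grade", "high-grade")


@dataclass
class BoneSurrogateSpec:
    """Parameters of one implicit bone surrogate.

    ``scale`` is the long-axis extent in mm (30-120).  ``shape`` holds the
    per-bone proportions (fractions of scale); defaults give an elongated
    femur/tibia (long axis >= 1.4x width, exercising principal-axes
    alignment) and a compact patella (extent ratio < 1.3, exercising the
    reference-model path).
    """

    kind: str = "femur"
    scale: float = 70.0
    shape: dict = field(default_factory=dict)
    pitch: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BONES:
            raise ValueError(f"kind must be one of {BONES}; got {self.kind!r}")
        if not (30.0 <= self.scale <= 120.0):
            raise ValueError("scale must be in [30, 120] mm")


@dataclass
class Bump:
    """One local surface perturbation: normal-direction Gaussian bump."""

    anchor: np.ndarray
    amplitude: float
    radius: float
    sign: int = 1

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=np.float64).reshape(3)
        if not (0.0 <= self.amplitude <= 5.0):
            raise ValueError("bump amplitude must be in [0, 5] mm")
        if self.radius <= 2.0:
            raise ValueError("bump radius must exceed 2 mm to be resolvable")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class AsymmetrySpec:
    """Injected left/right differences for a synthetic pair."""

    bumps: list[Bump] = field(default_factory=list)
    noise_sigma: float = 0.3
    misalign_rot_deg: float = 0.0
    misalign_trans_mm: float = 0.0
    loose_fragment: bool = False


@dataclass
class AsymmetryTruth:
    """Ground truth on the right-mesh vertices, recorded before noise."""

    displacement: np.ndarray  # (V,) true displacement magnitude, mm
    regions: list[np.ndarray]  # vertex index set per bump (within 2 radii)
    amplitudes: list[float]


# ---------------------------------------------------------------------------
# implicit primitives (negative inside)
# ---------------------------------------------------------------------------


def _sd_sphere(p, center, r):
    return np.linalg.norm(p - center, axis=-1) - r


def _sd_capsule(p, a, b, r):
    pa = p - a
    ba = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    h = np.clip((pa @ ba) / (ba @ ba), 0.0, 1.0)
    return np.linalg.norm(pa - h[..., None] * ba, axis=-1) - r


def _sd_ellipsoid(p, center, radii):
    # standard bound-approximation of the ellipsoid distance; exact enough
    # for surfacing at the voxel pitches used here
    q = (p - center) / radii
    k0 = np.linalg.norm(q, axis=-1)
    k1 = np.linalg.norm(q / radii, axis=-1)
    k1 = np.where(k1 == 0, 1.0, k1)
    return k0 * (k0 - 1.0) / k1


def _smooth_union(values, k):
    """Smooth minimum with blending range ``k`` (mm)."""
    v = np.stack(values, axis=-1)
    return -k * np.log(np.exp(-v / k).sum(axis=-1))


def _implicit_for(spec: BoneSurrogateSpec):
    """Return (signed implicit fn, bounding box, min feature radius)."""
    L = spec.scale
    sh = spec.shape

    if spec.kind == "femur":
        r_shaft = sh.get("shaft_radius", 0.13) * L
        r_cond = sh.get("condyle_radius", 0.16) * L
        sep = sh.get("condyle_separation", 0.30) * L
        r_troch = sh.get("trochlea_radius", 0.12) * L
        cond_z = r_cond
        shaft_a = np.array([0.0, 0.0, 0.30 * L])
        shaft_b = np.array([0.0, 0.0, L - r_shaft])
        c1 = np.array([-sep / 2, 0.03 * L, cond_z])
        c2 = np.array([+sep / 2, 0.03 * L, cond_z])
        ct = np.array([0.0, -0.08 * L, 0.22 * L])

        def f(p):
            return _smooth_union(
                [
                    _sd_capsule(p, shaft_a, shaft_b, r_shaft),
                    _sd_sphere(p, c1, r_cond),
                    _sd_sphere(p, c2, r_cond),
                    _sd_sphere(p, ct, r_troch),
                ],
                k=0.04 * L,
            )

        half_w = sep / 2 + r_cond + 0.08 * L
        lo = np.array([-half_w, -0.25 * L, -0.05 * L])
        hi = np.array([half_w, 0.25 * L, 1.05 * L])
        feature = min(r_shaft, r_cond, r_troch)

    elif spec.kind == "tibia":
        r_shaft = sh.get("shaft_radius", 0.11) * L
        plat_r = sh.get("plateau_radius", 0.26) * L
        plat_h = sh.get("plateau_height", 0.10) * L
        r_tub = sh.get("tuberosity_radius", 0.055) * L
        plat_z = L - plat_h
        shaft_a = np.array([0.0, 0.0, r_shaft])
        shaft_b = np.array([0.0, 0.0, 0.80 * L])
        # anterior tibial tuberosity: breaks the axisymmetry of the shaft,
        # as on a real proximal tibia
        tub_a = np.array([0.0, -1.15 * r_shaft, 0.45 * L])
        tub_b = np.array([0.0, -0.90 * r_shaft, 0.78 * L])

        def f(p):
            return _smooth_union(
                [
                    _sd_capsule(p, shaft_a, shaft_b, r_shaft),
                    _sd_capsule(p, tub_a, tub_b, r_tub),
                    _sd_ellipsoid(
                        p,
                        np.array([0.0, 0.0, plat_z]),
                        np.array([plat_r, 0.85 * plat_r, plat_h]),
                    ),
                ],
                k=0.05 * L,
            )

        half_w = plat_r + 0.06 * L
        lo = np.array([-half_w, -half_w, -0.05 * L])
        hi = np.array([half_w, half_w, 1.10 * L])
        feature = min(r_shaft, plat_h, r_tub)

    else:  # patella
        ax = sh.get("semi_axes", (0.50, 0.38, 0.44))
        radii = np.array(ax) * L
        ridge_r = sh.get("ridge_radius", 0.10) * L
        apex_r = sh.get("apex_radius", 0.14) * L
        # off-centre, tilted ridge (unequal medial/lateral facets) and an
        # inferior apex: real patellae have no rotational symmetry, and an
        # identifiable pose needs these asymmetries
        ridge_a = np.array([0.08 * L, radii[1] * 0.70, -radii[2] * 0.35])
        ridge_b = np.array([0.0, radii[1] * 0.78, radii[2] * 0.45])
        apex_c = np.array([0.0, 0.10 * radii[1], -0.95 * radii[2]])

        def f(p):
            return _smooth_union(
                [
                    _sd_ellipsoid(p, np.zeros(3), radii),
                    _sd_capsule(p, ridge_a, ridge_b, ridge_r),
                    _sd_sphere(p, apex_c, apex_r),
                ],
                k=0.06 * L,
            )

        half = radii + ridge_r + 0.08 * L
        lo = -half
        hi = half
        feature = min(radii.min(), ridge_r, apex_r)

    return f, (lo, hi), feature


def make_surrogate(spec: BoneSurrogateSpec, target_edge: float = 2.0) -> TriangleMesh:
    """Build a closed, single-component surrogate surface at ~2 mm elements."""
    f, (lo, hi), feature = _implicit_for(spec)
    if spec.pitch > feature / 2.0:
        raise ValueError(
            f"voxel pitch {spec.pitch} mm too coarse for the smallest feature "
            f"radius {feature:.1f} mm"
        )
    pad = 3 * spec.pitch
    lo = lo - pad
    hi = hi + pad
    nx, ny, nz = (np.ceil((hi - lo) / spec.pitch).astype(int) + 1)
    xs = lo[0] + spec.pitch * np.arange(nx)
    ys = lo[1] + spec.pitch * np.arange(ny)
    zs = lo[2] + spec.pitch * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    vol = f(grid.reshape(-1, 3)).reshape(nx, ny, nz)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(spec.pitch,) * 3)
    verts = verts + lo
    mesh = TriangleMesh.from_arrays(verts, faces)
    if mesh.signed_volume() < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])
    mesh = largest_component(mesh)
    mesh = remesh_isotropic(mesh, target_edge=target_edge, iterations=4)
    return largest_component(mesh)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------


def _random_rigid(rot_deg: float, trans_mm: float, rng: np.random.Generator) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(rot_deg) * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return RigidTransform(R, trans_mm * direction)


def make_pair(
    base: TriangleMesh,
    asym: AsymmetrySpec,
    seed: int = 0,
) -> tuple[TriangleMesh, TriangleMesh, AsymmetryTruth]:
    """Derive a (left, right) pair from a base surrogate.

    right = base with bumps applied along vertex normals (truth recorded
    before noise); left = sagittal mirror of the unmodified base, perturbed
    by the specified rigid misalignment.  Independent per-vertex noise is
    then added to both sides along their normals.
    """
    rng = np.random.default_rng(seed)
    normals = base.vertex_normals()
    V = base.vertices

    disp = np.zeros_like(V)
    regions: list[np.ndarray] = []
    for bump in asym.bumps:
        d_anchor = np.linalg.norm(V - bump.anchor, axis=1)
        if d_anchor.min() > 5.0:
            raise ValueError(
                f"bump anchor {bump.anchor.tolist()} is {d_anchor.min():.1f} mm "
                "from the surface (max 5 mm)"
            )
        w = np.exp(-(d_anchor**2) / (2.0 * bump.radius**2))
        disp += bump.sign * bump.amplitude * w[:, None] * normals
        regions.append(np.nonzero(d_anchor <= 2.0 * bump.radius)[0])

    truth = AsymmetryTruth(
        displacement=np.linalg.norm(disp, axis=1),
        regions=regions,
        amplitudes=[b.amplitude for b in asym.bumps],
    )

    right_v = V + disp
    right = TriangleMesh(right_v, base.faces.copy())

    left = mirror_sagittal(base)
    if asym.misalign_rot_deg or asym.misalign_trans_mm:
        T = _random_rigid(asym.misalign_rot_deg, asym.misalign_trans_mm, rng)
        left = TriangleMesh(T.apply(left.vertices), left.faces.copy())

    if asym.noise_sigma > 0:
        right = TriangleMesh(
            right.vertices
            + right.vertex_normals() * rng.normal(0, asym.noise_sigma, len(right_v))[:, None],
            right.faces.copy(),
        )
        left = TriangleMesh(
            left.vertices
            + left.vertex_normals() * rng.normal(0, asym.noise_sigma, left.n_vertices)[:, None],
            left.faces.copy(),
        )

    if asym.loose_fragment:
        right = _add_fragment(right, rng)

    return left, right, truth


def _add_fragment(mesh: TriangleMesh, rng: np.random.Generator) -> TriangleMesh:
    """Concatenate a small detached sphere near the surface (loose fragment)."""
    normals = mesh.vertex_normals()
    i = int(rng.integers(mesh.n_vertices))
    center = mesh.vertices[i] + normals[i] * 8.0
    frag = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
    fv = np.asarray(frag.vertices) + center
    ff = np.asarray(frag.faces) + mesh.n_vertices
    return TriangleMesh(
        np.vstack([mesh.vertices, fv]), np.vstack([mesh.faces, ff])
    )


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def score_recovery(
    cs,
    truth: AsymmetryTruth,
    *,
    cs_vertices: np.ndarray | None = None,
    truth_vertices: np.ndarray | None = None,
    to_input: RigidTransform | None = None,
) -> dict:
    """Compare measured CP distances against injected ground truth.

    When the correspondence set lives on a different vertex set than the truth
    (the pipeline trims and re-registers the right mesh), supply both vertex
    arrays; measured values are mapped to truth vertices by nearest neighbour
    after undoing the pipeline's rigid motion ``to_input``.
    """
    measured = np.asarray(cs.distances, dtype=np.float64)
    include = np.asarray(cs.include, dtype=bool)

    if len(measured) == len(truth.displacement) and cs_vertices is None:
        truth_idx = np.arange(len(measured))
    else:
        if cs_vertices is None or truth_vertices is None:
            raise ValueError(
                "vertex count mismatch: supply cs_vertices and truth_vertices "
                "to map correspondences onto the truth mesh"
            )
        from scipy.spatial import cKDTree

        pts = np.asarray(cs_vertices, dtype=np.float64)
        if to_input is not None:
            pts = to_input.apply(pts)
        _, truth_idx = cKDTree(np.asarray(truth_vertices)).query(pts)

    true_on_cs = truth.displacement[truth_idx]
    in_any_region = np.zeros(len(truth.displacement), dtype=bool)
    for r in truth.regions:
        in_any_region[r] = True
    region_mask_cs = in_any_region[truth_idx]

    per_bump = []
    for r, amp in zip(truth.regions, truth.amplitudes):
        r_set = np.zeros(len(truth.displacement), dtype=bool)
        r_set[r] = True
        sel = r_set[truth_idx] & include
        if not sel.any():
            per_bump.append(
                {"amplitude": amp, "max_measured": np.nan, "relative_error": np.nan}
            )
            continue
        mx = float(measured[sel].max())
        per_bump.append(
            {
                "amplitude": amp,
                "max_measured": mx,
                "relative_error": (mx - amp) / amp if amp > 0 else np.nan,
            }
        )

    off = include & ~region_mask_cs
    off_median = float(np.median(measured[off])) if off.any() else np.nan
    err = measured[include] - true_on_cs[include]
    return {
        "per_bump": per_bump,
        "off_region_median": off_median,
        "abs_error_median": float(np.median(np.abs(err))),
        "n_compared": int(include.sum()),
    }


# ---------------------------------------------------------------------------
# fixture cohort
# ---------------------------------------------------------------------------

_BONE_SCALES = {"femur": 70.0, "patella": 38.0, "tibia": 75.0}


def _group_asymmetry(
    group: str, bone: str, base: TriangleMesh, rng: np.random.Generator
) -> AsymmetrySpec:
    """Injected asymmetry per cohort group: none / 1-2 mm / 2-4 mm bumps."""
    if group == "no":
        amplitudes: list[float] = []
    elif group == "low-grade":
        amplitudes = [1.0, 2.0]
    elif group == "high-grade":
        amplitudes = [2.0, 3.0, 4.0]
    else:
        raise ValueError(f"unknown group {group!r}")
    # group asymmetry emulates joint-level shape differences, so anchors go on
    # the joint half of long bones (the shaft is trimmed away by the pipeline):
    # femur joint end is at low z in the generated frame, tibia at high z
    z = base.vertices[:, 2]
    if bone == "femur":
        candidates = np.nonzero(z < np.median(z))[0]
    elif bone == "tibia":
        candidates = np.nonzero(z > np.median(z))[0]
    else:
        candidates = np.arange(base.n_vertices)
    bumps = []
    for amp in amplitudes:
        anchor = base.vertices[candidates[int(rng.integers(len(candidates)))]]
        bumps.append(Bump(anchor=anchor, amplitude=amp, radius=12.0))
    return AsymmetrySpec(
        bumps=bumps,
        noise_sigma=0.3,
        misalign_rot_deg=5.0,
        misalign_trans_mm=5.0,
        loose_fragment=(group == "high-grade" and bone == "patella"),
    )


def write_fixture_cohort(
    out_dir: str | Path, n_per_group: int = 1, seed: int = 0
) -> Path:
    """Emit a ready-to-run synthetic cohort and its manifest CSV.

    Three groups with increasing injected asymmetry mimic a cohort's
    no / low-grade / high-grade structure; each subject contributes a
    left/right STL pair for each of the three bones.  Deterministic per seed.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    subject = 0
    for gi, group in enumerate(GROUPS):
        for _ in range(n_per_group):
            subject += 1
            sid = f"S{subject:03d}"
            for bone in BONES:
                pair_seed = seed * 10007 + subject * 101 + BONES.index(bone)
                rng = np.random.default_rng(pair_seed)
                scale = _BONE_SCALES[bone] * (1.0 + 0.1 * (rng.random() - 0.5))
                base = make_surrogate(
                    BoneSurrogateSpec(kind=bone, scale=scale, seed=pair_seed)
                )
                asym = _group_asymmetry(group, bone, base, rng)
                left, right, _ = make_pair(base, asym, seed=pair_seed)
                lp = out_dir / f"{sid}_{bone}_left.stl"
                rp = out_dir / f"{sid}_{bone}_right.stl"
                write_mesh(left, lp)
                write_mesh(right, rp)
                rows.append(
                    {
                        "subject_id": sid,
                        "bone": bone,
                        "left_path": lp.name,
                        "right_path": rp.name,
                        "group": group,
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
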