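"""Triangle-mesh data model, STL/PLY I/O, mirroring, remeshing, fragment filtering.

All coordinates are millimetres.  The :class:`TriangleMesh` container is the
currency of the whole pipeline; it wraps plain numpy arrays and converts to and
from :class:`trimesh.Trimesh` for I/O and topology queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: duplicate vertices closer than this (mm) are merged on construction;
#: far below CT resolution, so no anatomical detail can be lost.
MERGE_TOLERANCE = 1e-6

#: name of the per-vertex scalar property carried in PLY exports.
SCALAR_PROPERTY = "cp_distance"


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural precondition."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """A triangle surface mesh: ``vertices`` (V, 3) mm and ``faces`` (F, 3).

    ``scalars`` is an optional per-vertex channel (mm), used to carry
    correspondence-point distances into heatmap exports.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshValidationError("face indices out of range")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=np.float64)
            if self.scalars.shape != (len(self.vertices),):
                raise MeshValidationError("scalars must have one value per vertex")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        vertices: np.ndarray,
        faces: np.ndarray,
        scalars: np.ndarray | None = None,
        merge: bool = True,
    ) -> "TriangleMesh":
        """Build a mesh, merging duplicate vertices and dropping degenerate faces."""
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if len(vertices) == 0 or len(faces) == 0:
            raise MeshValidationError("empty mesh")
        if merge:
            vertices, faces, scalars = _merge_duplicate_vertices(
                vertices, faces, scalars
            )
        faces = _drop_degenerate_faces(vertices, faces)
        if len(faces) == 0:
            raise MeshValidationError("mesh has no non-degenerate faces")
        vertices, faces, scalars = _drop_unreferenced(vertices, faces, scalars)
        return cls(vertices, faces, scalars)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, merge: bool = True) -> "TriangleMesh":
        return cls.from_arrays(np.asarray(tm.vertices), np.asarray(tm.faces), merge=merge)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalars is None else self.scalars.copy(),
        )

    # -- basic geometry -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_lengths(self) -> np.ndarray:
        """Lengths (mm) of the unique undirected edges."""
        e = _unique_edges(self.faces)
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (mm^3).

        Positive for a closed surface with outward-oriented faces.
        """
        v = self.vertices
        f = self.faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, f[:, k], fn)
        norm = np.linalg.norm(vn, axis=1)
        norm[norm == 0] = 1.0
        return vn / norm[:, None]

    def extents(self) -> np.ndarray:
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)


@dataclass
class MeshStats:
    """Descriptive statistics of a mesh, for logging and validity checks."""

    n_vertices: int
    n_faces: int
    mean_edge: float
    median_edge: float
    extents: tuple[float, float, float]
    n_components: int
    watertight: bool


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------


def _merge_duplicate_vertices(vertices, faces, scalars, tol: float = MERGE_TOLERANCE):
    """Merge vertices whose coordinates coincide within ``tol`` (mm)."""
    # quantize to a grid finer than tol; exact duplicates land in one cell
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)  # keep original ordering of representatives
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[np.sort(first)]
    remap = rank[inverse]
    new_faces = remap[faces]
    new_scalars = scalars[np.sort(first)] if scalars is not None else None
    return new_vertices, new_faces, new_scalars


def _drop_degenerate_faces(vertices, faces, area_tol: float = 1e-12):
    """Remove faces with repeated indices or (numerically) zero area."""
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    if len(faces):
        cross = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )
        faces = faces[np.linalg.norm(cross, axis=1) > 2 * area_tol]
    return faces


def _drop_unreferenced(vertices, faces, scalars=None):
    used = np.unique(faces)
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_scalars = scalars[used] if scalars is not None else None
    return vertices[used], remap[faces], new_scalars


def _unique_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def _edge_face_counts(faces: np.ndarray):
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    edges, counts = np.unique(e, axis=0, return_counts=True)
    return edges, counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path, file_format: str | None = None) -> TriangleMesh:
    """Read an STL or PLY surface into a :class:`TriangleMesh`.

    Duplicate vertices are merged within 1e-6 mm and degenerate faces dropped.
    A per-vertex ``cp_distance`` property in a PLY file is read into
    ``scalars``.  Units are assumed to be millimetres; no unit metadata is
    interpreted.
    """
    path = Path(path)
    if file_format is None:
        file_format = path.suffix.lstrip(".").lower()
    if file_format not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format: {file_format!r}")
    if not path.is_file():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=file_format, process=False)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise IOError(f"could not read mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.vertices) == 0:
        raise MeshValidationError(f"file contains no surface geometry: {path}")

    scalars = _extract_ply_scalar(tm) if file_format == "ply" else None
    return TriangleMesh.from_arrays(
        np.asarray(tm.vertices), np.asarray(tm.faces), scalars=scalars
    )


def _extract_ply_scalar(tm: trimesh.Trimesh) -> np.ndarray | None:
    raw = tm.metadata.get("_ply_raw", {})
    vert = raw.get("vertex", {})
    data = vert.get("data")
    if data is None:
        return None
    names = getattr(data.dtype, "names", None) or ()
    if SCALAR_PROPERTY in names:
        return np.asarray(data[SCALAR_PROPERTY], dtype=np.float64)
    return None


def write_mesh(
    mesh: TriangleMesh,
    path: str | Path,
    file_format: str | None = None,
    scalars: np.ndarray | None = None,
) -> Path:
    """Write a mesh as STL or PLY.

    PLY carries ``scalars`` (or ``mesh.scalars``) as a per-vertex
    ``cp_distance`` property; STL cannot store per-vertex data, so scalars are
    dropped with a logged warning.
    """
    path = Path(path)
    if file_format is None:
        file_format = path.suffix.lstrip(".").lower()
    if file_format not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format: {file_format!r}")
    if scalars is None:
        scalars = mesh.scalars
    if scalars is not None:
        scalars = np.asarray(scalars, dtype=np.float64)
        if scalars.shape != (mesh.n_vertices,):
            raise MeshValidationError("scalars must have one value per vertex")

    tm = mesh.to_trimesh()
    if file_format == "ply" and scalars is not None:
        tm.vertex_attributes[SCALAR_PROPERTY] = scalars
    if file_format == "stl" and scalars is not None:
        logger.warning(
            "STL cannot store per-vertex scalars; dropping %d values for %s",
            len(scalars),
            path,
        )
    try:
        tm.export(str(path), file_type=file_format)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write mesh file {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def mirror_sagittal(mesh: TriangleMesh, axis: str = "x") -> TriangleMesh:
    """Mirror a mesh across the plane perpendicular to ``axis``.

    The chosen coordinate is negated and the face winding flipped, so outward
    normal orientation is preserved.  Applying the mirror twice reproduces the
    input vertex-exactly.  The default axis ``x`` matches the patient
    left-right direction of LPS/RAS CT frames; mesh provenance varies, so the
    axis is configurable.
    """
    try:
        idx = _AXIS_INDEX[axis]
    except KeyError:
        raise ValueError(f"axis must be one of x, y, z; got {axis!r}") from None
    v = mesh.vertices.copy()
    v[:, idx] = -v[:, idx]
    f = mesh.faces[:, [0, 2, 1]].copy()
    scal = None if mesh.scalars is None else mesh.scalars.copy()
    return TriangleMesh(v, f, scal)


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


def _face_components(mesh: TriangleMesh) -> list[np.ndarray]:
    """Connected components as arrays of face indices (vertex-connectivity)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components as cc

    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    n = mesh.n_vertices
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = cc(adj, directed=False)
    face_label = labels[f[:, 0]]
    return [np.nonzero(face_label == i)[0] for i in range(n_comp)]


def largest_component(mesh: TriangleMesh) -> TriangleMesh:
    """Keep only the connected component with the largest surface area.

    Emulates the exclusion of loose bone fragments from segmented surfaces.
    Ties within 1e-9 relative area are broken deterministically by the lowest
    contained vertex index.
    """
    if mesh.n_faces == 0:
        raise MeshValidationError("empty mesh")
    comps = _face_components(mesh)
    if len(comps) == 1:
        return mesh
    areas = mesh.face_areas()
    comp_areas = np.array([areas[c].sum() for c in comps])
    best_area = comp_areas.max()
    candidates = [
        i
        for i, a in enumerate(comp_areas)
        if a >= best_area * (1 - 1e-9)
    ]
    # tie-break: lowest contained vertex index
    winner = min(candidates, key=lambda i: mesh.faces[comps[i]].min())
    removed_area = comp_areas.sum() - comp_areas[winner]
    logger.info(
        "largest_component: removed %d fragment(s), total area %.2f mm^2",
        len(comps) - 1,
        removed_area,
    )
    keep_faces = mesh.faces[comps[winner]]
    v, f, s = _drop_unreferenced(mesh.vertices, keep_faces, mesh.scalars)
    return TriangleMesh(v, f, s)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def mesh_stats(mesh: TriangleMesh) -> MeshStats:
    lengths = mesh.edge_lengths()
    _, counts = _edge_face_counts(mesh.faces)
    return MeshStats(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        mean_edge=float(lengths.mean()),
        median_edge=float(np.median(lengths)),
        extents=tuple(float(x) for x in mesh.extents()),
        n_components=len(_face_components(mesh)),
        watertight=bool(np.all(counts == 2)),
    )


# ---------------------------------------------------------------------------
# closest-point queries (used by remeshing and by surface-distance checks)
# ---------------------------------------------------------------------------


class SurfaceProjector:
    """Closest-point-on-surface queries against a fixed triangle mesh.

    Candidate faces come from a k-d tree over triangle centroids; the exact
    closest point is then computed per candidate triangle.  ``k`` nearest
    centroids bound the search; for meshes with roughly uniform triangle size
    (our remeshed surfaces) this is effectively exact.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 24):
        self._tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
        centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(centroids)
        self._k = min(k, len(centroids))

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points (N, 3), distances (N,))."""
        points = np.asarray(points, dtype=np.float64)
        _, idx = self._tree.query(points, k=self._k, workers=-1)
        if self._k == 1:
            idx = idx[:, None]
        cand = self._tri[idx]  # (N, k, 3, 3)
        closest = _closest_point_triangle(
            points[:, None, :], cand[..., 0, :], cand[..., 1, :], cand[..., 2, :]
        )
        d2 = ((closest - points[:, None, :]) ** 2).sum(axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return closest[rows, best], np.sqrt(d2[rows, best])


def _closest_point_triangle(p, a, b, c):
    """Closest point on triangles (a, b, c) to points p; broadcasting over
    leading axes.  Standard barycentric region classification."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-30, 1.0, denom)
    v = vb / denom
    w = vc / denom
    face_pt = a + ab * v[..., None] + ac * w[..., None]

    # edge/vertex regions
    t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0), 0, 1)
    pt_ab = a + ab * t_ab[..., None]
    t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0), 0, 1)
    pt_ac = a + ac * t_ac[..., None]
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(np.where(den_bc != 0, num_bc / np.where(den_bc == 0, 1, den_bc), 0), 0, 1)
    pt_bc = b + (c - b) * t_bc[..., None]

    out = face_pt.copy()
    # vertex a
    mask = (d1 <= 0) & (d2 <= 0)
    out = np.where(mask[..., None], a, out)
    # vertex b
    m = (d3 >= 0) & (d4 <= d3) & ~mask
    out = np.where(m[..., None], b, out)
    mask |= m
    # vertex c
    m = (d6 >= 0) & (d5 <= d6) & ~mask
    out = np.where(m[..., None], c, out)
    mask |= m
    # edge ab
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~mask
    out = np.where(m[..., None], pt_ab, out)
    mask |= m
    # edge ac
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~mask
    out = np.where(m[..., None], pt_ac, out)
    mask |= m
    # edge bc
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~mask
    out = np.where(m[..., None], pt_bc, out)
    return out


def surface_distance(
    from_mesh: TriangleMesh, to_mesh: TriangleMesh, sample: int | None = None
) -> np.ndarray:
    """Distance (mm) from each vertex of ``from_mesh`` to the surface of
    ``to_mesh``."""
    proj = SurfaceProjector(to_mesh)
    pts = from_mesh.vertices
    if sample is not None and len(pts) > sample:
        step = max(1, len(pts) // sample)
        pts = pts[::step]
    return proj.project(pts)[1]


def hausdorff_distance(a: TriangleMesh, b: TriangleMesh) -> float:
    """Symmetric vertex-to-surface Hausdorff distance (mm)."""
    return float(max(surface_distance(a, b).max(), surface_distance(b, a).max()))


# ---------------------------------------------------------------------------
# isotropic remeshing
# ---------------------------------------------------------------------------


def remesh_isotropic(
    mesh: TriangleMesh, target_edge: float = 2.0, iterations: int = 5
) -> TriangleMesh:
    """Remesh a closed manifold surface to near-uniform edge length.

    Incremental remeshing in the classic split / collapse / flip / tangential-
    relax cycle: edges longer than 4/3 of the target are split at their
    midpoint, edges shorter than 4/5 of the target are collapsed, edges are
    flipped toward valence 6, and vertices are relaxed tangentially and
    projected back onto the *original* surface so geometry is preserved.

    Postconditions (verified in tests): median edge length within +/-25% of
    ``target_edge``; Hausdorff distance to the input below 0.2 mm; surface
    area and volume preserved within 2% for closed inputs.
    """
    edges, counts = _edge_face_counts(mesh.faces)
    bad = edges[counts != 2]
    if len(bad):
        raise MeshValidationError(
            f"input is not a closed manifold; {len(bad)} offending edge(s), "
            f"first few: {bad[:5].tolist()}"
        )

    projector = SurfaceProjector(mesh)
    v = mesh.vertices.copy()
    f = mesh.faces.copy()
    high = 4.0 / 3.0 * target_edge
    low = 4.0 / 5.0 * target_edge

    for _ in range(iterations):
        v, f = _split_long_edges(v, f, high)
        v, f = _collapse_short_edges(v, f, low, high)
        f = _flip_edges_for_valence(v, f)
        v = _tangential_relax(v, f, projector)

    out = TriangleMesh.from_arrays(v, f, merge=False)
    return out


def _split_long_edges(v, f, max_edge):
    # trimesh's subdivide_to_size performs midpoint 1->4 subdivision of faces
    # whose longest edge exceeds max_edge, exactly the split step we need.
    ln = np.linalg.norm(v[f[:, 1]] - v[f[:, 0]], axis=1)
    ln = np.maximum(ln, np.linalg.norm(v[f[:, 2]] - v[f[:, 1]], axis=1))
    ln = np.maximum(ln, np.linalg.norm(v[f[:, 0]] - v[f[:, 2]], axis=1))
    if ln.max() <= max_edge:
        return v, f
    nv, nf = trimesh.remesh.subdivide_to_size(v, f, max_edge=max_edge, max_iter=8)
    nv, nf, _ = _merge_duplicate_vertices(nv, nf, None)
    return nv, nf


def _vertex_adjacency(f, n):
    adj = [set() for _ in range(n)]
    for a, b, c in f:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def _collapse_short_edges(v, f, min_edge, max_edge):
    edges = _unique_edges(f)
    lengths = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    short = edges[lengths < min_edge]
    if len(short) == 0:
        return v, f
    order = np.argsort(np.linalg.norm(v[short[:, 0]] - v[short[:, 1]], axis=1))
    short = short[order]

    adj = _vertex_adjacency(f, len(v))
    locked = np.zeros(len(v), dtype=bool)
    remap = np.arange(len(v))
    v = v.copy()
    for a, b in short:
        if locked[a] or locked[b]:
            continue
        na, nb = adj[a], adj[b]
        # link condition: shared neighbours must be exactly the two opposite
        # vertices of the edge, else the collapse pinches the surface
        if len(na & nb) != 2:
            continue
        mid = 0.5 * (v[a] + v[b])
        ring = (na | nb) - {a, b}
        ring_idx = np.fromiter(ring, dtype=np.int64)
        if len(ring_idx) and np.linalg.norm(v[ring_idx] - mid, axis=1).max() > max_edge:
            continue
        v[a] = mid
        remap[b] = a
        locked[a] = locked[b] = True
        locked[ring_idx] = True

    f = remap[f]
    f = _drop_degenerate_faces(v, f)
    v, f, _ = _drop_unreferenced(v, f)
    return v, f


def _flip_edges_for_valence(v, f):
    n = len(v)
    valence = np.bincount(f.ravel(), minlength=n)

    # map undirected edge -> list of (face index, opposite vertex)
    edge_faces: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for fi, (a, b, c) in enumerate(f):
        for u, w, opp in ((a, b, c), (b, c, a), (c, a, b)):
            key = (u, w) if u < w else (w, u)
            edge_faces.setdefault(key, []).append((fi, opp))

    existing = set(edge_faces.keys())
    f = f.copy()
    face_dirty = np.zeros(len(f), dtype=bool)

    for (u, w), lst in edge_faces.items():
        if len(lst) != 2:
            continue
        (f1, o1), (f2, o2) = lst
        if face_dirty[f1] or face_dirty[f2]:
            continue
        key_new = (o1, o2) if o1 < o2 else (o2, o1)
        if o1 == o2 or key_new in existing:
            continue
        dev = lambda x: (x - 6) ** 2  # noqa: E731
        before = dev(valence[u]) + dev(valence[w]) + dev(valence[o1]) + dev(valence[o2])
        after = (
            dev(valence[u] - 1)
            + dev(valence[w] - 1)
            + dev(valence[o1] + 1)
            + dev(valence[o2] + 1)
        )
        if after >= before:
            continue
        # orient: find the face of the pair holding directed edge u->w
        t1, t2 = f[f1], f[f2]
        if not _has_directed_edge(t1, u, w):
            f1, f2 = f2, f1
            o1, o2 = o2, o1
            t1, t2 = t2, t1
        # old: (u, w, o1) and (w, u, o2)  ->  new: (u, o2, o1), (o2, w, o1)
        nf1 = np.array([u, o2, o1])
        nf2 = np.array([o2, w, o1])
        if _triangle_area(v, nf1) < 1e-10 or _triangle_area(v, nf2) < 1e-10:
            continue
        # reject flips that fold the surface
        old_n = _face_normal(v, t1) + _face_normal(v, t2)
        if (
            np.dot(_face_normal(v, nf1), old_n) <= 0
            or np.dot(_face_normal(v, nf2), old_n) <= 0
        ):
            continue
        f[f1] = nf1
        f[f2] = nf2
        face_dirty[f1] = face_dirty[f2] = True
        valence[u] -= 1
        valence[w] -= 1
        valence[o1] += 1
        valence[o2] += 1
        existing.add(key_new)

    return f


def _has_directed_edge(tri, u, w):
    return any(
        (tri[i] == u and tri[(i + 1) % 3] == w) for i in range(3)
    )


def _triangle_area(v, tri):
    return 0.5 * np.linalg.norm(
        np.cross(v[tri[1]] - v[tri[0]], v[tri[2]] - v[tri[0]])
    )


def _face_normal(v, tri):
    n = np.cross(v[tri[1]] - v[tri[0]], v[tri[2]] - v[tri[0]])
    ln = np.linalg.norm(n)
    return n / ln if ln > 0 else n


def _tangential_relax(v, f, projector: SurfaceProjector, lam: float = 0.5):
    import scipy.sparse as sp

    n = len(v)
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0  # duplicates collapse to 1 after sum; normalize by degree
    adj = (adj > 0).astype(np.float64)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    centroid = adj @ v / deg[:, None]

    mesh_tmp = TriangleMesh(v, f)
    normals = mesh_tmp.vertex_normals()
    d = centroid - v
    d_t = d - np.einsum("ij,ij->i", d, normals)[:, None] * normals
    moved = v + lam * d_t
    projected, _ = projector.project(moved)
    return projected
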