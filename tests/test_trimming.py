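"""Global alignment, trim rule, iterative trim-and-register, exclusion masks."""

import numpy as np
import pytest
import trimesh as tm

from pairmorph.mesh_core import (
    MeshValidationError,
    TriangleMesh,
    hausdorff_distance,
    mirror_sagittal,
)
from pairmorph.registration import CpdParams, apply_rigid, rigid_cpd
from pairmorph.trimming import (
    TrimSpec,
    TrimmingError,
    align_to_global,
    compute_trim_spec,
    cut_at_plane,
    exclusion_mask,
    iterative_trim_register,
)


def _ellipsoid(rx, ry, rz, subdiv=3):
    s = tm.creation.icosphere(subdivisions=subdiv, radius=1.0)
    return TriangleMesh.from_arrays(
        np.asarray(s.vertices) * [rx, ry, rz], np.asarray(s.faces)
    )


def _rot(deg, axis):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.radians(deg) * axis / np.linalg.norm(axis)).as_matrix()


def _z_angle_deg(mesh):
    """Angle between the mesh's longest principal axis and global Z."""
    c = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = c.T @ c
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    return np.degrees(np.arccos(min(abs(axis[2]), 1.0)))


class TestAlignment:
    def test_elongated_ellipsoid_long_axis_to_z(self):
        mesh = _ellipsoid(40, 20, 20)  # long axis along x
        aligned, res = align_to_global(mesh, "femur")
        assert res.method == "principal-axes"
        assert _z_angle_deg(aligned) < 1.0
        assert np.abs(aligned.vertices.mean(axis=0)).max() < 1.0

    def test_rotation_invariant_pose(self):
        mesh = _ellipsoid(40, 20, 20)
        rotated = TriangleMesh(mesh.vertices @ _rot(37, [0, 1, 0]).T, mesh.faces)
        a1, _ = align_to_global(mesh, "femur")
        a2, _ = align_to_global(rotated, "femur")
        assert _z_angle_deg(a1) < 1.0 and _z_angle_deg(a2) < 1.0

    def test_compact_mesh_requires_reference(self, patella_surrogate):
        with pytest.raises(TrimmingError, match="reference"):
            align_to_global(patella_surrogate, "patella")

    def test_reference_model_alignment(self, patella_surrogate):
        rotated = TriangleMesh(
            patella_surrogate.vertices @ _rot(20, [1, 1, 0]).T + [5.0, -3.0, 2.0],
            patella_surrogate.faces,
        )
        aligned, res = align_to_global(
            rotated, "patella", reference=patella_surrogate, params=CpdParams(w=0.0)
        )
        assert res.method == "reference-model"
        assert (
            np.linalg.norm(aligned.vertices - patella_surrogate.vertices, axis=1).max()
            < 0.5
        )

    def test_joint_end_convention(self, femur_surrogate, tibia_surrogate):
        fa, _ = align_to_global(femur_surrogate, "femur")
        ta, _ = align_to_global(tibia_surrogate, "tibia")

        def end_width(mesh, top):
            v = mesh.vertices
            z = v[:, 2]
            h = np.ptp(z) * 0.15
            sel = z >= z.max() - h if top else z <= z.min() + h
            return np.ptp(v[sel, 0]) + np.ptp(v[sel, 1])

        # femur joint (wide condylar) end at -Z, tibia joint (plateau) at +Z
        assert end_width(fa, top=False) > end_width(fa, top=True)
        assert end_width(ta, top=True) > end_width(ta, top=False)


class TestTrimSpec:
    def _box_mesh(self, x, y, z):
        b = tm.creation.box(extents=(x, y, z))
        return TriangleMesh.from_arrays(b.vertices, b.faces)

    def test_medial_lateral_rule(self):
        spec = compute_trim_spec(self._box_mesh(80, 30, 120), "femur")
        assert spec.target_height == pytest.approx(80.0)
        assert not spec.short_bone
        assert spec.keep_end == "distal"

    def test_short_bone_rule(self):
        spec = compute_trim_spec(self._box_mesh(80, 30, 60), "femur")
        assert spec.target_height == pytest.approx(55.0)
        assert spec.short_bone

    def test_patella_untrimmed(self, patella_surrogate):
        spec = compute_trim_spec(patella_surrogate, "patella")
        assert spec.keep_end == "none"
        assert spec.cut_plane_z is None
        assert spec.cut_planes == []

    def test_untrimmable_height_rejected(self):
        with pytest.raises(MeshValidationError):
            compute_trim_spec(self._box_mesh(80, 30, 4), "femur")

    def test_cut_plane_at_joint_end(self):
        femur = compute_trim_spec(self._box_mesh(50, 30, 100), "femur")
        tibia = compute_trim_spec(self._box_mesh(50, 30, 100), "tibia")
        # box is centred at the origin: z in [-50, 50]
        assert femur.cut_plane_z == pytest.approx(-50 + 50)
        assert tibia.cut_plane_z == pytest.approx(50 - 50)


#: rigid settings matching the pipeline's: sigma^2 floored at the sampling
#: scale of 2 mm meshes, so registration cannot lock onto individual vertices
TRIM_CPD = dict(w=0.0, sigma2_floor=0.5, subsample_cap=4000)


class TestIterativeTrimRegister:
    @pytest.fixture(scope="class")
    def aligned_femur(self):
        # adult-scale femur: registration noise scales down with vertex count
        # and lever arm, matching the size regime the pipeline targets
        from pairmorph.synthetic_data import BoneSurrogateSpec, make_surrogate

        mesh = make_surrogate(BoneSurrogateSpec(kind="femur", scale=90.0))
        aligned, _ = align_to_global(mesh, "femur")
        return aligned

    def test_symmetric_pair_fixed_point(self, aligned_femur):
        left = mirror_sagittal(aligned_femur)
        lt, rt, spec, corr = iterative_trim_register(
            left, aligned_femur, "femur", CpdParams(**TRIM_CPD)
        )
        assert abs(np.ptp(rt.vertices[:, 2]) - spec.target_height) < 2.0
        assert abs(np.ptp(lt.vertices[:, 2]) - spec.target_height) < 2.0
        assert corr.rotation_angle_deg() < 0.1
        assert np.linalg.norm(corr.t) < 0.1

    def test_invariant_to_initial_misalignment(self, aligned_femur):
        left = mirror_sagittal(aligned_femur)
        lt_ref, _, _, _ = iterative_trim_register(
            left, aligned_femur, "femur", CpdParams(**TRIM_CPD)
        )
        perturbed = TriangleMesh(
            left.vertices @ _rot(10, [1, 2, 0]).T + [5.0, 0.0, -2.0], left.faces
        )
        pre, _ = rigid_cpd(
            perturbed.vertices, aligned_femur.vertices, CpdParams(**TRIM_CPD)
        )
        pre_reg = TriangleMesh(apply_rigid(perturbed.vertices, pre), perturbed.faces)
        lt_pert, _, _, _ = iterative_trim_register(
            pre_reg, aligned_femur, "femur", CpdParams(**TRIM_CPD)
        )
        assert hausdorff_distance(lt_pert, lt_ref) < 0.2

    def test_unequal_shaft_lengths_cut_at_shared_plane(self, aligned_femur):
        right = aligned_femur
        spec_r = compute_trim_spec(right, "femur")
        z_max = right.vertices[:, 2].max()
        shorten = TrimSpec(
            bone="femur",
            keep_end="distal",
            target_height=np.ptp(right.vertices[:, 2]) - 10.0,
            cut_plane_z=z_max - 10.0,
        )
        left = mirror_sagittal(cut_at_plane(right, shorten))
        lt, rt, spec, _ = iterative_trim_register(
            left, right, "femur", CpdParams(**TRIM_CPD)
        )
        assert spec.cut_plane_z == pytest.approx(spec_r.cut_plane_z)
        assert abs(np.ptp(lt.vertices[:, 2]) - np.ptp(rt.vertices[:, 2])) < 2.0

    def test_third_iteration_moves_plane_less_than_half_mm(self, aligned_femur):
        left = mirror_sagittal(aligned_femur)
        _, rt, spec, _ = iterative_trim_register(
            left, aligned_femur, "femur", CpdParams(**TRIM_CPD)
        )
        spec_again = compute_trim_spec(rt, "femur")
        assert abs(spec_again.cut_plane_z - spec.cut_plane_z) < 0.5

    def test_patella_passes_through(self, patella_surrogate):
        left = mirror_sagittal(patella_surrogate)
        lt, rt, spec, corr = iterative_trim_register(
            left, patella_surrogate, "patella", CpdParams(w=0.0)
        )
        assert rt is patella_surrogate
        assert spec.keep_end == "none"
        assert corr.rotation_angle_deg() == 0.0


class TestExclusionMask:
    def test_threshold_semantics_inclusive(self):
        z = np.array([10.5, 11.9, 12.0, 12.1, 40.0])
        v = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        # slab of vertices at z-distances {0.5, 1.9, 2.0, 2.1, 30} from z=10...
        mesh = TriangleMesh(
            np.vstack([v, [[1, 0, 25], [0, 1, 25], [1, 1, 25]]]),
            np.array([[5, 6, 7], [0, 1, 2], [2, 3, 4], [0, 2, 4]]),
        )
        spec = TrimSpec(
            bone="tibia", keep_end="proximal", target_height=30.0, cut_plane_z=10.0
        )
        mask = exclusion_mask(mesh, spec, margin=2.0)
        assert mask.include[:5].tolist() == [False, False, True, True, True]

    def test_patella_all_included(self, patella_surrogate):
        spec = compute_trim_spec(patella_surrogate, "patella")
        mask = exclusion_mask(patella_surrogate, spec)
        assert mask.include.all()

    def test_margin_violation_impossible(self, femur_surrogate):
        aligned, _ = align_to_global(femur_surrogate, "femur")
        left = mirror_sagittal(aligned)
        _, rt, spec, _ = iterative_trim_register(left, aligned, "femur", CpdParams(w=0.0))
        mask = exclusion_mask(rt, spec)
        for pz in spec.cut_planes:
            d = np.abs(rt.vertices[mask.include, 2] - pz)
            assert (d >= mask.margin).all()

    def test_overzealous_exclusion_rejected(self):
        z = np.linspace(0, 3.0, 12)  # everything within 2 mm of plane z=1.5
        v = np.column_stack([np.arange(12) % 3, np.arange(12) // 3, z])
        mesh = TriangleMesh(v, np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]]))
        spec = TrimSpec(
            bone="femur", keep_end="distal", target_height=3.0, cut_plane_z=1.5
        )
        with pytest.raises(TrimmingError):
            exclusion_mask(mesh, spec, margin=2.0)
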