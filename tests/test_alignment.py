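"""Rigid registration, template construction and correspondence."""

import numpy as np
import pytest

from aortashape.alignment import (
    RigidTransform,
    build_template,
    correspond,
    icp_rigid,
    kabsch,
    select_initial_reference,
    tube_frame_landmarks,
    tube_frame_pose,
)
from aortashape.errors import DegenerateInputError
from aortashape.mesh_io import CohortTable, SurfaceMesh
from aortashape.sampling import PointCloud, resample_surface
from aortashape.synthetic import _random_rigid
import pandas as pd


@pytest.fixture(scope="module")
def tube_cloud(tube_subject):
    mesh, _ = tube_subject
    return resample_surface(mesh, 1500, seed=1)


class TestRigidTransform:
    def test_compose_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            T = _random_rigid(rng, 90, 100)
            pts = rng.normal(size=(20, 3))
            assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-10)
            comp = T.compose(T.inverse())
            assert comp.rotation_angle_deg() < 1e-9
            assert np.linalg.norm(comp.translation) < 1e-9

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper orthogonal"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


def test_kabsch_recovers_known_transform():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(40, 3))
    T = _random_rigid(rng, 120, 30)
    est = kabsch(pts, T.apply(pts))
    assert est.compose(T.inverse()).rotation_angle_deg() < 1e-9


class TestICP:
    def test_source_equals_target_gives_identity(self, tube_cloud):
        res = icp_rigid(tube_cloud, tube_cloud)
        # arccos of a trace this close to 3 bottoms out around 1e-6 deg
        assert res.transform.rotation_angle_deg() < 1e-4
        assert np.linalg.norm(res.transform.translation) < 1e-9
        assert res.rmsd < 1e-9

    def test_known_transform_recovered_tightly(self, tube_cloud):
        """Rotations up to 30 deg / 50 mm recovered within 0.1 deg / 0.01 mm."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            T = _random_rigid(rng, 30, 50)
            moved = tube_cloud.transformed(T.rotation, T.translation)
            res = icp_rigid(moved, tube_cloud, tol=1e-12)
            rel = res.transform.compose(T)
            assert rel.rotation_angle_deg() < 0.1
            assert np.linalg.norm(rel.translation) < 0.01

    def test_rmsd_history_non_increasing(self, tube_cloud):
        rng = np.random.default_rng(6)
        T = _random_rigid(rng, 25, 40)
        moved = tube_cloud.transformed(T.rotation, T.translation)
        res = icp_rigid(moved, tube_cloud)
        diffs = np.diff(res.rmsd_history)
        assert np.all(diffs <= 1e-9)

    def test_degenerate_inputs_rejected(self):
        tiny = PointCloud(np.zeros((2, 3)))
        with pytest.raises(DegenerateInputError, match=">= 3"):
            icp_rigid(tiny, tiny)
        line = PointCloud(np.outer(np.arange(10.0), [1, 0, 0]))
        with pytest.raises(DegenerateInputError, match="collinear"):
            icp_rigid(line, line)


class TestSelectInitialReference:
    @staticmethod
    def _cohort(diams, ids=None):
        ids = ids or [f"s{i}" for i in range(len(diams))]
        return CohortTable(pd.DataFrame({"subject_id": ids, "diameter_midaa": diams}))

    def test_exact_mean_member(self):
        assert select_initial_reference(self._cohort([40, 44, 48])) == "s1"

    def test_nearest_to_mean(self):
        assert select_initial_reference(self._cohort([40, 45, 49])) == "s1"

    def test_tie_breaks_lexicographically(self):
        cohort = self._cohort([43, 45], ids=["zeta", "alpha"])
        assert select_initial_reference(cohort) == "alpha"

    def test_missing_diameter_lists_subjects(self):
        cohort = self._cohort([44, np.nan, 45])
        with pytest.raises(ValueError, match="s1"):
            select_initial_reference(cohort)


class TestCorrespond:
    def test_identity_when_subject_equals_template(self, tube_cloud):
        out = correspond(tube_cloud.points, tube_cloud.points, refine="nearest")
        assert np.array_equal(out, tube_cloud.points)

    def test_permutation_invariance(self, tube_cloud):
        rng = np.random.default_rng(2)
        perm = rng.permutation(tube_cloud.n_points)
        out = correspond(tube_cloud.points, tube_cloud.points[perm], refine="nearest")
        assert np.allclose(out, tube_cloud.points)

    def test_uniform_radial_offset_measured_on_cylinder(self, straight_cylinder):
        mesh, _ = straight_cylinder
        template = resample_surface(mesh, 2000, seed=4).points
        r = np.linalg.norm(mesh.vertices[:, :2], axis=1, keepdims=True)
        offset_vertices = mesh.vertices + np.column_stack(
            [mesh.vertices[:, 0] / r[:, 0], mesh.vertices[:, 1] / r[:, 0], np.zeros(len(r))]
        )
        subject = resample_surface(SurfaceMesh(offset_vertices, mesh.faces), 4000, seed=5)
        feet = correspond(template, subject.points, refine="quadric")
        d = np.linalg.norm(feet - template, axis=1)
        interior = np.abs(template[:, 2] - 50.0) < 40.0  # away from open rims
        assert abs(np.median(d[interior]) - 1.0) < 0.05


class TestBuildTemplate:
    def test_common_shape_recovered_from_rigid_perturbations(self, tube_cloud):
        rng = np.random.default_rng(7)
        clouds = []
        for i in range(10):
            T = _random_rigid(rng, 30, 50)
            c = tube_cloud.transformed(T.rotation, T.translation)
            c.subject_id = f"s{i}"
            clouds.append(c)
        template, transforms = build_template(clouds, reference=0, icp_tol=1e-12)
        rmsd = np.sqrt(np.mean(np.sum((template.points - clouds[0].points) ** 2, axis=1)))
        assert rmsd < 0.01
        for c, t in zip(clouds, transforms):
            aligned = t.apply(c.points)
            assert np.allclose(aligned, clouds[0].points, atol=1e-6)

    def test_unconverged_flag_with_zero_tolerance(self, tube_cloud):
        rng = np.random.default_rng(8)
        clouds = [
            tube_cloud.transformed(*(lambda T: (T.rotation, T.translation))(_random_rigid(rng, 10, 10)))
            for _ in range(3)
        ]
        template, _ = build_template(clouds, reference=0, max_rounds=1, tol=0.0)
        assert template.converged is False
        assert template.iteration_count == 1

    def test_two_clouds_give_midpoint_shape(self):
        base = np.random.default_rng(9).normal(size=(200, 3)) * 10
        a = PointCloud(base.copy(), "a")
        b = PointCloud(base + np.array([0.0, 0.0, 0.4]), "b")
        template, _ = build_template([a, b], reference=0, max_rounds=0)
        # midpoint up to the rigid re-alignment of b onto a
        assert template.n_points == 200

    def test_mismatched_sizes_rejected(self, tube_cloud):
        other = PointCloud(tube_cloud.points[:500], "short")
        with pytest.raises(ValueError, match="equal N"):
            build_template([tube_cloud, other])

    def test_equivariance_under_global_transform(self, tube_cloud):
        """Rigidly moving every input moves the template rigidly, nothing more."""
        rng = np.random.default_rng(11)
        clouds = []
        for i in range(5):
            T = _random_rigid(rng, 20, 30)
            c = tube_cloud.transformed(T.rotation, T.translation)
            c.subject_id = f"s{i}"
            clouds.append(c)
        t1, _ = build_template(clouds, reference=0)
        G = _random_rigid(rng, 40, 60)
        moved = [c.transformed(G.rotation, G.translation) for c in clouds]
        t2, _ = build_template(moved, reference=0)
        assert np.allclose(G.apply(t1.points), t2.points, atol=1e-6)


class TestTubeFrameRegistration:
    def test_pose_of_rigidly_moved_mesh_recovered_exactly(self, tube_subject):
        mesh, _ = tube_subject
        lm0 = tube_frame_landmarks(mesh)
        rng = np.random.default_rng(12)
        for _ in range(3):
            T = _random_rigid(rng, 30, 50)
            moved = SurfaceMesh(T.apply(mesh.vertices), mesh.faces, "m")
            pose = tube_frame_pose(tube_frame_landmarks(moved), lm0)
            rel = pose.compose(T)
            assert rel.rotation_angle_deg() < 0.01
            assert np.linalg.norm(rel.translation) < 0.01

    def test_end_to_end_orientation_resolved(self, tube_subject):
        """A flipped copy of the tube still registers un-flipped."""
        mesh, _ = tube_subject
        lm0 = tube_frame_landmarks(mesh)
        # 180-degree rotation about the chord axis approximates a flip
        chord = lm0.centers[-1] - lm0.centers[0]
        axis = chord / np.linalg.norm(chord)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + 2.0 * (K @ K)  # Rodrigues at angle pi
        T = RigidTransform(R, np.array([5.0, -3.0, 8.0]))
        moved = SurfaceMesh(T.apply(mesh.vertices), mesh.faces, "m")
        pose = tube_frame_pose(tube_frame_landmarks(moved), lm0)
        rel = pose.compose(T)
        assert rel.rotation_angle_deg() < 1.0

    def test_population_pose_consistency(self, recovery_cohort):
        """Residual pose scatter across deformed, perturbed subjects stays small."""
        from aortashape.pipeline import _landmark_poses

        meshes = recovery_cohort.meshes[:30]
        poses = _landmark_poses(meshes, 0)
        rels = [
            poses[i].compose(recovery_cohort.truth.transforms[i]) for i in range(30)
        ]
        G = rels[0]
        angles = [r.compose(G.inverse()).rotation_angle_deg() for r in rels]
        assert np.median(angles) < 3.0
        assert max(angles) < 15.0
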