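import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from erupt3d.core_io import RigidTransform, TriangleMesh
from erupt3d.eruption_analysis import (AnatomicalFrame, EruptionMeasures,
                                       IcpParams, assess_eruption, compose,
                                       decompose, icp_register, mesh_centroid,
                                       mesh_volume, nearest_rotation)


def _rigid(angles_deg, translation, center=(0, 0, 0)):
    r = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
    center = np.asarray(center, float)
    about = RigidTransform.from_rotation_translation(r, center - r @ center)
    return RigidTransform.from_rotation_translation(
        np.eye(3), np.asarray(translation, float)).compose(about)


# ---------------------------------------------------------------------------
# ICP


def test_icp_identity_on_identical_meshes(tooth_mesh):
    t = icp_register(tooth_mesh, tooth_mesh, IcpParams(seed=0))
    assert np.linalg.norm(t.translation) < 1e-6
    assert np.rad2deg(Rotation.from_matrix(t.rotation).magnitude()) < 1e-5


@pytest.mark.parametrize("angles,shift", [
    ((3.0, -5.0, 7.5), (1.2, -0.4, 2.6)),
    ((-8.0, 2.0, -1.0), (-2.9, 0.1, 0.5)),
])
def test_icp_recovers_known_transform_on_clean_meshes(tooth_mesh, angles, shift):
    center = mesh_centroid(tooth_mesh)
    truth = _rigid(angles, shift, center)
    moved = tooth_mesh.transformed(truth)
    # clean data: nothing to trim, and a tight tolerance is affordable
    t = icp_register(tooth_mesh, moved,
                     IcpParams(seed=1, trim_fraction=0.0, tol_mm=1e-5))
    err_t = np.linalg.norm(t.apply(center) - truth.apply(center))
    err_r = Rotation.from_matrix(t.rotation @ truth.rotation.T).magnitude()
    assert err_t < 1e-3
    assert np.rad2deg(err_r) < 0.01


def test_icp_trimming_rejects_outlier_vertices(tooth_mesh):
    center = mesh_centroid(tooth_mesh)
    truth = _rigid((2.0, 4.0, -3.0), (0.8, -1.1, 1.9), center)
    moved = tooth_mesh.transformed(truth)
    rng = np.random.default_rng(2)
    verts = moved.vertices.copy()
    hit = rng.choice(len(verts), size=len(verts) // 5, replace=False)
    verts[hit] += rng.normal(scale=1.0 / np.sqrt(3), size=(len(hit), 3))
    corrupted = TriangleMesh(verts, moved.faces)
    t = icp_register(tooth_mesh, corrupted, IcpParams(seed=3, trim_fraction=0.25))
    err_t = np.linalg.norm(t.apply(center) - truth.apply(center))
    err_r = Rotation.from_matrix(t.rotation @ truth.rotation.T).magnitude()
    assert err_t < 0.05
    assert np.rad2deg(err_r) < 0.1


def test_icp_rms_history_attached(tooth_mesh):
    t = icp_register(tooth_mesh, tooth_mesh, IcpParams(seed=0))
    assert t.meta["rms_history"]
    assert t.meta["final_rms_mm"] < 1e-6


# ---------------------------------------------------------------------------
# nearest_rotation


def test_nearest_rotation_fixes_orthonormal_input():
    r = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    np.testing.assert_allclose(nearest_rotation(r), r, atol=1e-12)


def test_nearest_rotation_beats_random_rotations():
    rng = np.random.default_rng(4)
    r = Rotation.random(random_state=5).as_matrix()
    noisy = r + 1e-3 * rng.normal(size=(3, 3))
    fixed = nearest_rotation(noisy)
    np.testing.assert_allclose(fixed.T @ fixed, np.eye(3), atol=1e-12)
    d_fixed = np.linalg.norm(noisy - fixed)
    for _ in range(20):
        other = Rotation.random(random_state=rng).as_matrix()
        assert d_fixed <= np.linalg.norm(noisy - other)


def test_nearest_rotation_repairs_reflection():
    refl = np.diag([-1.0, 1.0, 1.0])
    out = nearest_rotation(refl)
    assert np.linalg.det(out) == pytest.approx(1.0)


def test_nearest_rotation_singular_rejected():
    with pytest.raises(ValueError, match="singular"):
        nearest_rotation(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# Decomposition


FRAME = AnatomicalFrame.identity()


def test_identity_decomposes_to_zero():
    m = decompose(RigidTransform.identity(), FRAME, [3.0, 2.0, 1.0])
    np.testing.assert_allclose(m.components(), 0.0, atol=1e-12)


def test_pure_incisal_translation():
    t = RigidTransform.from_rotation_translation(np.eye(3), [0, 0, 1.0])
    m = decompose(t, FRAME, [5.0, 5.0, 5.0])
    np.testing.assert_allclose(
        m.components(), [0, 0, 1.0, 0, 0, 0], atol=1e-12)


def test_worked_example_round_trip():
    """Translations (1.4 mesial, 1.4 facial, 2.4 incisal) mm with rotations
    (4.5, 6.3, 6.0) deg about the centroid survive compose -> decompose to
    1e-9 (the magnitudes of a reported non-cleft erupted canine)."""
    centroid = np.array([11.2, 11.2, 18.5])
    target = EruptionMeasures(1.4, 1.4, 2.4, 4.5, 6.3, 6.0)
    t = compose(target, FRAME, centroid)
    back = decompose(t, FRAME, centroid)
    np.testing.assert_allclose(back.components(), target.components(), atol=1e-9)


def test_yaw_quarter_turn():
    centroid = np.zeros(3)
    t = _rigid((0, 0, 90.0), (0, 0, 0), centroid)
    m = decompose(t, FRAME, centroid)
    np.testing.assert_allclose(m.components(), [0, 0, 0, 0, 0, 90.0], atol=1e-9)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        comps=st.tuples(
            st.floats(-4, 4), st.floats(-4, 4), st.floats(-4, 4),
            st.floats(-170, 170), st.floats(-80, 80), st.floats(-170, 170)),
        side=st.sampled_from(["left", "right"]),
    )
    def test_compose_decompose_round_trip_property(comps, side):
        """For any six components (roll away from the gimbal band) and
        either side flag, compose and decompose are exact inverses."""
        frame = AnatomicalFrame.identity(side=side)
        centroid = np.array([3.0, -1.0, 2.0])
        target = EruptionMeasures(*comps)
        back = decompose(compose(target, frame, centroid), frame, centroid)
        np.testing.assert_allclose(back.components(), target.components(),
                                   atol=1e-9)
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_round_trip_1000_random_transforms():
    rng = np.random.default_rng(6)
    frame = AnatomicalFrame(Rotation.random(random_state=8).as_matrix())
    centroid = np.array([4.0, -2.0, 7.0])
    n = 0
    while n < 1000:
        angles = rng.uniform(-170, 170, 3)
        if abs(angles[1]) > 85:
            continue
        n += 1
        target = EruptionMeasures(*rng.uniform(-4, 4, 3), *angles)
        t = compose(target, frame, centroid)
        back = decompose(t, frame, centroid)
        np.testing.assert_allclose(back.components(), target.components(),
                                   atol=1e-9)


def test_frame_equivariance():
    """Rotating the scene (transform, frame, centroid) together leaves the
    six components unchanged."""
    rng = np.random.default_rng(7)
    frame = AnatomicalFrame.identity()
    centroid = np.array([1.0, 2.0, 3.0])
    t = _rigid((4.0, -6.0, 3.0), (1.1, 0.4, -2.0), centroid)
    base = decompose(t, frame, centroid)
    for _ in range(5):
        g = _rigid(rng.uniform(-90, 90, 3), rng.uniform(-10, 10, 3))
        t_g = g.compose(t).compose(g.inverse())
        frame_g = frame.transformed(g)
        m = decompose(t_g, frame_g, g.apply(centroid))
        np.testing.assert_allclose(m.components(), base.components(), atol=1e-6)


def test_pure_rotation_about_centroid_has_zero_translation():
    rng = np.random.default_rng(8)
    centroid = np.array([-3.0, 5.0, 2.0])
    for _ in range(20):
        t = _rigid(rng.uniform(-80, 80, 3), (0, 0, 0), centroid)
        m = decompose(t, FRAME, centroid)
        np.testing.assert_allclose(m.components()[:3], 0.0, atol=1e-9)


def test_side_consistency_under_mirroring():
    """Mirroring the scene left<->right and flipping the side flag yields
    identical measures (in particular dMD)."""
    mirror = np.diag([-1.0, 1.0, 1.0])
    centroid = np.array([2.0, 1.0, -4.0])
    t = _rigid((5.0, -3.0, 8.0), (1.2, -0.7, 2.1), centroid)
    left = decompose(t, AnatomicalFrame.identity(side="left"), centroid)

    t_m = RigidTransform.from_rotation_translation(
        mirror @ t.rotation @ mirror, mirror @ t.translation)
    m_frame = AnatomicalFrame.identity(side="left").mirrored()
    assert m_frame.side == "right"
    right = decompose(t_m, m_frame, mirror @ centroid)
    np.testing.assert_allclose(right.components(), left.components(), atol=1e-9)


def test_gimbal_proximity_flagged():
    t = _rigid((10.0, 90.0, -20.0), (0, 0, 0))
    with pytest.warns(UserWarning, match="degenerate"):
        m = decompose(t, FRAME, np.zeros(3))
    assert m.gimbal_warning


# ---------------------------------------------------------------------------
# Volumes


def test_unit_cube_volume():
    import trimesh

    cube = trimesh.creation.box(extents=(1, 1, 1))
    mesh = TriangleMesh(np.asarray(cube.vertices), np.asarray(cube.faces))
    assert mesh_volume(mesh) == pytest.approx(1.0, abs=1e-12)


def test_icosphere_volume():
    import trimesh

    ico = trimesh.creation.icosphere(4, radius=5.0)
    mesh = TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
    assert mesh_volume(mesh) == pytest.approx(523.5988, rel=0.005)


def test_volume_translation_invariant(tooth_mesh):
    t = RigidTransform.from_rotation_translation(np.eye(3), [10.0, -4.0, 2.0])
    assert mesh_volume(tooth_mesh.transformed(t)) == pytest.approx(
        mesh_volume(tooth_mesh), rel=1e-12)


def test_open_mesh_rejected_with_edge_count():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
    single = TriangleMesh(verts, np.array([[0, 1, 2]]))
    with pytest.raises(ValueError, match="3 boundary edges"):
        mesh_volume(single)


# ---------------------------------------------------------------------------
# Frames


def test_frame_from_landmarks_orthonormal_right_handed():
    f = AnatomicalFrame.from_landmarks([0, 0, 0], [3.0, 0.5, 0.2],
                                       [0.4, 2.0, -0.1], side="right")
    np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(f.axes) == pytest.approx(1.0)
    assert f.side == "right"


def test_degenerate_landmarks_rejected():
    with pytest.raises(ValueError):
        AnatomicalFrame.from_landmarks([0, 0, 0], [0, 0, 0], [1, 0, 0])
    with pytest.raises(ValueError):
        AnatomicalFrame.from_landmarks([0, 0, 0], [1, 0, 0], [2, 0, 0])


# ---------------------------------------------------------------------------
# Full assessment


def test_assess_identical_meshes_all_zero(tooth_mesh):
    m = assess_eruption(tooth_mesh, tooth_mesh, FRAME, IcpParams(seed=0))
    np.testing.assert_allclose(m.components()[:3], 0.0, atol=1e-4)
    np.testing.assert_allclose(m.components()[3:], 0.0, atol=1e-3)
    assert m.volume_pre == pytest.approx(m.volume_post)


def test_assess_recovers_phantom_motion(pipeline_result, phantom_pair):
    from erupt3d.pipeline import truth_measures

    truth = truth_measures(phantom_pair)
    err = pipeline_result.measures.components() - truth.components()
    assert np.all(np.abs(err[:3]) <= 0.1)
    assert np.all(np.abs(err[3:]) <= 0.5)
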