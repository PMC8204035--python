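import numpy as np
import pytest

from erupt3d.core_io import ImageVolume
from erupt3d.eruption_analysis import mesh_volume
from erupt3d.tooth_segmentation import (LivewireParams, SliceContour,
                                        auto_segment_phantom, close_contour,
                                        interpolate_contours, livewire_cost,
                                        livewire_path, mesh_from_mask)


# ---------------------------------------------------------------------------
# Livewire cost


def test_constant_slice_uniform_cost_with_warning():
    with pytest.warns(UserWarning, match="constant"):
        cost = livewire_cost(np.full((10, 10), 3.0))
    assert np.allclose(cost, cost.flat[0])


def test_step_edge_column_has_minimal_cost():
    img = np.zeros((20, 20))
    img[:, 10:] = 100.0
    cost = livewire_cost(img, LivewireParams(1.0, 0.0, 0.0))
    # finite-difference oracle for the gradient term
    gy, gx = np.gradient(img)
    g = np.hypot(gx, gy)
    expected = 1.0 - g / g.max()
    np.testing.assert_allclose(cost, expected, atol=1e-12)
    interior = cost[2:-2]
    edge_cols = interior[:, [9, 10]]
    flat_cols = interior[:, [2, 3, 16, 17]]
    assert edge_cols.max() < flat_cols.min()


def test_cost_bounded_by_weight_sum():
    rng = np.random.default_rng(0)
    params = LivewireParams(0.43, 0.43, 0.14)
    for _ in range(5):
        img = rng.normal(size=(15, 17))
        cost = livewire_cost(img, params)
        assert cost.min() >= -1e-12
        assert cost.max() <= 0.43 + 0.43 + 0.14 + 1e-12


def test_livewire_params_validation():
    with pytest.raises(ValueError):
        LivewireParams(-0.1, 0.5, 0.5)
    with pytest.raises(ValueError):
        LivewireParams(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Livewire path


def test_path_seed_equals_target():
    cost = np.ones((5, 5))
    path = livewire_path(cost, (2, 2), (2, 2))
    assert path.shape == (1, 2)


def test_uniform_cost_path_has_chebyshev_length():
    cost = np.ones((30, 30))
    path = livewire_path(cost, (3, 4), (20, 11))
    assert len(path) - 1 == max(abs(20 - 3), abs(11 - 4))


def _csgraph_oracle(cost, seed, target):
    """Independent shortest-path: scipy.sparse.csgraph on the 8-connected
    lattice with the same into-pixel link costs."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    nr, nc = cost.shape
    n = nr * nc
    g = lil_matrix((n, n))
    for r in range(nr):
        for c in range(nc):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        w = cost[rr, cc] * (np.sqrt(2) if dr and dc else 1.0)
                        g[r * nc + c, rr * nc + cc] = w + 1e-300  # keep 0 edges
    d = cs_dijkstra(g.tocsr(), indices=seed[0] * nc + seed[1])
    return d[target[0] * nc + target[1]]


@pytest.mark.parametrize("seed_rng", [1, 2, 3])
def test_path_cost_matches_csgraph_oracle(seed_rng):
    rng = np.random.default_rng(seed_rng)
    cost = rng.uniform(0.0, 1.0, size=(20, 20))
    seed, target = (1, 2), (17, 15)
    path = livewire_path(cost, seed, target)
    sqrt2 = np.sqrt(2)
    total = sum(cost[tuple(q)] * (sqrt2 if (abs(q[0] - p[0]) and abs(q[1] - p[1]))
                                  else 1.0)
                for p, q in zip(path[:-1], path[1:]))
    oracle = _csgraph_oracle(cost, seed, target)
    assert total == pytest.approx(oracle, abs=1e-9)


def test_path_hugs_synthetic_disk_boundary():
    n = 80
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot(xx - 40, yy - 40)
    img = (r <= 30).astype(float) * 100.0
    cost = livewire_cost(img)
    # two boundary points a quarter turn apart
    seed = (40 + 30, 40)
    target = (40, 40 + 30)
    path = livewire_path(cost, seed, target)
    dist_to_circle = np.abs(np.hypot(path[:, 1] - 40, path[:, 0] - 40) - 30)
    assert np.mean(dist_to_circle <= 1.5) >= 0.95


def test_path_endpoints_validated():
    with pytest.raises(ValueError, match="outside"):
        livewire_path(np.ones((5, 5)), (0, 0), (9, 0))


# ---------------------------------------------------------------------------
# Contour closing


def _ident_mm(p):
    return (float(p[1]), float(p[0]))  # (col, row) -> (x, y) mm


def test_square_from_four_segments():
    a = np.array([[0, 0], [0, 5]])
    b = np.array([[0, 5], [5, 5]])
    c = np.array([[5, 5], [5, 0]])
    d = np.array([[5, 0], [0, 0]])
    contour = close_contour([a, b, c, d], "axial", 0, _ident_mm)
    from shapely.geometry import Polygon

    assert Polygon(contour.points).area == pytest.approx(25.0)


def test_reversed_segments_give_same_polygon():
    a = np.array([[0, 0], [0, 5]])
    b = np.array([[0, 5], [5, 5]])
    c = np.array([[5, 5], [5, 0]])
    d = np.array([[5, 0], [0, 0]])
    c1 = close_contour([a, b, c, d], "axial", 0, _ident_mm)
    c2 = close_contour([a, b[::-1], c, d[::-1]], "axial", 0, _ident_mm)
    np.testing.assert_allclose(c1.points, c2.points)


def test_traced_disk_area():
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    img = (np.hypot(xx - 32, yy - 32) <= 20).astype(float) * 100
    cost = livewire_cost(img)
    anchors = [(32 + 20, 32), (32, 32 + 20), (32 - 20, 32), (32, 32 - 20)]
    segs = [livewire_path(cost, anchors[i], anchors[(i + 1) % 4])
            for i in range(4)]
    contour = close_contour(segs, "axial", 0, _ident_mm)
    from shapely.geometry import Polygon

    assert Polygon(contour.points).area == pytest.approx(np.pi * 400, rel=0.06)


def test_non_chaining_segments_rejected():
    a = np.array([[0, 0], [0, 5]])
    b = np.array([[3, 3], [4, 4]])
    with pytest.raises(ValueError, match="chain"):
        close_contour([a, b], "axial", 0, _ident_mm)


# ---------------------------------------------------------------------------
# Shape-based interpolation


def _circle_contour(k, cx, cy, r, n=48, axis="axial"):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return SliceContour(axis, k, np.column_stack([cx + r * np.cos(th),
                                                  cy + r * np.sin(th)]))


def _grid(shape=(12, 40, 40), spacing=0.5):
    return ImageVolume(np.zeros(shape, np.uint8), np.full(3, spacing),
                       np.full(3, spacing / 2))


def test_identical_circles_reproduce_between_slices():
    target = _grid()
    c0 = _circle_contour(0, 10.0, 10.0, 6.0)
    c4 = _circle_contour(4, 10.0, 10.0, 6.0)
    out = interpolate_contours([c0, c4], target)
    ref = out.data[0].astype(bool)
    assert ref.sum() > 100
    for k in range(1, 5):
        inter = out.data[k].astype(bool)
        dice = 2 * (ref & inter).sum() / (ref.sum() + inter.sum())
        assert dice >= 0.98
    assert out.data[5:].sum() == 0  # nothing beyond the contoured range


def test_linear_radius_interpolation():
    target = _grid(shape=(12, 60, 60))
    c0 = _circle_contour(0, 15.0, 15.0, 2.5)     # r = 5 px at 0.5 mm/px
    c10 = _circle_contour(10, 15.0, 15.0, 5.0)   # r = 10 px
    out = interpolate_contours([c0, c10], target)
    area = out.data[5].sum()
    r_mid_px = np.sqrt(area / np.pi)
    assert r_mid_px == pytest.approx(7.5, abs=1.0)


def test_orthogonal_constraint_only_carves():
    target = _grid()
    axial = [_circle_contour(0, 10.0, 10.0, 6.0), _circle_contour(6, 10.0, 10.0, 6.0)]
    free = interpolate_contours(axial, target)
    # a tight coronal contour at the mid plane: (x, z) coordinates
    j = 20  # y-index of the carved plane
    coronal = SliceContour("coronal", j, np.array(
        [[7.0, 0.0], [13.0, 0.0], [13.0, 6.0], [7.0, 6.0]]))
    carved = interpolate_contours(axial + [coronal], target)
    assert carved.data.sum() < free.data.sum()
    assert np.all(carved.data <= free.data)


def test_single_contour_rejected():
    with pytest.raises(ValueError, match="2 axial"):
        interpolate_contours([_circle_contour(0, 10, 10, 5)], _grid())


def test_duplicate_indices_rejected():
    cs = [_circle_contour(3, 10, 10, 5), _circle_contour(3, 10, 10, 4)]
    with pytest.raises(ValueError, match="duplicate"):
        interpolate_contours(cs, _grid())


# ---------------------------------------------------------------------------
# Surfacing


def test_voxelized_sphere_mesh_volume():
    spacing = 0.2
    n = 60
    c = (n / 2) * spacing
    half = spacing / 2
    ax = half + spacing * np.arange(n)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = ((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) <= 5.0 ** 2
    vol = ImageVolume(mask.astype(np.uint8), np.full(3, spacing), np.full(3, half))
    mesh = mesh_from_mask(vol)
    assert mesh.is_closed()
    assert mesh_volume(mesh) == pytest.approx(4 / 3 * np.pi * 125, rel=0.02)


def test_single_voxel_mask():
    data = np.zeros((5, 5, 5), np.uint8)
    data[2, 2, 2] = 1
    vol = ImageVolume(data, np.full(3, 0.2), np.zeros(3))
    mesh = mesh_from_mask(vol)
    assert mesh.is_closed()
    # marching cubes turns one voxel into an octahedron with vertices at the
    # half-voxel midpoints: volume = (2h)^3 / 6 with h = half voxel
    assert mesh_volume(mesh) == pytest.approx(0.2 ** 3 / 6, rel=1e-6)


def test_empty_mask_rejected():
    vol = ImageVolume(np.zeros((4, 4, 4), np.uint8), np.full(3, 0.2), np.zeros(3))
    with pytest.raises(ValueError, match="empty"):
        mesh_from_mask(vol)


# ---------------------------------------------------------------------------
# Phantom auto-segmentation


def test_auto_segment_noiseless_phantom_volume():
    from dataclasses import replace

    from erupt3d.phantom import PhantomSpec, analytic_tooth_volume, generate_pair

    spec = replace(PhantomSpec(), noise_sd=0.0, seed=12)
    pair = generate_pair(spec)
    mesh = auto_segment_phantom(pair.pre, (1200.0, np.inf))
    assert mesh_volume(mesh) == pytest.approx(analytic_tooth_volume(spec), rel=0.03)


def test_auto_segment_noisy_phantom_volume(phantom_pair):
    from erupt3d.phantom import analytic_tooth_volume

    mesh = auto_segment_phantom(phantom_pair.pre, (1200.0, np.inf))
    assert mesh_volume(mesh) == pytest.approx(
        analytic_tooth_volume(phantom_pair.spec), rel=0.05)


def test_auto_segment_band_above_max_rejected(phantom_pair):
    with pytest.raises(ValueError, match="band"):
        auto_segment_phantom(phantom_pair.pre, (1e6, 2e6))


def test_cohort_segmentation_volume_accuracy(cohort20):
    """Across 10 phantom teeth the segmented volume tracks the analytic
    solid volume to 5%."""
    from erupt3d.phantom import analytic_tooth_volume

    for pair in cohort20[0][:10]:
        v = mesh_volume(auto_segment_phantom(pair.pre, (1200.0, np.inf)))
        assert v == pytest.approx(analytic_tooth_volume(pair.spec), rel=0.05)
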