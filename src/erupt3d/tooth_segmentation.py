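"""Semi-automatic tooth delineation.

The interactive workflow is livewire contouring: the user drops anchor
points on a slice and the computer pulls the contour onto the tooth edge by
minimum-cost paths through an edge-sensitive cost image (Mortensen-Barrett
style local costs, Dijkstra search). Contours drawn on axial slices are
fused into a binary volume by shape-based interpolation (per-slice signed
distance fields, linearly interpolated along the slice axis); contours from
the coronal/sagittal views act as carving constraints. The binary volume is
surfaced with marching cubes at the 0.5 level.

For unattended phantom runs, :func:`auto_segment_phantom` replaces the
interactive step with intensity-band thresholding.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.measure import marching_cubes

from .core_io import ImageVolume, TriangleMesh

__all__ = [
    "LivewireParams",
    "SliceContour",
    "livewire_cost",
    "livewire_path",
    "close_contour",
    "interpolate_contours",
    "mesh_from_mask",
    "auto_segment_phantom",
]

AXES = ("axial", "coronal", "sagittal")   # slice axis = z, y, x respectively


@dataclass
class LivewireParams:
    """Local-cost weights: gradient magnitude, Laplacian zero-crossing,
    gradient-direction smoothness (Mortensen-Barrett defaults)."""

    w_gradient: float = 0.43
    w_zero_crossing: float = 0.43
    w_direction: float = 0.14

    def __post_init__(self) -> None:
        w = (self.w_gradient, self.w_zero_crossing, self.w_direction)
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("weights must be non-negative with positive sum")


@dataclass
class SliceContour:
    """A closed simple polygon on one slice, in in-slice mm coordinates.

    In-slice point order: axial -> (x, y), coronal -> (x, z),
    sagittal -> (y, z).
    """

    axis: str
    index: int
    points: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        if not Polygon(self.points).is_simple:
            raise ValueError("contour polygon is self-intersecting")


# ---------------------------------------------------------------------------
# Livewire


def livewire_cost(slice_image: np.ndarray, params: LivewireParams | None = None) -> np.ndarray:
    """Per-pixel local cost in [0, w_g + w_z + w_d]; strong edges are cheap.

    Terms: ``w_g * (1 - g/g_max)`` (gradient magnitude), ``w_z * z``
    (0 on Laplacian zero-crossings, 1 elsewhere) and ``w_d * d`` (local
    disagreement of gradient direction with the 4-neighbour mean, as an
    angle fraction of pi).
    """
    params = params or LivewireParams()
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("slice must be a 2D image of at least 3x3 pixels")

    gy, gx = np.gradient(img)
    g = np.hypot(gx, gy)
    g_max = g.max()
    if g_max == 0:
        warnings.warn("constant slice: livewire cost is spatially uniform",
                      stacklevel=2)
        g_term = np.ones_like(img)
    else:
        g_term = 1.0 - g / g_max

    lap = ndimage.laplace(img)
    z_term = np.ones_like(img)
    sign = np.sign(lap)
    crossing = np.zeros_like(img, dtype=bool)
    for shift_axis, shift in (((0,), 1), ((0,), -1), ((1,), 1), ((1,), -1)):
        rolled = np.roll(sign, shift, axis=shift_axis)
        crossing |= (sign * rolled) < 0
    z_term[crossing | (sign == 0)] = 0.0

    # direction term: angle between the gradient and its 4-neighbour mean
    norm = np.maximum(g, 1e-12)
    ux, uy = gx / norm, gy / norm
    mx = sum(np.roll(ux, s, axis=a) for a, s in ((0, 1), (0, -1), (1, 1), (1, -1))) / 4.0
    my = sum(np.roll(uy, s, axis=a) for a, s in ((0, 1), (0, -1), (1, 1), (1, -1))) / 4.0
    dot = np.clip(ux * mx + uy * my, -1.0, 1.0)
    d_term = np.where(g > 0, np.arccos(dot) / np.pi, 0.0)

    return (params.w_gradient * g_term + params.w_zero_crossing * z_term
            + params.w_direction * d_term)


_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def livewire_path(cost: np.ndarray, seed: tuple[int, int],
                  target: tuple[int, int]) -> np.ndarray:
    """Minimum-cumulative-cost 8-connected pixel path from seed to target.

    A step into pixel q costs ``cost[q]`` scaled by the step length (1 or
    sqrt(2)); the seed pixel itself is free. Returns an (L, 2) array of
    (row, col) pixels including both endpoints.
    """
    cost = np.asarray(cost, dtype=float)
    nr, nc = cost.shape
    for name, (r, c) in (("seed", seed), ("target", target)):
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"{name} {r, c} outside the image")
    seed = tuple(map(int, seed))
    target = tuple(map(int, target))
    if seed == target:
        return np.array([seed])

    dist = np.full(cost.shape, np.inf)
    dist[seed] = 0.0
    prev = np.full(cost.shape + (2,), -1, dtype=np.int32)
    heap = [(0.0, seed)]
    visited = np.zeros(cost.shape, dtype=bool)
    sqrt2 = np.sqrt(2.0)
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if visited[r, c]:
            continue
        if (r, c) == target:
            break
        visited[r, c] = True
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not visited[rr, cc]:
                step = sqrt2 if dr and dc else 1.0
                nd = d + cost[rr, cc] * step
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    prev[rr, cc] = (r, c)
                    heapq.heappush(heap, (nd, (rr, cc)))
    path = [target]
    while tuple(path[-1]) != seed:
        path.append(tuple(prev[tuple(path[-1])]))
    return np.array(path[::-1])


def close_contour(segments: list[np.ndarray], axis: str, index: int,
                  pixel_to_mm) -> SliceContour:
    """Chain livewire path segments head-to-tail into a closed contour.

    ``pixel_to_mm`` maps (row, col) pixels to in-slice mm coordinates.
    Segment order/orientation is normalized: a segment is reversed when its
    tail, not its head, continues the chain. Raises if the resulting polygon
    self-intersects.
    """
    if not segments:
        raise ValueError("no path segments given")
    segs = [np.asarray(s, dtype=float).reshape(-1, 2) for s in segments]
    chain = [segs[0]]
    for s in segs[1:]:
        tail = chain[-1][-1]
        if np.allclose(s[0], tail):
            chain.append(s)
        elif np.allclose(s[-1], tail):
            chain.append(s[::-1])
        else:
            raise ValueError("segments do not chain head-to-tail")
    pix = np.vstack([c[:-1] for c in chain] + [chain[-1][-1:]])
    # drop the duplicated closing point if the chain returns to the start
    if np.allclose(pix[0], pix[-1]):
        pix = pix[:-1]
    pts = np.asarray([pixel_to_mm(p) for p in pix], dtype=float)
    # orientation/start normalization: counter-clockwise, lexicographic start
    if Polygon(pts).exterior.is_ccw is False:
        pts = pts[::-1]
    start = np.lexsort((pts[:, 1], pts[:, 0]))[0]
    pts = np.roll(pts, -start, axis=0)
    return SliceContour(axis=axis, index=index, points=pts)


# ---------------------------------------------------------------------------
# Shape-based interpolation


def _slice_grid(vol: ImageVolume, axis: str) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """In-slice per-axis mm coordinates (u, v) and slice shape for an axis.

    Convention (matching SliceContour): axial slices are indexed [y, x] with
    in-slice coords (x, y); coronal [z, x] with (x, z); sagittal [z, y] with
    (y, z).
    """
    xs, ys, zs = vol.voxel_center_axes()
    if axis == "axial":
        return xs, ys, (len(ys), len(xs))
    if axis == "coronal":
        return xs, zs, (len(zs), len(xs))
    return ys, zs, (len(zs), len(ys))


def _rasterize(contour: SliceContour, vol: ImageVolume) -> np.ndarray:
    us, vs, shape = _slice_grid(vol, contour.axis)
    # polygon2mask works in index space (row, col) = (v, u)
    rows = np.interp(contour.points[:, 1], vs, np.arange(len(vs)))
    cols = np.interp(contour.points[:, 0], us, np.arange(len(us)))
    return polygon2mask(shape, np.column_stack([rows, cols]))


def _signed_distance(mask: np.ndarray, sampling) -> np.ndarray:
    """Positive outside, negative inside (mm)."""
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    return outside - inside


def interpolate_contours(contours: list[SliceContour],
                         target: ImageVolume) -> ImageVolume:
    """Shape-based interpolation of axial contours into a binary volume.

    Each axial contour is rasterized and converted to a signed distance
    field on its slice; fields are linearly interpolated along z and voxels
    with non-positive interpolated distance become foreground. Coronal and
    sagittal contours carve their planes: foreground there must lie inside
    the covering contour. No foreground is produced outside the axial index
    range.
    """
    axial = sorted((c for c in contours if c.axis == "axial"), key=lambda c: c.index)
    if len(axial) < 2:
        raise ValueError("need at least 2 axial contours to interpolate")
    indices = [c.index for c in axial]
    if len(set(indices)) != len(indices):
        raise ValueError(f"duplicate axial contour indices: {indices}")
    nz = target.data.shape[0]
    if indices[0] < 0 or indices[-1] >= nz:
        raise ValueError("axial contour index outside the target grid")

    sampling = (target.spacing[1], target.spacing[0])   # (y, x) mm
    fields = {c.index: _signed_distance(_rasterize(c, target), sampling)
              for c in axial}

    out = np.zeros(target.data.shape, dtype=bool)
    for k0, k1 in zip(indices[:-1], indices[1:]):
        f0, f1 = fields[k0], fields[k1]
        for k in range(k0, k1 + 1):
            w = (k - k0) / (k1 - k0)
            out[k] = ((1.0 - w) * f0 + w * f1) <= 0.0

    for c in contours:
        if c.axis == "axial":
            continue
        mask = _rasterize(c, target)          # coronal: [z, x]; sagittal: [z, y]
        if c.axis == "coronal":
            out[:, c.index, :] &= mask
        else:
            out[:, :, c.index] &= mask
    return ImageVolume(out.astype(np.uint8), target.spacing.copy(),
                       target.origin.copy(), target.direction.copy())


# ---------------------------------------------------------------------------
# Surfacing


def mesh_from_mask(mask: ImageVolume) -> TriangleMesh:
    """Marching-cubes surface of a binary volume at the 0.5 level (mm).

    The mask is zero-padded first so the surface is always closed; only the
    largest connected surface component is kept.
    """
    data = (np.asarray(mask.data) > 0)
    if not data.any():
        raise ValueError("mask is empty; nothing to surface")
    padded = np.pad(data, 1).astype(np.float32)
    sz, sy, sx = mask.spacing[2], mask.spacing[1], mask.spacing[0]
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=(sz, sy, sx))
    # padded index space -> physical: subtract one voxel, add origin
    verts_mm = np.column_stack([
        verts[:, 2] - sx + mask.origin[0],
        verts[:, 1] - sy + mask.origin[1],
        verts[:, 0] - sz + mask.origin[2],
    ])
    tm = trimesh.Trimesh(vertices=verts_mm, faces=faces, process=False)
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: abs(p.volume))
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if not mesh.is_closed():
        raise RuntimeError("surfacing produced an open mesh")
    return mesh


def auto_segment_phantom(vol: ImageVolume, band: tuple[float, float]) -> TriangleMesh:
    """Non-interactive tooth segmentation for phantom volumes: intensity
    band threshold, largest connected voxel component, marching cubes."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must be (lo, hi) with lo < hi")
    sel = (vol.data >= lo) & (vol.data <= hi)
    if not sel.any():
        raise ValueError(f"no voxels in intensity band [{lo}, {hi}]")
    labels, n = ndimage.label(sel)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        sel = labels == (1 + int(np.argmax(sizes)))
    return mesh_from_mask(ImageVolume(sel.astype(np.uint8), vol.spacing,
                                      vol.origin, vol.direction))
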