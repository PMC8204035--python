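"""Core containers and file I/O for volumes, meshes and rigid transforms.

All physical quantities are exchanged in millimetres in the scanner/world
frame implied by ``origin + spacing + direction``; module interfaces never
pass voxel indices across module boundaries.

Volume formats (DICOM series read, MetaImage, NIfTI) are handled through
SimpleITK; STL meshes through trimesh; rigid transforms as plain-text 4x4
matrices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
import trimesh

__all__ = [
    "ImageVolume",
    "RigidTransform",
    "TriangleMesh",
    "ROIBox",
    "read_volume",
    "write_volume",
    "read_stl",
    "write_stl",
    "read_transform",
    "write_transform",
    "crop_to_roi",
]

_ORTHO_TOL = 1e-6


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    ``data`` is indexed ``[k, j, i]`` (z, y, x — the numpy convention used
    by ``sitk.GetArrayFromImage``), while ``spacing``, ``origin`` and the
    columns of ``direction`` are ordered (x, y, z) in mm.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError(f"volume must be at least 2 voxels per axis, got {self.data.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if self.direction.shape != (3, 3) or not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=_ORTHO_TOL
        ):
            raise ValueError("direction must be a 3x3 orthonormal matrix")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Grid size in (x, y, z) order."""
        return self.data.shape[2], self.data.shape[1], self.data.shape[0]

    def index_to_physical(self, idx_xyz: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, (x, y, z) ordered, to mm."""
        idx_xyz = np.asarray(idx_xyz, dtype=float)
        return idx_xyz * self.spacing @ self.direction.T + self.origin

    def physical_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_physical` (continuous indices)."""
        pts_mm = np.asarray(pts_mm, dtype=float)
        return (pts_mm - self.origin) @ self.direction / self.spacing

    def voxel_center_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical voxel-centre coordinates (x, y, z).

        Only valid for identity-direction volumes, where the grid is axis
        aligned and coordinates are separable.
        """
        if not np.allclose(self.direction, np.eye(3), atol=_ORTHO_TOL):
            raise NotImplementedError("separable centres require identity direction")
        nx, ny, nz = self.dims
        return (
            self.origin[0] + self.spacing[0] * np.arange(nx),
            self.origin[1] + self.spacing[1] * np.arange(ny),
            self.origin[2] + self.spacing[2] * np.arange(nz),
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing.copy(), self.origin.copy(), self.direction.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageVolume):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.direction, other.direction)
        )


@dataclass
class RigidTransform:
    """A proper rigid motion as a 4x4 homogeneous matrix.

    Convention: maps point coordinates (mm) from the moving space into the
    fixed space, ``y = R x + t``.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("bottom row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        if np.linalg.norm(r.T @ r - np.eye(3)) > 1e-8:
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has det -1 (reflection, not rigid)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` N x 3 mm, ``faces`` M x 3 indices.

    ``scalars`` optionally holds one value per vertex (e.g. a distance map).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).ravel()
            if len(self.scalars) != len(self.vertices):
                raise ValueError("scalars must have one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def boundary_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces (0 for closed)."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def is_closed(self) -> bool:
        return self.n_faces > 0 and self.boundary_edge_count() == 0

    def transformed(self, t: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(t.apply(self.vertices), self.faces.copy(),
                            None if self.scalars is None else self.scalars.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


@dataclass
class ROIBox:
    """Axis-aligned box in physical (mm) space: ``lower <= x < upper``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != (3,) or self.upper.shape != (3,):
            raise ValueError("ROI bounds must be 3-vectors")
        if not np.all(self.lower < self.upper):
            raise ValueError(f"ROI lower must be < upper, got {self.lower} vs {self.upper}")

    def contains(self, pts_mm: np.ndarray) -> np.ndarray:
        """Half-open membership test: lower <= p < upper, componentwise."""
        pts_mm = np.asarray(pts_mm, dtype=float)
        return np.all((pts_mm >= self.lower) & (pts_mm < self.upper), axis=-1)


# ---------------------------------------------------------------------------
# SimpleITK conversion


def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(vol.data)
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(vol.direction.ravel()))
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    return ImageVolume(
        sitk.GetArrayFromImage(img),
        np.array(img.GetSpacing()),
        np.array(img.GetOrigin()),
        np.array(img.GetDirection()).reshape(3, 3),
    )


# ---------------------------------------------------------------------------
# Volume I/O

_SUPPORTED_DTYPES = (np.uint8, np.int8, np.uint16, np.int16, np.uint32, np.int32,
                     np.float32, np.float64)


def read_volume(path: str | os.PathLike, fmt: str = "auto") -> ImageVolume:
    """Read a 3D volume from a DICOM series directory, MetaImage or NIfTI file.

    Parameters
    ----------
    path
        File path, or a directory containing a single DICOM series.
    fmt
        One of ``dicom_series``, ``metaimage``, ``nifti`` or ``auto``
        (inferred: directories are DICOM series, otherwise the extension).
    """
    path = os.fspath(path)
    if fmt == "auto":
        if os.path.isdir(path):
            fmt = "dicom_series"
        elif path.endswith((".mha", ".mhd")):
            fmt = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise FormatError(f"cannot infer volume format from {path!r}")
    if fmt == "dicom_series":
        return _read_dicom_series(path)
    if fmt not in ("metaimage", "nifti"):
        raise ValueError(f"unknown volume format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise FormatError(f"could not read {path!r} as {fmt}: {exc}") from exc
    return from_sitk(img)


def _read_dicom_series(directory: str) -> ImageVolume:
    if not os.path.isdir(directory):
        raise FileNotFoundError(directory)
    series_ids = sitk.ImageSeriesReader.GetGDCMSeriesIDs(directory)
    if not series_ids:
        raise FormatError(f"no DICOM series found in {directory!r}")
    if len(series_ids) > 1:
        raise FormatError(
            f"directory {directory!r} mixes {len(series_ids)} DICOM series: "
            + ", ".join(series_ids)
        )
    reader = sitk.ImageSeriesReader()
    reader.SetFileNames(reader.GetGDCMSeriesFileNames(directory, series_ids[0]))
    return from_sitk(reader.Execute())


def write_volume(vol: ImageVolume, path: str | os.PathLike, fmt: str = "auto") -> str:
    """Write a volume losslessly as MetaImage or NIfTI (DICOM is read-only)."""
    path = os.fspath(path)
    if fmt == "auto":
        if path.endswith((".mha", ".mhd")):
            fmt = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        else:
            raise FormatError(f"cannot infer volume format from {path!r}")
    if fmt == "dicom_series":
        raise ValueError("DICOM writing is not supported; use metaimage or nifti")
    if fmt not in ("metaimage", "nifti"):
        raise ValueError(f"unknown volume format {fmt!r}")
    if vol.data.dtype.type not in _SUPPORTED_DTYPES:
        raise TypeError(f"unsupported voxel dtype {vol.data.dtype} "
                        f"(supported: {[np.dtype(t).name for t in _SUPPORTED_DTYPES]})")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    sitk.WriteImage(to_sitk(vol), path)
    return path


# ---------------------------------------------------------------------------
# STL I/O

_WELD_DIGITS = 6  # merge duplicated triangle corners within 1e-6 mm


def read_stl(path: str | os.PathLike) -> TriangleMesh:
    """Read an STL file (binary or ascii) and weld duplicated vertices."""
    path = os.fspath(path)
    try:
        tm = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise FormatError(f"could not parse {path!r} as STL: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path!r} contains no triangles")
    tm.merge_vertices(digits_vertex=_WELD_DIGITS)
    faces = np.asarray(tm.faces)
    # STL stores float32: vertices closer than its resolution collapse on
    # write, leaving degenerate (zero-area) faces after welding
    degenerate = ((faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2])
                  | (faces[:, 0] == faces[:, 2]))
    return TriangleMesh(np.asarray(tm.vertices), faces[~degenerate])


def write_stl(mesh: TriangleMesh, path: str | os.PathLike, mode: str = "binary") -> str:
    path = os.fspath(path)
    if mode not in ("binary", "ascii"):
        raise ValueError("mode must be 'binary' or 'ascii'")
    tm = mesh.to_trimesh()
    if mode == "binary":
        tm.export(path, file_type="stl")
    else:
        tm.export(path, file_type="stl_ascii")
    return path


# ---------------------------------------------------------------------------
# Transform I/O


def write_transform(t: RigidTransform, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    np.savetxt(path, t.matrix, fmt="%.17g")
    return path


def read_transform(path: str | os.PathLike) -> RigidTransform:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise FormatError(f"transform file {path!r} is not a 4x4 matrix")
    return RigidTransform(m)  # invariant violations raise ValueError


# ---------------------------------------------------------------------------
# ROI cropping


def crop_to_roi(vol: ImageVolume, roi: ROIBox) -> ImageVolume:
    """Crop to the voxels whose centres lie in ``roi`` (half-open box).

    The origin is updated so every retained voxel keeps its physical
    coordinates. Requires an identity direction matrix (axis-aligned grid);
    the ROI is axis-aligned in physical space by definition.
    """
    xs, ys, zs = vol.voxel_center_axes()
    keep = []
    for axis_coords, lo, hi in zip((xs, ys, zs), roi.lower, roi.upper):
        inside = np.nonzero((axis_coords >= lo) & (axis_coords < hi))[0]
        if len(inside) == 0:
            raise ValueError("ROI does not contain any voxel centres")
        keep.append((inside[0], inside[-1] + 1))
    (x0, x1), (y0, y1), (z0, z1) = keep
    data = vol.data[z0:z1, y0:y1, x0:x1]
    new_origin = vol.index_to_physical([x0, y0, z0])
    return ImageVolume(data, vol.spacing.copy(), new_origin, vol.direction.copy())
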