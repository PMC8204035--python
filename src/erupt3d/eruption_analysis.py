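"""Tooth displacement measurement: surface (ICP) registration between the
pre- and registered post-operative tooth meshes, and decomposition of the
recovered rigid motion into the six clinically named degrees of freedom.

Conventions
-----------
* The anatomical frame is a right-handed orthonormal triad whose rows are
  the mesiodistal (M/D), palatofacial (P/F) and incisoapical (I/A) axes.
* Translations are reported as the displacement of the pre-operative tooth
  centroid projected onto the frame axes; signs: + mesial, + facial,
  + incisal.
* Rotations are extrinsic Euler angles applied in the fixed order
  pitch (about M/D) -> roll (about P/F) -> yaw (about I/A), in degrees,
  positive counter-clockwise about each axis. Euler orders do not commute,
  so the order is part of every report's metadata.
* For a right-side tooth the scene is the sagittal mirror image of a
  left-side one; reported dMD, roll and yaw change sign (the three
  mirror-antisymmetric components) so that "+ mesial" and the rotation
  senses read identically for both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core_io import RigidTransform, TriangleMesh
from .mesh_queries import MeshDistanceQuery

__all__ = [
    "AnatomicalFrame",
    "EruptionMeasures",
    "IcpParams",
    "EULER_ORDER",
    "icp_register",
    "nearest_rotation",
    "decompose",
    "compose",
    "mesh_volume",
    "mesh_centroid",
    "assess_eruption",
]

#: Extrinsic Euler order: rotations about the frame's M/D (pitch), then
#: P/F (roll), then I/A (yaw) axes; scipy convention string.
EULER_ORDER = "xyz"

GIMBAL_MARGIN_DEG = 0.5


class IcpConvergenceError(RuntimeError):
    pass


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal tooth coordinate frame.

    ``axes`` rows are the mesiodistal, palatofacial and incisoapical unit
    vectors (in that order) expressed in world/mm coordinates.
    """

    axes: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    side: str = "left"
    cleft: bool = False

    def __post_init__(self) -> None:
        self.axes = np.asarray(self.axes, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix (rows = M/D, P/F, I/A)")
        if np.linalg.norm(self.axes @ self.axes.T - np.eye(3)) > 1e-9:
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame must be right-handed (det +1)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @classmethod
    def identity(cls, side: str = "left", cleft: bool = False) -> "AnatomicalFrame":
        """Scan-axis frame: M/D = +x, P/F = +y, I/A = +z (phantom default)."""
        return cls(np.eye(3), np.zeros(3), side=side, cleft=cleft)

    @classmethod
    def from_landmarks(cls, incisal_tip, mesial_point, facial_point,
                       side: str = "left", cleft: bool = False) -> "AnatomicalFrame":
        """Build the frame from three operator landmarks (mm).

        M/D points from the incisal tip toward the mesial crown point; P/F is
        the facial direction orthogonalized against M/D (Gram-Schmidt); I/A
        completes the right-handed triad; origin is the incisal tip.
        """
        tip = np.asarray(incisal_tip, dtype=float)
        md = np.asarray(mesial_point, dtype=float) - tip
        if np.linalg.norm(md) < 1e-9:
            raise ValueError("mesial point coincides with the incisal tip")
        md = md / np.linalg.norm(md)
        pf = np.asarray(facial_point, dtype=float) - tip
        pf = pf - (pf @ md) * md
        if np.linalg.norm(pf) < 1e-9:
            raise ValueError("facial point is collinear with the M/D axis")
        pf = pf / np.linalg.norm(pf)
        ia = np.cross(md, pf)
        return cls(np.vstack([md, pf, ia]), tip, side=side, cleft=cleft)

    def transformed(self, t: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(self.axes @ t.rotation.T, t.apply(self.origin),
                               side=self.side, cleft=self.cleft)

    def mirrored(self, plane_normal=(1.0, 0.0, 0.0)) -> "AnatomicalFrame":
        """The contralateral frame: reflect through the sagittal plane and
        reverse the M/D axis (mesial points the other way on the other
        side), which restores right-handedness; the side flag flips."""
        n = np.asarray(plane_normal, dtype=float)
        n = n / np.linalg.norm(n)
        m = np.eye(3) - 2.0 * np.outer(n, n)
        axes = self.axes @ m.T
        axes[0] = -axes[0]
        return AnatomicalFrame(axes, self.origin @ m.T,
                               side=("right" if self.side == "left" else "left"),
                               cleft=self.cleft)


@dataclass
class EruptionMeasures:
    """The six outcome numbers plus tooth volumes.

    Signs: + mesial / + facial / + incisal for translations (mm);
    + counter-clockwise for rotations (degrees).
    """

    dMD: float
    dPF: float
    dIA: float
    pitch: float
    roll: float
    yaw: float
    volume_pre: float | None = None
    volume_post: float | None = None
    gimbal_warning: bool = False

    def components(self) -> np.ndarray:
        """The six motion components as (dMD, dPF, dIA, pitch, roll, yaw)."""
        return np.array([self.dMD, self.dPF, self.dIA, self.pitch, self.roll, self.yaw])

    def as_dict(self) -> dict:
        d = {
            "dMD_mm": self.dMD, "dPF_mm": self.dPF, "dIA_mm": self.dIA,
            "pitch_deg": self.pitch, "roll_deg": self.roll, "yaw_deg": self.yaw,
            "volume_pre_mm3": self.volume_pre, "volume_post_mm3": self.volume_post,
            "euler_order": "pitch(M/D)->roll(P/F)->yaw(I/A), extrinsic",
            "gimbal_warning": self.gimbal_warning,
        }
        return d


@dataclass
class IcpParams:
    """Settings for trimmed point-to-surface ICP."""

    max_iterations: int = 200
    tol_mm: float = 1e-4          # convergence: largest point-motion change
    trim_fraction: float = 0.1    # worst residuals discarded each iteration
    max_source_points: int = 2000
    seed: int = 0
    rms_sanity_mm: float = 2.0
    #: Taubin-smooth voxelization staircase off both meshes before ICP
    #: (assess_eruption only; volumes are measured on the raw meshes)
    presmooth_iterations: int = 10

    def __post_init__(self) -> None:
        if self.tol_mm <= 0:
            raise ValueError("tol_mm must be > 0")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")


def nearest_rotation(matrix: np.ndarray) -> np.ndarray:
    """Closest proper rotation (Frobenius norm) to a 3x3 matrix, via SVD.

    ``R = U diag(1, 1, det(U V^T)) V^T`` — projects out scale/shear and
    repairs reflections.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("input must be 3x3")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("matrix is singular; nearest rotation undefined")
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit mapping src onto dst (closed form)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(r, mu_d - r @ mu_s)


def icp_register(source: TriangleMesh, target: TriangleMesh,
                 params: IcpParams | None = None) -> RigidTransform:
    """Trimmed point-to-surface ICP: transform mapping source onto target.

    Correspondences are exact nearest points on the target surface (not
    nearest vertices); each iteration discards the ``trim_fraction`` worst
    residuals and solves the rigid update in closed form (Kabsch/SVD).
    The result carries a ``meta`` attribute with the RMS history.
    """
    params = params or IcpParams()
    if source.n_faces == 0 or target.n_faces == 0:
        raise ValueError("source and target must be non-degenerate meshes")
    rng = np.random.default_rng(params.seed)
    pts = source.vertices
    if len(pts) > params.max_source_points:
        pts = pts[rng.choice(len(pts), params.max_source_points, replace=False)]
    query = MeshDistanceQuery(target)

    # initialize with the centroid offset (scans of the same tooth are
    # coarsely aligned by the upstream voxel registration); full vertex
    # means, so identical meshes start — and stay — exactly aligned
    t = RigidTransform.from_rotation_translation(
        np.eye(3), target.vertices.mean(axis=0) - source.vertices.mean(axis=0))
    n_keep = max(3, int(round(len(pts) * (1.0 - params.trim_fraction))))
    rms_history: list[float] = []
    converged = False
    prev_step: np.ndarray | None = None
    for _ in range(params.max_iterations):
        moved = t.apply(pts)
        closest, dist = query.query_nearby(moved)
        keep = np.argsort(dist)[:n_keep]
        rms_history.append(float(np.sqrt(np.mean(dist[keep] ** 2))))
        # correspondences come from the moved points but are paired with the
        # original source points, so the fit replaces the whole transform
        t_new = _kabsch(pts[keep], closest[keep])
        # converged when the update no longer moves any source point
        shift = float(np.max(np.linalg.norm(t_new.apply(pts) - moved, axis=1)))
        # geometric-series extrapolation of the slow sliding mode: when
        # consecutive incremental updates stay aligned and shrink by a
        # steady ratio r, the remaining tail sums to ~ r/(1-r) extra steps
        delta = t_new.compose(t.inverse())
        step = np.concatenate([Rotation.from_matrix(delta.rotation).as_rotvec(),
                               delta.translation])
        extrapolated = False
        if prev_step is not None:
            n_now, n_prev = np.linalg.norm(step), np.linalg.norm(prev_step)
            if n_now > 0 and n_prev > 0:
                align = step @ prev_step / (n_now * n_prev)
                ratio = n_now / n_prev
                if align > 0.9 and ratio < 0.999:
                    gain = min(ratio / (1.0 - ratio), 20.0)
                    boost = RigidTransform.from_rotation_translation(
                        Rotation.from_rotvec(
                            gain * Rotation.from_matrix(delta.rotation).as_rotvec()
                        ).as_matrix(),
                        gain * delta.translation)
                    t_new = boost.compose(t_new)
                    extrapolated = True
        prev_step = None if extrapolated else step
        t = t_new
        if shift < params.tol_mm:
            converged = True
            break
    if not converged:
        raise IcpConvergenceError(
            f"ICP did not converge in {params.max_iterations} iterations "
            f"(final trimmed RMS {rms_history[-1]:.4g} mm)")
    if rms_history[-1] > params.rms_sanity_mm:
        warnings.warn(
            f"ICP trimmed RMS {rms_history[-1]:.3g} mm exceeds the "
            f"{params.rms_sanity_mm} mm sanity bound; correspondences are "
            "probably wrong", stacklevel=2)
    t.meta = {"rms_history": rms_history, "iterations": len(rms_history),
              "final_rms_mm": rms_history[-1], "n_source_points": len(pts)}
    return t


def _apply_side(components: np.ndarray, side: str) -> np.ndarray:
    """Flip the mirror-antisymmetric components (dMD, roll, yaw) for the
    right side. Involution: applying it twice is the identity."""
    if side == "right":
        components = components * np.array([-1, 1, 1, 1, -1, -1.0])
    return components


def decompose(t: RigidTransform, frame: AnatomicalFrame,
              centroid: np.ndarray) -> EruptionMeasures:
    """Decompose a rigid motion into the six clinical components.

    The rotation is expressed in the anatomical frame (``R' = A R A^T``) and
    read as extrinsic Euler angles pitch -> roll -> yaw; the translation is
    the centroid displacement ``t(c) - c`` projected onto the frame axes
    (independent of the rotation's lever arm).
    """
    a = frame.axes
    centroid = np.asarray(centroid, dtype=float)
    r_frame = a @ t.rotation @ a.T
    pitch, roll, yaw = Rotation.from_matrix(r_frame).as_euler(EULER_ORDER, degrees=True)
    d = a @ (t.apply(centroid) - centroid)
    comps = _apply_side(np.array([d[0], d[1], d[2], pitch, roll, yaw]), frame.side)
    gimbal = bool(abs(abs(comps[4]) - 90.0) < GIMBAL_MARGIN_DEG)
    if gimbal:
        warnings.warn("roll within 0.5 deg of +/-90: pitch/yaw are degenerate",
                      stacklevel=2)
    return EruptionMeasures(*comps, gimbal_warning=gimbal)


def compose(measures: EruptionMeasures, frame: AnatomicalFrame,
            centroid: np.ndarray) -> RigidTransform:
    """Inverse of :func:`decompose`: rebuild the rigid motion from the six
    components (rotation about ``centroid``, then the frame translation)."""
    comps = _apply_side(measures.components(), frame.side)
    a = frame.axes
    centroid = np.asarray(centroid, dtype=float)
    r_frame = Rotation.from_euler(EULER_ORDER, comps[3:], degrees=True).as_matrix()
    r = a.T @ r_frame @ a
    d = a.T @ comps[:3]
    return RigidTransform.from_rotation_translation(r, centroid + d - r @ centroid)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) of a closed mesh by the signed-tetrahedron sum.

    Orientation is auto-corrected (absolute value), so the result is >= 0.
    """
    n_boundary = mesh.boundary_edge_count()
    if n_boundary:
        raise ValueError(f"mesh is not closed: {n_boundary} boundary edges")
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def mesh_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Volume centroid of a closed mesh (falls back to the vertex mean for
    meshes that enclose no volume)."""
    tm = mesh.to_trimesh()
    if mesh.boundary_edge_count() == 0 and tm.volume > 1e-12:
        return np.asarray(tm.center_mass, dtype=float)
    return mesh.vertices.mean(axis=0)


def _taubin_smoothed(mesh: TriangleMesh, iterations: int) -> TriangleMesh:
    import trimesh.smoothing

    tm = mesh.to_trimesh()
    trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53, iterations=iterations)
    return TriangleMesh.from_trimesh(tm)


def assess_eruption(pre_tooth: TriangleMesh, post_tooth_registered: TriangleMesh,
                    frame: AnatomicalFrame,
                    params: IcpParams | None = None) -> EruptionMeasures:
    """Full per-tooth measurement: ICP (pre -> registered post), decomposition
    about the pre-operative tooth centroid, and both tooth volumes.

    Voxelization staircase artifacts are Taubin-smoothed off both meshes
    before ICP (the smoothing is volume-preserving to first order and
    identical on both sides, so it does not bias the recovered motion);
    centroid and volumes come from the raw meshes.
    """
    params = params or IcpParams()
    src, dst = pre_tooth, post_tooth_registered
    if params.presmooth_iterations > 0:
        src = _taubin_smoothed(src, params.presmooth_iterations)
        dst = _taubin_smoothed(dst, params.presmooth_iterations)
    t = icp_register(src, dst, params)
    centroid = mesh_centroid(pre_tooth)
    measures = decompose(t, frame, centroid)
    measures.volume_pre = mesh_volume(pre_tooth)
    measures.volume_post = mesh_volume(post_tooth_registered)
    return measures
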