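"""Rigid voxel-based registration by mutual-information maximization.

The follow-up (moving) scan is aligned onto the baseline (fixed) scan using
only the intensities inside a stable-bone region of interest of the fixed
image, so that independently moving structures (the erupting tooth) do not
drag the global alignment.

Mutual information is computed from a joint histogram: fixed intensities
are binned directly at the masked voxel centres, moving intensities are
sampled there through the current transform with trilinear interpolation.
The optimizer is Powell's direction-set method over translation plus a
rotation vector, run through a 3-level shrink pyramid; everything is
deterministic (full sampling by default, seed-controlled otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from skimage.measure import block_reduce

from .core_io import ImageVolume, RigidTransform, ROIBox

__all__ = [
    "RegistrationParams",
    "mutual_information",
    "register_rigid_mi",
    "resample",
]

MIN_OVERLAP_FRACTION = 0.10


class InsufficientOverlapError(ValueError):
    pass


class RegistrationDivergenceError(RuntimeError):
    pass


@dataclass
class RegistrationParams:
    """Numeric settings for :func:`register_rigid_mi`.

    Defaults: 64-bin joint histogram, 3 pyramid levels (shrink 4/2/1),
    Powell optimization initialized at identity, full deterministic
    sampling. The source method names only "mutual information"; these
    settings are this package's declared choices.
    """

    bins: int = 64
    pyramid_levels: int = 3
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    max_iterations: int = 60                 # Powell iterations per level
    sampling_fraction: float | tuple[float, ...] = 1.0   # scalar or per level
    seed: int = 0
    convergence_tol_mm: float = 5e-4         # Powell xtol at the finest level
    smoothing_sigma_voxels: float = 1.0      # per-level Gaussian presmoothing
    #: exhaustive translation scan at the coarsest level before hill
    #: climbing, so a poor initialization cannot strand the optimizer in an
    #: MI side lobe; half-width and step in mm (0 disables)
    coarse_search_mm: float = 2.4
    coarse_search_step_mm: float = 0.6
    initial_transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.bins < 8:
            raise ValueError("bins must be >= 8")
        if self.pyramid_levels < 1 or len(self.shrink_factors) != self.pyramid_levels:
            raise ValueError("need one shrink factor per pyramid level (>= 1 level)")
        fracs = (self.sampling_fraction if isinstance(self.sampling_fraction, tuple)
                 else (self.sampling_fraction,))
        if any(not (0.0 < f <= 1.0) for f in fracs):
            raise ValueError("sampling_fraction must be in (0, 1]")
        if isinstance(self.sampling_fraction, tuple) and \
                len(self.sampling_fraction) != self.pyramid_levels:
            raise ValueError("need one sampling fraction per pyramid level")

    def fraction_at(self, level: int) -> float:
        if isinstance(self.sampling_fraction, tuple):
            return self.sampling_fraction[level]
        return self.sampling_fraction


# ---------------------------------------------------------------------------
# Mutual information


class _MIObjective:
    """Joint-histogram MI of a fixed point set against a moving volume.

    Fixed intensities are binned once; each evaluation interpolates the
    moving volume at the transformed points and accumulates the joint
    histogram with a single bincount.
    """

    def __init__(self, fixed: ImageVolume, moving: ImageVolume, bins: int,
                 mask: ROIBox | np.ndarray | None = None,
                 sampling_fraction: float = 1.0, seed: int = 0):
        self.bins = bins
        self.moving = moving
        xs, ys, zs = fixed.voxel_center_axes()
        zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        vals = fixed.data.ravel().astype(float)
        if isinstance(mask, ROIBox):
            sel = mask.contains(pts)
            pts, vals = pts[sel], vals[sel]
        elif mask is not None:
            sel = np.asarray(mask, dtype=bool).ravel()
            pts, vals = pts[sel], vals[sel]
        if len(pts) == 0:
            raise ValueError("mask selects no voxels of the fixed image")
        if sampling_fraction < 1.0:
            rng = np.random.default_rng(seed)
            n = max(1, int(round(len(pts) * sampling_fraction)))
            idx = rng.choice(len(pts), n, replace=False)
            pts, vals = pts[idx], vals[idx]
        self.points = pts
        lo, hi = vals.min(), vals.max()
        width = (hi - lo) or 1.0
        self.fixed_bins = np.clip(((vals - lo) / width * bins).astype(np.int64),
                                  0, bins - 1)
        m_lo = float(moving.data.min())
        m_hi = float(moving.data.max())
        self._m_lo, self._m_width = m_lo, (m_hi - m_lo) or 1.0
        self._moving_data = np.ascontiguousarray(moving.data, dtype=np.float32)
        # out-of-field sentinel: large enough that any interpolation weight
        # above ~1e-4 on it drags the sample below the validity threshold
        self._oob = np.float32(m_lo - 1e4 * self._m_width)
        self._valid_min = m_lo - 0.5 * self._m_width

    def _sample_moving(self, t: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
        idx = self.moving.physical_to_index(t.inverse().apply(self.points))
        # map_coordinates wants (z, y, x) index order
        coords = idx[:, ::-1].T
        vals = map_coordinates(self._moving_data, coords, order=1,
                               mode="constant", cval=self._oob, prefilter=False)
        valid = vals >= self._valid_min
        return vals, valid

    def mi_bits(self, t: RigidTransform) -> float:
        vals, valid = self._sample_moving(t)
        frac = valid.mean()
        if frac < MIN_OVERLAP_FRACTION:
            raise InsufficientOverlapError(
                f"volumes overlap on only {frac:.1%} of masked voxels "
                f"(minimum {MIN_OVERLAP_FRACTION:.0%})")
        mb = np.clip(((vals[valid] - self._m_lo) / self._m_width * self.bins)
                     .astype(np.int64), 0, self.bins - 1)
        fb = self.fixed_bins[valid]
        joint = np.bincount(fb * self.bins + mb,
                            minlength=self.bins * self.bins).astype(float)
        joint = joint.reshape(self.bins, self.bins)
        p = joint / joint.sum()
        pf = p.sum(axis=1)
        pm = p.sum(axis=0)
        nz = p > 0
        return float(np.sum(p[nz] * np.log2(p[nz] / np.outer(pf, pm)[nz])))


def mutual_information(fixed: ImageVolume, moving: ImageVolume,
                       t: RigidTransform | None = None, bins: int = 64,
                       mask: ROIBox | np.ndarray | None = None) -> float:
    """MI (bits) between fixed intensities and moving intensities sampled
    through ``t`` at the (masked) fixed voxel centres:
    ``MI = H(F) + H(M) - H(F, M)`` from the joint histogram.

    Raises :class:`InsufficientOverlapError` if fewer than 10% of the masked
    voxels land inside the moving volume.
    """
    t = t or RigidTransform.identity()
    return _MIObjective(fixed, moving, bins, mask).mi_bits(t)


# ---------------------------------------------------------------------------
# Pyramid


def _shrink(vol: ImageVolume, factor: int, sigma_voxels: float = 0.0) -> ImageVolume:
    if factor == 1:
        data = vol.data.astype(float)
        spacing, origin = vol.spacing.copy(), vol.origin.copy()
    else:
        nz, ny, nx = vol.data.shape
        data = vol.data[: nz - nz % factor, : ny - ny % factor, : nx - nx % factor]
        data = block_reduce(data.astype(float), (factor,) * 3, np.mean)
        spacing = vol.spacing * factor
        origin = vol.origin + vol.direction @ (vol.spacing * (factor - 1) / 2.0)
    if sigma_voxels > 0:
        # smooth the MI landscape: suppresses intensity noise and trilinear
        # interpolation artifacts without moving edge locations
        data = gaussian_filter(data, sigma_voxels)
    return ImageVolume(data, spacing, origin, vol.direction.copy())


# ---------------------------------------------------------------------------
# Rigid parameterization: translation (mm) + rotation vector scaled to
# mm-equivalent units so Powell sees a roughly isotropic landscape.


def _params_to_transform(p: np.ndarray, center: np.ndarray, lever: float) -> RigidTransform:
    r = Rotation.from_rotvec(p[3:] / lever).as_matrix()
    rot_about = RigidTransform.from_rotation_translation(r, center - r @ center)
    return RigidTransform.from_rotation_translation(np.eye(3), p[:3]).compose(rot_about)


def _transform_to_params(t: RigidTransform, center: np.ndarray, lever: float) -> np.ndarray:
    rv = Rotation.from_matrix(t.rotation).as_rotvec()
    # t = Trans(tr) o RotAbout(center): tr = t(center) - center
    tr = t.apply(center) - center
    return np.concatenate([tr, rv * lever])


def register_rigid_mi(fixed: ImageVolume, moving: ImageVolume, roi: ROIBox,
                      params: RegistrationParams | None = None) -> RigidTransform:
    """Find the rigid transform (moving -> fixed, mm) maximizing MI over the
    ROI of the fixed image.

    Returns the transform with a ``meta`` attribute holding per-level MI,
    function-evaluation counts and the optimizer's convergence status.
    Raises :class:`RegistrationDivergenceError` if optimization ends below
    the starting MI at the coarsest level (a sign the initialization is too
    far off).
    """
    params = params or RegistrationParams()
    center = (roi.lower + roi.upper) / 2.0
    lever = float(np.linalg.norm(roi.upper - roi.lower) / 2.0)
    p = _transform_to_params(params.initial_transform, center, lever)

    meta = {"levels": [], "bins": params.bins}
    for level, factor in enumerate(params.shrink_factors):
        f_l = _shrink(fixed, factor, params.smoothing_sigma_voxels)
        m_l = _shrink(moving, factor, params.smoothing_sigma_voxels)
        obj = _MIObjective(f_l, m_l, params.bins, mask=roi,
                           sampling_fraction=params.fraction_at(level),
                           seed=params.seed)
        neg_mi = lambda q: -obj.mi_bits(_params_to_transform(q, center, lever))
        if level == 0 and params.coarse_search_mm > 0:
            # pick the best translation basin around the initialization
            steps = np.arange(-params.coarse_search_mm,
                              params.coarse_search_mm + 1e-9,
                              params.coarse_search_step_mm)
            best = (np.inf, p)
            for dx in steps:
                for dy in steps:
                    for dz in steps:
                        q = p.copy()
                        q[:3] = p[:3] + (dx, dy, dz)
                        try:
                            val = neg_mi(q)
                        except InsufficientOverlapError:
                            continue
                        if val < best[0]:
                            best = (val, q)
            p = best[1]
        mi_start = -neg_mi(p)
        xtol = params.convergence_tol_mm * factor
        res = minimize(neg_mi, p, method="Powell",
                       options={"xtol": xtol, "ftol": 1e-10,
                                "maxiter": params.max_iterations})
        mi_end = -res.fun
        if mi_end < mi_start - 1e-12:
            raise RegistrationDivergenceError(
                f"MI decreased from {mi_start:.4f} to {mi_end:.4f} bits at "
                f"pyramid level {level} (shrink {factor}); provide a closer "
                "initial_transform")
        p = res.x
        meta["levels"].append({"shrink": factor, "mi_start_bits": mi_start,
                               "mi_bits": mi_end, "nfev": int(res.nfev),
                               "iterations": int(res.nit)})
    t = _params_to_transform(p, center, lever)
    t.meta = meta
    return t


# ---------------------------------------------------------------------------
# Resampling


def resample(vol: ImageVolume, t: RigidTransform, reference: ImageVolume,
             fill_value: float = 0.0) -> ImageVolume:
    """Sample ``vol`` on ``reference``'s grid through ``t`` (moving -> fixed)
    with trilinear interpolation; out-of-field voxels get ``fill_value``."""
    xs, ys, zs = reference.voxel_center_axes()
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    idx = vol.physical_to_index(t.inverse().apply(pts))
    vals = map_coordinates(vol.data.astype(float), idx[:, ::-1].T, order=1,
                           mode="constant", cval=fill_value, prefilter=False)
    return ImageVolume(vals.reshape(reference.data.shape).astype(vol.data.dtype
                       if np.issubdtype(vol.data.dtype, np.floating) else float),
                       reference.spacing.copy(), reference.origin.copy(),
                       reference.direction.copy())
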