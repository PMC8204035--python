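"""End-to-end orchestration of the eruption measurement workflow.

One case = a pre-operative and a follow-up volume. The stages are:

1. rigid MI registration of the follow-up onto the baseline over the
   stable-bone ROI;
2. resampling of the follow-up into baseline space;
3. part-comparison MAD of the thresholded ROI surfaces (registration QC);
4. tooth segmentation in both volumes (livewire contours or intensity
   band);
5. ICP + decomposition into the six movement components and tooth volumes.

Every output carries a machine-readable provenance block (package version,
seeds, parameters) sufficient to re-run the producing stage bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .comparison_validation import part_comparison
from .core_io import ImageVolume, RigidTransform, ROIBox, crop_to_roi
from .eruption_analysis import (AnatomicalFrame, EruptionMeasures, IcpParams,
                                assess_eruption, decompose, mesh_centroid)
from .phantom import PhantomPair, stable_roi
from .reliability_stats import summarize, wilcoxon_signed_rank
from .tooth_segmentation import (LivewireParams, auto_segment_phantom,
                                 close_contour, interpolate_contours,
                                 livewire_cost, livewire_path, mesh_from_mask)
from .voxel_registration import RegistrationParams, register_rigid_mi, resample

logger = logging.getLogger(__name__)

__all__ = [
    "CaseResult",
    "ConfigError",
    "StageError",
    "default_registration_params",
    "run_phantom_case",
    "truth_measures",
    "run_case",
    "run_cohort",
    "segment_from_anchors",
]


class ConfigError(ValueError):
    """Invalid or incomplete case configuration (caught before any stage)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class CaseResult:
    measures: EruptionMeasures
    registration_transform: RigidTransform
    registration_mad_mm: float
    registration_sd_mm: float
    pre_roi: ImageVolume
    post_registered_roi: ImageVolume
    bone_band: tuple[float, float]
    tooth_band: tuple[float, float]
    pre_tooth_mesh: object = None
    post_tooth_mesh: object = None
    provenance: dict = field(default_factory=dict)


def default_registration_params(seed: int = 0,
                                initial_transform: RigidTransform | None = None
                                ) -> RegistrationParams:
    """Pipeline registration defaults: full sampling at the coarse level,
    seeded 50% / 30% sampling at the finer levels (keeps the alignment
    deterministic for a given seed at a fraction of the cost of exhaustive
    sampling)."""
    return RegistrationParams(
        sampling_fraction=(1.0, 0.5, 0.3), seed=seed,
        initial_transform=initial_transform or RigidTransform.identity())


def _provenance(stage: str, seeds: dict, params: dict) -> dict:
    return {"package": "erupt3d", "version": __version__, "stage": stage,
            "seeds": seeds, "params": params}


def run_phantom_case(pair: PhantomPair,
                     initial_transform: RigidTransform | None = None,
                     threshold_shift: float = 0.0,
                     run_seed: int = 0,
                     reg_params: RegistrationParams | None = None,
                     icp_params: IcpParams | None = None) -> CaseResult:
    """Run the full pipeline on one phantom pair (auto segmentation).

    ``initial_transform`` and ``threshold_shift`` are the observer-emulation
    knobs: the registration start and a shift of the tooth threshold.
    """
    spec = pair.spec
    if spec is None:
        raise ConfigError("phantom pair carries no spec; cannot derive bands/ROI")
    roi = stable_roi(spec)
    bone_band = ((spec.intensity_background + spec.intensity_bone) / 2.0,
                 (spec.intensity_bone + spec.intensity_tooth) / 2.0)
    tooth_lo = (spec.intensity_bone + spec.intensity_tooth) / 2.0 + threshold_shift
    tooth_band = (tooth_lo, np.inf)

    reg_params = reg_params or default_registration_params(run_seed, initial_transform)
    try:
        t = register_rigid_mi(pair.pre, pair.post, roi, reg_params)
    except Exception as exc:
        raise StageError(f"registration failed: {exc}") from exc
    try:
        post_reg = resample(pair.post, t, pair.pre)
        pre_roi = crop_to_roi(pair.pre, roi)
        post_roi = crop_to_roi(post_reg, roi)
        part = part_comparison(pre_roi, post_roi, bone_band)
    except Exception as exc:
        raise StageError(f"part comparison failed: {exc}") from exc
    try:
        pre_tooth = auto_segment_phantom(pair.pre, tooth_band)
        # segment the native follow-up scan and carry the mesh through the
        # registration transform: thresholding the resampled volume instead
        # grid-locks the staircase surface and biases the recovered
        # rotations (the resampled volume is still what part comparison and
        # visual QC use)
        post_tooth = auto_segment_phantom(pair.post, tooth_band).transformed(t)
    except Exception as exc:
        raise StageError(f"segmentation failed: {exc}") from exc
    try:
        icp_params = icp_params or IcpParams(seed=run_seed)
        measures = assess_eruption(pre_tooth, post_tooth, pair.frame, icp_params)
    except Exception as exc:
        raise StageError(f"eruption analysis failed: {exc}") from exc

    prov = _provenance(
        "run_phantom_case",
        seeds={"run_seed": run_seed, "phantom_seed": spec.seed},
        params={"registration": {k: v for k, v in asdict(reg_params).items()
                                 if k != "initial_transform"},
                "initial_transform": reg_params.initial_transform.matrix.tolist(),
                "threshold_shift": threshold_shift,
                "bone_band": list(bone_band),
                "tooth_band": [tooth_band[0], None],
                "icp": asdict(icp_params)})
    return CaseResult(measures=measures, registration_transform=t,
                      registration_mad_mm=part["mad_mm"],
                      registration_sd_mm=part["sd_mm"],
                      pre_roi=pre_roi, post_registered_roi=post_roi,
                      bone_band=bone_band, tooth_band=tooth_band,
                      pre_tooth_mesh=pre_tooth, post_tooth_mesh=post_tooth,
                      provenance=prov)


def truth_measures(pair: PhantomPair) -> EruptionMeasures:
    """Ground-truth decomposition of the phantom's local tooth motion,
    about the true pre-operative tooth centroid."""
    c = mesh_centroid(pair.truth_tooth_pre)
    return decompose(pair.truth_local, pair.frame, c)


# ---------------------------------------------------------------------------
# Interactive-style segmentation from an anchor file


def segment_from_anchors(vol: ImageVolume, contour_spec: list[dict],
                         livewire_params: LivewireParams | None = None):
    """Livewire segmentation driven by per-slice anchor points.

    ``contour_spec`` entries: ``{"axis": "axial", "index": k,
    "anchors_mm": [[u, v], ...]}`` with in-slice mm coordinates (axial:
    (x, y); coronal: (x, z); sagittal: (y, z)). For each slice, minimum-cost
    paths are traced between consecutive anchors (closing back to the
    first), chained into a contour; axial contours are interpolated into a
    binary volume, other axes carve it, and the mask is surfaced.
    """
    livewire_params = livewire_params or LivewireParams()
    xs, ys, zs = vol.voxel_center_axes()
    axis_coords = {"axial": (xs, ys), "coronal": (xs, zs), "sagittal": (ys, zs)}
    contours = []
    for entry in contour_spec:
        axis, k = entry["axis"], int(entry["index"])
        anchors = np.asarray(entry["anchors_mm"], dtype=float)
        if len(anchors) < 3:
            raise ConfigError(f"contour on {axis} slice {k} needs >= 3 anchors")
        if axis == "axial":
            img = vol.data[k].astype(float)
        elif axis == "coronal":
            img = vol.data[:, k, :].astype(float)
        else:
            img = vol.data[:, :, k].astype(float)
        us, vs = axis_coords[axis]
        cost = livewire_cost(img, livewire_params)

        def mm_to_pix(p):
            return (int(round(np.interp(p[1], vs, np.arange(len(vs))))),
                    int(round(np.interp(p[0], us, np.arange(len(us))))))

        def pix_to_mm(p):
            return (np.interp(p[1], np.arange(len(us)), us),
                    np.interp(p[0], np.arange(len(vs)), vs))

        pix_anchors = [mm_to_pix(p) for p in anchors]
        segments = [livewire_path(cost, pix_anchors[i],
                                  pix_anchors[(i + 1) % len(pix_anchors)])
                    for i in range(len(pix_anchors))]
        contours.append(close_contour(segments, axis, k, pix_to_mm))
    mask = interpolate_contours(contours, vol)
    return mesh_from_mask(mask)


# ---------------------------------------------------------------------------
# File/config based execution


_REQUIRED_CASE_KEYS = ("pre", "post", "roi", "frame", "segmentation")


def _load_frame(obj: dict) -> AnatomicalFrame:
    if "landmarks" in obj:
        lm = obj["landmarks"]
        return AnatomicalFrame.from_landmarks(
            lm["incisal_tip"], lm["mesial_point"], lm["facial_point"],
            side=obj.get("side", "left"), cleft=bool(obj.get("cleft", False)))
    return AnatomicalFrame(np.asarray(obj["axes"], dtype=float),
                           np.asarray(obj.get("origin", [0, 0, 0]), dtype=float),
                           side=obj.get("side", "left"),
                           cleft=bool(obj.get("cleft", False)))


def validate_case_config(config: dict) -> None:
    missing = [k for k in _REQUIRED_CASE_KEYS if k not in config]
    if missing:
        raise ConfigError(f"case config missing required keys: {missing}")
    seg = config["segmentation"]
    if "band" not in seg and "contours" not in seg:
        raise ConfigError("segmentation config needs either 'band' or 'contours'")


def run_case(config: dict) -> CaseResult:
    """Run the full workflow from a configuration mapping (file paths or
    in-memory objects). Validates the configuration before any computation.
    """
    from .core_io import read_volume

    validate_case_config(config)
    seed = int(config.get("seed", 0))

    def _vol(v):
        return v if isinstance(v, ImageVolume) else read_volume(v)

    pre = _vol(config["pre"])
    post = _vol(config["post"])
    roi_cfg = config["roi"]
    roi = roi_cfg if isinstance(roi_cfg, ROIBox) else ROIBox(
        np.asarray(roi_cfg["lower"], float), np.asarray(roi_cfg["upper"], float))
    frame = (config["frame"] if isinstance(config["frame"], AnatomicalFrame)
             else _load_frame(config["frame"]))
    seg = config["segmentation"]
    bone_band = tuple(config.get("bone_band", (np.nanpercentile(pre.data, 60), np.inf)))

    reg_params = config.get("registration_params") or default_registration_params(seed)
    try:
        t = register_rigid_mi(pre, post, roi, reg_params)
        post_reg = resample(post, t, pre)
        pre_roi = crop_to_roi(pre, roi)
        post_roi = crop_to_roi(post_reg, roi)
        part = part_comparison(pre_roi, post_roi, bone_band)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"registration/part-comparison failed: {exc}") from exc

    try:
        if "band" in seg:
            band = (float(seg["band"][0]), float(seg["band"][1]))
            pre_tooth = auto_segment_phantom(pre, band)
            # threshold the native scan, then transform the mesh (avoids
            # resampling blur and staircase grid-locking in the measurement)
            post_tooth = auto_segment_phantom(post, band).transformed(t)
        else:
            pre_tooth = segment_from_anchors(pre, seg["contours"]["pre"])
            post_tooth = segment_from_anchors(post_reg, seg["contours"]["post"])
            band = (float("nan"), float("nan"))
    except Exception as exc:
        raise StageError(f"segmentation failed: {exc}") from exc

    try:
        icp_params = config.get("icp_params") or IcpParams(seed=seed)
        measures = assess_eruption(pre_tooth, post_tooth, frame, icp_params)
    except Exception as exc:
        raise StageError(f"eruption analysis failed: {exc}") from exc

    prov = _provenance("run_case", seeds={"seed": seed},
                       params={"roi": {"lower": roi.lower.tolist(),
                                       "upper": roi.upper.tolist()},
                               "bone_band": [float(b) for b in bone_band],
                               "segmentation_band": list(band)})
    return CaseResult(measures=measures, registration_transform=t,
                      registration_mad_mm=part["mad_mm"],
                      registration_sd_mm=part["sd_mm"],
                      pre_roi=pre_roi, post_registered_roi=post_roi,
                      bone_band=bone_band, tooth_band=band,
                      pre_tooth_mesh=pre_tooth, post_tooth_mesh=post_tooth,
                      provenance=prov)


COMPONENT_COLS = ("dMD_mm", "dPF_mm", "dIA_mm", "pitch_deg", "roll_deg", "yaw_deg")


def run_cohort(results: list[CaseResult | None], sides: list[bool] | None = None
               ) -> dict:
    """Cohort summary over per-case results.

    ``sides``: per-case cleft flags (True = cleft). Failed cases are passed
    as None; survivors are counted and disclosed. Returns per-case table,
    per-side mean ± SD per component, and a cleft vs non-cleft Wilcoxon
    signed-rank p per component when both sides are present in equal,
    pairable numbers.
    """
    survivors = [(i, r) for i, r in enumerate(results) if r is not None]
    if not survivors:
        raise StageError("no cases survived; cohort statistics undefined")
    if sides is None:
        sides = [False] * len(results)
    rows = []
    for i, r in survivors:
        d = r.measures.as_dict()
        rows.append({"case": i, "cleft": bool(sides[i]),
                     **{c: d[c] for c in COMPONENT_COLS},
                     "volume_pre_mm3": r.measures.volume_pre,
                     "volume_post_mm3": r.measures.volume_post,
                     "reg_mad_mm": r.registration_mad_mm})
    table = pd.DataFrame(rows)

    stats_rows = []
    for cleft, group in table.groupby("cleft"):
        for c in COMPONENT_COLS + ("volume_pre_mm3", "volume_post_mm3"):
            s = summarize(group[c].to_numpy())
            stats_rows.append({"side": "cleft" if cleft else "non_cleft",
                               "component": c, **s})
    stats = pd.DataFrame(stats_rows)

    wilcoxon = {}
    cleft_tab = table[table["cleft"]].sort_values("case")
    non_tab = table[~table["cleft"]].sort_values("case")
    if len(cleft_tab) >= 3 and len(cleft_tab) == len(non_tab):
        for c in COMPONENT_COLS:
            try:
                w, p = wilcoxon_signed_rank(non_tab[c].to_numpy(),
                                            cleft_tab[c].to_numpy())
                wilcoxon[c] = {"W": w, "p": p}
            except ValueError as exc:
                wilcoxon[c] = {"error": str(exc)}
    return {"per_case": table, "stats": stats, "wilcoxon": wilcoxon,
            "n_requested": len(results), "n_survived": len(survivors)}


def write_case_outputs(result: CaseResult, out_dir: str) -> None:
    """Write the standard artifact set for one case."""
    import os

    from .core_io import write_stl, write_transform, write_volume

    os.makedirs(out_dir, exist_ok=True)
    write_transform(result.registration_transform, os.path.join(out_dir, "t.txt"))
    write_stl(result.pre_tooth_mesh, os.path.join(out_dir, "tooth_pre.stl"))
    write_stl(result.post_tooth_mesh, os.path.join(out_dir, "tooth_post_reg.stl"))
    with open(os.path.join(out_dir, "measures.json"), "w") as fh:
        json.dump({**result.measures.as_dict(),
                   "registration_mad_mm": result.registration_mad_mm,
                   "registration_sd_mm": result.registration_sd_mm,
                   "provenance": result.provenance}, fh, indent=2)
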