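"""Geometric / intensity accuracy metrics: MAE over anatomical regions,
volume index (VI), and Dice similarity coefficient (DSC).

Region construction follows the planning-CT thresholding recipe: bone is
CT > 150 HU within the MRI FOV closed and hole-filled to pull in softer bone
and marrow; soft tissue is CT > -150 HU within the FOV minus the bone
region.  Thresholds are strict inequalities for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import UndefinedMetricError
from .image import BinaryMask, VolumeImage, morphology, require_compatible

DSC_GOOD_OVERLAP = 0.7


@dataclass
class RegionThresholds:
    bone_hu: float = 150.0
    soft_hu: float = -150.0
    morph_radius_mm: float = 3.0

    def __post_init__(self):
        if self.bone_hu <= self.soft_hu:
            raise ValueError("bone_hu must exceed soft_hu")


def mae(ct: VolumeImage, sct: VolumeImage, region: BinaryMask) -> float:
    """Mean absolute error (HU): (1/N) sum_{x in region} |sCT(x) - CT(x)|."""
    require_compatible(ct, sct, region, what="mae")
    m = region.values
    if not m.any():
        raise UndefinedMetricError("MAE undefined on an empty region")
    return float(np.abs(sct.values[m] - ct.values[m]).mean())


def bone_region(ct: VolumeImage, fov: BinaryMask,
                thr: RegionThresholds | None = None) -> BinaryMask:
    """Bone region: (CT > bone_hu) within the FOV, then morphological closing
    (radius ``morph_radius_mm``) and hole filling to include marrow."""
    thr = thr or RegionThresholds()
    require_compatible(ct, fov, what="bone_region")
    raw = BinaryMask((ct.values > thr.bone_hu) & fov.values, ct.grid)
    closed = morphology(raw, "close", thr.morph_radius_mm)
    filled = morphology(closed, "fill_holes")
    return filled & fov


def soft_tissue_region(ct: VolumeImage, fov: BinaryMask, bone: BinaryMask,
                       thr: RegionThresholds | None = None) -> BinaryMask:
    """Soft tissue: (CT > soft_hu) within the FOV, minus the bone region."""
    thr = thr or RegionThresholds()
    require_compatible(ct, fov, bone, what="soft_tissue_region")
    raw = (ct.values > thr.soft_hu) & fov.values & ~bone.values
    return BinaryMask(raw, ct.grid)


def volume_index(ref: BinaryMask, eval_mask: BinaryMask) -> float:
    """VI = (V(ref) - V(eval)) / V(ref) + 1 with volumes in cm3.

    VI = 1 for identical volumes; VI > 1 when the reference (clinical)
    contour is larger than the evaluated one, VI < 1 vice versa.
    """
    v_ref = ref.volume_cm3
    if v_ref <= 0:
        raise UndefinedMetricError("VI undefined for an empty reference contour")
    return (v_ref - eval_mask.volume_cm3) / v_ref + 1.0


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|)."""
    require_compatible(a, b, what="dice")
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        raise UndefinedMetricError("DSC undefined for two empty masks")
    inter = int((a.values & b.values).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class GeometryReport:
    """Per-region MAE plus external/bone contour VI and DSC for one sCT."""

    mae_hu: dict          # region name -> MAE in HU
    vi: dict              # contour name -> volume index
    dsc: dict             # contour name -> Dice
    dsc_good_overlap: dict  # contour name -> DSC > 0.7 flag
    voxel_counts: dict    # region name -> N

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_geometry(ct: VolumeImage, sct: VolumeImage, fov: BinaryMask,
                      ct_external: BinaryMask, sct_external: BinaryMask,
                      thr: RegionThresholds | None = None) -> GeometryReport:
    """Full geometric evaluation of one synthetic CT against the planning CT.

    MAE is computed in the external contour, the bone region and the
    soft-tissue region (all restricted to the MRI FOV); VI and DSC compare
    the external and bone contours extracted from each image.
    """
    thr = thr or RegionThresholds()
    bone_ct = bone_region(ct, fov, thr)
    soft_ct = soft_tissue_region(ct, fov, bone_ct, thr)
    external = BinaryMask(ct_external.values & fov.values, ct.grid)
    bone_sct = bone_region(sct, fov, thr)

    regions = {"external": external, "bone": bone_ct, "soft_tissue": soft_ct}
    mae_hu = {name: mae(ct, sct, m) for name, m in regions.items()}
    counts = {name: m.voxel_count for name, m in regions.items()}

    ext_eval = BinaryMask(sct_external.values & fov.values, ct.grid)
    vi = {
        "external": volume_index(external, ext_eval),
        "bone": volume_index(bone_ct, bone_sct),
    }
    dsc_vals = {
        "external": dice(external, ext_eval),
        "bone": dice(bone_ct, bone_sct),
    }
    flags = {k: v > DSC_GOOD_OVERLAP for k, v in dsc_vals.items()}
    return GeometryReport(mae_hu, vi, dsc_vals, flags, counts)
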