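"""Bulk density assignment baseline (sCT_bda).

Tissue classes — bone (supplied mask), air (low MR intensity inside the
body), water (the rest of the body) — are mapped to fixed physical densities:
bone 1.53 g/cm3 for head-and-neck, 1.22 g/cm3 for prostate, air 0.001 g/cm3,
water 1.0 g/cm3.  A companion HU volume is produced through a piecewise
linear density-to-HU calibration anchored at air (-1000 HU) and water (0 HU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, UsageError
from .image import BinaryMask, VolumeImage, morphology, require_compatible

LABELS = {"outside": 0, "water": 1, "bone": 2, "air": 3}

#: default density -> HU calibration anchors (g/cm3, HU)
DEFAULT_CALIBRATION = ((0.001, -1000.0), (1.0, 0.0), (1.53, 883.0))


@dataclass
class DensityTable:
    """Per-class physical densities (g/cm3) for one anatomical site."""

    site: str = "head_neck"
    bone: float | None = None
    air: float = 0.001
    water: float = 1.0
    calibration: tuple = DEFAULT_CALIBRATION

    def __post_init__(self):
        if self.site not in ("head_neck", "prostate"):
            raise UsageError(f"unknown site {self.site!r}")
        if self.bone is None:
            self.bone = 1.53 if self.site == "head_neck" else 1.22
        if not (0 < self.air < self.water < self.bone):
            raise UsageError("densities must satisfy 0 < air < water < bone")

    def density_of(self, label: str) -> float:
        if label == "outside":
            return self.air
        try:
            return {"water": self.water, "bone": self.bone, "air": self.air}[label]
        except KeyError:
            raise DataError(f"unknown tissue label {label!r}") from None


@dataclass
class TissueClassMap:
    """Integer label lattice over the grid: outside/water/bone/air."""

    labels: np.ndarray
    grid: object

    def count(self, label: str) -> int:
        return int((self.labels == LABELS[label]).sum())

    def mask(self, label: str) -> BinaryMask:
        return BinaryMask(self.labels == LABELS[label], self.grid)


def segment_air_mr(mr: VolumeImage, body: BinaryMask, threshold: float = 8.0,
                   opening_radius_voxels: int = 1) -> BinaryMask:
    """Air cavities: MR intensity below ``threshold`` inside the body, with a
    one-voxel morphological opening to suppress single-voxel noise.  An empty
    result is valid (the prostate site has no air class)."""
    require_compatible(mr, body, what="segment_air_mr")
    raw = BinaryMask((mr.values < threshold) & body.values, mr.grid)
    if opening_radius_voxels <= 0:
        return raw
    radius_mm = opening_radius_voxels * min(mr.grid.spacing)
    return morphology(raw, "open", radius_mm)


def assemble_class_map(body: BinaryMask, bone: BinaryMask,
                       air: BinaryMask) -> TissueClassMap:
    """Partition the grid into outside/water/bone/air.

    Bone and air are clipped to the body; on overlap bone takes precedence
    (anatomic plausibility); the remainder of the body is water.
    """
    require_compatible(body, bone, air, what="assemble_class_map")
    labels = np.zeros(body.grid.shape, dtype=np.uint8)
    b = body.values
    bone_in = bone.values & b
    air_in = air.values & b & ~bone_in
    labels[b] = LABELS["water"]
    labels[bone_in] = LABELS["bone"]
    labels[air_in] = LABELS["air"]
    return TissueClassMap(labels, body.grid)


def density_to_hu(density, calibration=DEFAULT_CALIBRATION):
    """Piecewise-linear density (g/cm3) -> HU through the calibration anchors;
    densities outside the calibration hull are clamped with a warning."""
    d = np.asarray(density, dtype=float)
    if np.any(d <= 0):
        raise UsageError("density must be positive")
    xs = np.array([a[0] for a in calibration])
    ys = np.array([a[1] for a in calibration])
    if np.any(d < xs[0]) or np.any(d > xs[-1]):
        warnings.warn("density outside calibration hull; clamping", stacklevel=2)
    out = np.interp(d, xs, ys)
    return float(out) if np.isscalar(density) else out


def hu_to_density(hu, calibration=DEFAULT_CALIBRATION):
    """Inverse calibration: HU -> density (clamped to the anchor range)."""
    h = np.asarray(hu, dtype=float)
    xs = np.array([a[1] for a in calibration])
    ys = np.array([a[0] for a in calibration])
    out = np.interp(h, xs, ys)
    return float(out) if np.isscalar(hu) else out


def build_bulk_sct(classes: TissueClassMap, table: DensityTable
                   ) -> tuple[VolumeImage, VolumeImage]:
    """Density and HU volumes from a tissue-class map.

    Returns ``(density, hu)``: the density volume in g/cm3 (outside the body
    = air density) and the companion HU volume via the calibration.
    """
    known = np.isin(classes.labels, list(LABELS.values()))
    if not known.all():
        raise DataError("class map contains unknown labels")
    density = np.empty(classes.labels.shape, dtype=float)
    for name, code in LABELS.items():
        density[classes.labels == code] = table.density_of(name)
    hu = density_to_hu(density, table.calibration)
    return (
        VolumeImage(density, classes.grid, "DENSITY"),
        VolumeImage(hu, classes.grid, "CT"),
    )
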