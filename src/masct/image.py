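"""Geometry-aware 3-D volumes, NIfTI I/O, resampling and binary morphology.

World-coordinate convention used throughout the package: voxel index
``i = (i0, i1, i2)`` (0-based) sits at physical position

    ``world(i) = origin + orientation @ (spacing * i)``   [mm]

with ``orientation`` an orthonormal 3x3 matrix whose columns are the
direction cosines of the three index axes.  This matches the ITK/NIfTI
physical-space model, so conversion to and from SimpleITK is a pure axis
transpose (SimpleITK arrays are indexed ``[z, y, x]``, ours ``[x, y, z]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import GeometryError, SegmentationError, UsageError

GEOMETRY_TOL = 1e-6

#: default out-of-domain fill value per modality tag
DEFAULT_FILL = {"CT": -1000.0, "MR": 0.0, "DOSE": 0.0, "DENSITY": 0.0, "LABEL": 0.0}

MODALITIES = frozenset(DEFAULT_FILL)


def _as_tuple3(x, dtype=float) -> tuple:
    t = tuple(dtype(v) for v in np.asarray(x).ravel())
    if len(t) != 3:
        raise UsageError(f"expected a 3-vector, got {x!r}")
    return t


@dataclass(frozen=True)
class GridSpec:
    """Shape + world geometry of a regular 3-D sampling lattice."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "shape", _as_tuple3(self.shape, int))
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing))
        object.__setattr__(self, "origin", _as_tuple3(self.origin))
        R = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "orientation", R)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if any(n <= 0 for n in self.shape):
            raise GeometryError(f"shape must be positive, got {self.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=GEOMETRY_TOL):
            raise GeometryError("orientation matrix is not orthonormal within 1e-6")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world positions in mm."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + (idx * self.spacing) @ self.orientation.T

    def compatible_with(self, other: "GridSpec", tol: float = GEOMETRY_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )


@dataclass
class VolumeImage:
    """A scalar 3-D volume (CT in HU, MR in a.u., dose in Gy, density in g/cm3)."""

    values: np.ndarray
    grid: GridSpec
    modality: str = "CT"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.modality not in MODALITIES:
            raise UsageError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "VolumeImage":
        return VolumeImage(values, self.grid, modality or self.modality)

    def compatible_with(self, other: "VolumeImage | BinaryMask") -> bool:
        return self.grid.compatible_with(other.grid)


@dataclass
class BinaryMask:
    """A boolean lattice sharing the geometry of a reference volume."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3 / 1000.0

    def compatible_with(self, other) -> bool:
        return self.grid.compatible_with(other.grid)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & other.values, self.grid)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values | other.values, self.grid)

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(~self.values, self.grid)

    def difference(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & ~other.values, self.grid)


def require_compatible(*items, what: str = "voxelwise operation") -> None:
    """Raise GeometryError unless all volumes/masks share one grid."""
    ref = items[0].grid
    for it in items[1:]:
        if not ref.compatible_with(it.grid):
            raise GeometryError(f"{what} requires grid-compatible inputs")


# ---------------------------------------------------------------------------
# SimpleITK conversion and NIfTI I/O
# ---------------------------------------------------------------------------

def to_sitk(volume: VolumeImage | BinaryMask) -> sitk.Image:
    arr = volume.values
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(volume.grid.spacing)
    img.SetOrigin(volume.grid.origin)
    img.SetDirection(tuple(volume.grid.orientation.ravel()))
    return img


def grid_from_sitk(img: sitk.Image) -> GridSpec:
    return GridSpec(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        orientation=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def from_sitk(img: sitk.Image, modality: str = "CT") -> VolumeImage:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VolumeImage(arr, grid_from_sitk(img), modality)


def read_nifti(path, modality: str = "CT") -> VolumeImage:
    """Read a .nii/.nii.gz scalar volume.

    Geometry comes from the NIfTI s-form/q-form; the RAS/LPS flip is handled
    by the reader so internal world coordinates are consistent across files.
    """
    return from_sitk(sitk.ReadImage(str(path), sitk.sitkFloat64), modality)


def write_nifti(volume: VolumeImage | BinaryMask, path) -> None:
    sitk.WriteImage(to_sitk(volume), str(path))


def read_mask(path) -> BinaryMask:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return BinaryMask(arr > 0, grid_from_sitk(img))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "trilinear": sitk.sitkLinear}


def _reference_image(target: GridSpec) -> sitk.Image:
    ref = sitk.Image(*target.shape, sitk.sitkFloat64)
    ref.SetSpacing(target.spacing)
    ref.SetOrigin(target.origin)
    ref.SetDirection(tuple(target.orientation.ravel()))
    return ref


def resample(
    volume: VolumeImage,
    target: GridSpec,
    interpolation: str = "trilinear",
    fill_value: float | None = None,
) -> VolumeImage:
    """Resample ``volume`` onto ``target`` through world coordinates.

    Voxels of the target grid whose world position falls outside the input
    domain receive ``fill_value`` (default: -1000 for CT, 0 otherwise).
    """
    if interpolation not in _INTERPOLATORS:
        raise UsageError(f"interpolation must be one of {sorted(_INTERPOLATORS)}")
    if not np.all(np.isfinite(volume.values)):
        raise UsageError("resample requires a finite-valued volume")
    if fill_value is None:
        fill_value = DEFAULT_FILL[volume.modality]
    out = sitk.Resample(
        to_sitk(volume),
        _reference_image(target),
        sitk.Transform(),
        _INTERPOLATORS[interpolation],
        float(fill_value),
        sitk.sitkFloat64,
    )
    return from_sitk(out, volume.modality)


def resample_mask(mask: BinaryMask, target: GridSpec) -> BinaryMask:
    vol = VolumeImage(mask.values.astype(float), mask.grid, "LABEL")
    out = resample(vol, target, "nearest", fill_value=0.0)
    return BinaryMask(out.values > 0.5, target)


# ---------------------------------------------------------------------------
# Segmentation and morphology
# ---------------------------------------------------------------------------

def extract_body_mask(
    volume: VolumeImage,
    modality: str | None = None,
    ct_threshold_hu: float = -250.0,
) -> BinaryMask:
    """External (body) contour by thresholding.

    CT: ``> ct_threshold_hu`` (default -250 HU).  MR: ``>`` Otsu threshold.
    The largest 3-D connected component is kept and internal holes (air
    cavities) are filled, so the result is a single solid body region.
    """
    modality = modality or volume.modality
    if modality == "CT":
        fg = volume.values > ct_threshold_hu
    elif modality == "MR":
        fg = volume.values > threshold_otsu(volume.values)
    else:
        raise UsageError(f"body extraction supports CT or MR, got {modality!r}")
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding: no body found")
    labels, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=range(1, n + 1))) + 1
    body = ndimage.binary_fill_holes(labels == largest)
    return BinaryMask(body, volume.grid)


def _ball_element(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element of physical radius ``radius_mm``.

    The radius is converted to voxels per axis (rounded half-up, at least 1
    voxel for any positive radius) and the element keeps offsets inside the
    corresponding ellipsoid.
    """
    radii = [max(1, int(np.floor(radius_mm / s + 0.5))) for s in spacing]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    dist2 = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return dist2 <= 1.0 + 1e-12


def morphology(mask: BinaryMask, op: str, radius_mm: float = 0.0) -> BinaryMask:
    """Binary morphology with a physical-radius ball element.

    ``op`` is one of ``dilate, erode, close, open, fill_holes``.  Radius 0 is
    the identity for everything except ``fill_holes`` (which takes no radius).
    """
    if radius_mm < 0:
        raise UsageError("radius_mm must be >= 0")
    if op == "fill_holes":
        return BinaryMask(ndimage.binary_fill_holes(mask.values), mask.grid)
    if radius_mm == 0:
        return BinaryMask(mask.values.copy(), mask.grid)
    elem = _ball_element(radius_mm, mask.grid.spacing)
    fns = {
        "dilate": ndimage.binary_dilation,
        "erode": ndimage.binary_erosion,
        "close": ndimage.binary_closing,
        "open": ndimage.binary_opening,
    }
    if op not in fns:
        raise UsageError(f"unknown morphology op {op!r}")
    if op in ("close", "open"):
        # pad by the element radius so closing stays extensive and opening
        # anti-extensive at the lattice border
        pad = [(s // 2, s // 2) for s in elem.shape]
        padded = np.pad(mask.values, pad, mode="constant", constant_values=False)
        out = fns[op](padded, structure=elem)
        crop = tuple(slice(p[0], p[0] + n) for p, n in zip(pad, mask.grid.shape))
        return BinaryMask(out[crop], mask.grid)
    return BinaryMask(fns[op](mask.values, structure=elem), mask.grid)
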