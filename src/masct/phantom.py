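"""Seeded digital phantoms: paired CT/MR anatomies, deformed atlas
populations, ground-truth masks, and a density-sensitive toy dose model.

The phantom emulates the imaging situation of MR-only treatment planning at
desk scale: an ellipsoidal body of soft tissue with a fat inclusion,
heterogeneous bone (bright cortical shell around a marrow core on CT, both
dark on MR), optional air cavities (head-and-neck style), a spherical target
and an organ-at-risk, and a reduced MRI field of view cropped in the
cranio-caudal direction.  An atlas population is produced by warping one
base anatomy with independent smooth random deformation fields, so a
held-out deformed subject has a known ground-truth CT for leave-one-out
evaluation.

The toy dose model is a test harness, not a dose engine: exponential
attenuation along axis-aligned beams with water-equivalent depth from the
CT-derived density and a Gaussian lateral profile, scaled so the target mean
equals the prescription.  It exists so that gamma/DVH comparisons respond
to HU errors qualitatively the way recomputed clinical plans do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .bulk import hu_to_density
from .errors import SpecError
from .fusion import AtlasDatabase, AtlasPair
from .image import BinaryMask, GridSpec, VolumeImage, morphology
from .registration import DeformationField, warp, warp_mask

DEFAULT_TISSUE_TABLE = {
    #            CT (HU)   T2 (a.u.)  T1 (a.u.)
    "soft":     {"ct": 35.0,   "t2": 300.0, "t1": 350.0},
    "fat":      {"ct": -90.0,  "t2": 600.0, "t1": 650.0},
    "cortical": {"ct": 1100.0, "t2": 40.0,  "t1": 120.0},
    "marrow":   {"ct": 250.0,  "t2": 500.0, "t1": 600.0},
    "air":      {"ct": -995.0, "t2": 2.0,   "t1": 2.0},
    "outside":  {"ct": -1000.0, "t2": 1.0,  "t1": 1.0},
}

CHANNEL_NAMES = ["T2", "T1"]


@dataclass
class PhantomSpec:
    """Geometry, intensity and variability parameters of the digital subject."""

    site_style: str = "head_neck_like"
    grid: GridSpec = field(
        default_factory=lambda: GridSpec((64, 64, 64), (2.5, 2.5, 2.5))
    )
    body_semiaxes_mm: tuple = (55.0, 65.0, 72.0)
    bone_count: int = 3
    bone_radius_mm: float = 11.0
    cortical_thickness_mm: float = 3.5
    air_count: int = 2
    air_radius_mm: float = 8.0
    target_radius_mm: float = 10.0
    tissue_table: dict = field(default_factory=lambda: DEFAULT_TISSUE_TABLE)
    bias_amplitude: float = 0.15
    ct_noise_sd: float = 12.0
    mr_noise_sd: float = 5.0
    deformation_amplitude_mm: float = 4.0
    deformation_smoothness_mm: float = 15.0
    fov_crop_fraction: float = 0.25

    def __post_init__(self):
        if self.site_style not in ("head_neck_like", "prostate_like"):
            raise SpecError(f"unknown site_style {self.site_style!r}")
        for name in ("bias_amplitude", "ct_noise_sd", "mr_noise_sd",
                     "deformation_amplitude_mm", "deformation_smoothness_mm"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if not 0 < self.fov_crop_fraction < 1:
            raise SpecError("fov_crop_fraction must be in (0, 1)")
        t = self.tissue_table
        if not (t["cortical"]["ct"] > t["soft"]["ct"] > t["air"]["ct"]):
            raise SpecError("tissue table must order CT: cortical > soft > air")
        for ch in ("t1", "t2"):
            if not (t["soft"][ch] > t["cortical"][ch] > 0
                    and t["soft"][ch] > t["air"][ch]):
                raise SpecError("tissue table must leave bone and air MR-dark")


@dataclass
class PhantomCase:
    """One synthetic subject: CT, MR channels, ground-truth masks, and (for
    population members) the true deformation from the base anatomy."""

    ct: VolumeImage
    mr_channels: list          # [T2-like, T1-like]
    channel_names: list
    masks: dict                # body, bone, air, fat, target, oar, fov
    true_field: DeformationField | None
    seed: int


@dataclass
class BeamSpec:
    """Toy beam arrangement: axis-aligned directions, exponential attenuation
    per mm of water-equivalent depth, Gaussian lateral profile."""

    directions: tuple = ((1.0, 0.0, 0.0), (-1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
    fluence: float = 1.0
    mu_per_mm: float = 0.004
    penumbra_sigma_mm: float = 30.0
    prescription_gy: float = 65.0

    def __post_init__(self):
        if len(self.directions) < 1:
            raise SpecError("at least one beam is required")
        if self.mu_per_mm <= 0:
            raise SpecError("attenuation must be positive")
        for d in self.directions:
            v = np.asarray(d, dtype=float)
            if not (np.isclose(np.abs(v).sum(), 1.0) and np.isclose((v != 0).sum(), 1)):
                raise SpecError(
                    f"beam direction {d} is not an axis-aligned unit vector"
                )


# ---------------------------------------------------------------------------
# Base anatomy
# ---------------------------------------------------------------------------

def _coords_mm(grid: GridSpec) -> list[np.ndarray]:
    """Per-axis physical coordinates (mm) relative to the grid centre."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(grid.shape, grid.spacing)
    ]


def _ellipsoid(grid, center_mm, semiaxes_mm) -> np.ndarray:
    cx, cy, cz = _coords_mm(grid)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    return (
        ((X - center_mm[0]) / semiaxes_mm[0]) ** 2
        + ((Y - center_mm[1]) / semiaxes_mm[1]) ** 2
        + ((Z - center_mm[2]) / semiaxes_mm[2]) ** 2
    ) <= 1.0


def _z_cylinder(grid, center_mm, radius_mm, half_len_mm) -> np.ndarray:
    cx, cy, cz = _coords_mm(grid)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    return (
        ((X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2) <= radius_mm**2
    ) & (np.abs(Z - center_mm[2]) <= half_len_mm)


_BONE_SITES = [(0.0, 28.0), (-32.0, -14.0), (32.0, -14.0), (0.0, -36.0)]
_AIR_SITES = [(0.0, -35.0, 0.0), (14.0, -28.0, 25.0), (-14.0, -28.0, -25.0)]


def _base_anatomy(spec: PhantomSpec):
    """Noise-free class volumes + ground-truth masks of the base subject."""
    grid = spec.grid
    body = _ellipsoid(grid, (0, 0, 0), spec.body_semiaxes_mm)
    if not body.any():
        raise SpecError("body does not intersect the grid")
    interior = ndimage.binary_erosion(body, iterations=2)

    bone = np.zeros(grid.shape, bool)
    cortical = np.zeros(grid.shape, bool)
    if spec.bone_count > len(_BONE_SITES):
        raise SpecError(f"at most {len(_BONE_SITES)} bone structures supported")
    half_len = 0.8 * spec.body_semiaxes_mm[2]
    for cx, cy in _BONE_SITES[: spec.bone_count]:
        outer = _z_cylinder(grid, (cx, cy, 0), spec.bone_radius_mm, half_len)
        inner = _z_cylinder(
            grid, (cx, cy, 0),
            max(spec.bone_radius_mm - spec.cortical_thickness_mm, 1.0),
            half_len - spec.cortical_thickness_mm,
        )
        bone |= outer
        cortical |= outer & ~inner
    bone &= interior
    cortical &= interior
    if spec.bone_count and not bone.any():
        raise SpecError("bone structures do not fit inside the body")
    marrow = bone & ~cortical

    air = np.zeros(grid.shape, bool)
    if spec.site_style == "head_neck_like":
        if spec.air_count > len(_AIR_SITES):
            raise SpecError(f"at most {len(_AIR_SITES)} air cavities supported")
        for cx, cy, cz in _AIR_SITES[: spec.air_count]:
            air |= _ellipsoid(grid, (cx, cy, cz),
                              (spec.air_radius_mm,) * 3)
        air &= interior & ~bone
        if spec.air_count and not air.any():
            raise SpecError("air cavities do not fit inside the body")

    fat = _ellipsoid(grid, (-24.0, 12.0, -14.0), (13.0, 17.0, 24.0))
    fat &= interior & ~bone & ~air

    target = _ellipsoid(grid, (0.0, -8.0, 6.0), (spec.target_radius_mm,) * 3)
    target &= body & ~bone
    oar = _ellipsoid(grid, (18.0, 12.0, 0.0), (8.0, 10.0, 14.0))
    oar &= body & ~target
    if not target.any() or not oar.any():
        raise SpecError("target/OAR do not fit inside the body")
    if (target & oar).any():
        raise SpecError("target and OAR overlap")

    t = spec.tissue_table
    classes = [
        ("outside", ~body), ("soft", body), ("fat", fat),
        ("marrow", marrow), ("cortical", cortical), ("air", air),
    ]
    ct = np.empty(grid.shape)
    t2 = np.empty(grid.shape)
    t1 = np.empty(grid.shape)
    for name, m in classes:
        ct[m] = t[name]["ct"]
        t2[m] = t[name]["t2"]
        t1[m] = t[name]["t1"]

    n2 = grid.shape[2]
    fov = np.zeros(grid.shape, bool)
    fov[:, :, : int(np.ceil(n2 * (1.0 - spec.fov_crop_fraction)))] = True

    masks = {
        "body": body, "bone": bone, "air": air, "fat": fat,
        "target": target, "oar": oar, "fov": fov,
    }
    return ct, t2, t1, masks


def _smooth_noise(shape, rng, sigma_vox) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)


def _add_appearance(spec, ct, t2, t1, rng):
    """MR bias field + acquisition noise (noise on CT and MR, bias MR-only)."""
    grid = spec.grid
    sigma_vox = [spec.deformation_smoothness_mm / s for s in grid.spacing]
    out_mr = []
    for mr in (t2, t1):
        bias = np.ones(grid.shape)
        if spec.bias_amplitude > 0:
            b = _smooth_noise(grid.shape, rng, sigma_vox)
            bias += spec.bias_amplitude * b / max(np.abs(b).max(), 1e-12)
        noisy = mr * bias + rng.normal(0.0, spec.mr_noise_sd, grid.shape)
        out_mr.append(np.maximum(noisy, 0.0))
    ct_noisy = ct + rng.normal(0.0, spec.ct_noise_sd, grid.shape)
    return ct_noisy, out_mr[0], out_mr[1]


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Deterministic synthetic subject for the given (spec, seed)."""
    rng = np.random.default_rng(seed)
    ct, t2, t1, masks = _base_anatomy(spec)
    ct, t2, t1 = _add_appearance(spec, ct, t2, t1, rng)
    grid = spec.grid
    return PhantomCase(
        ct=VolumeImage(ct, grid, "CT"),
        mr_channels=[VolumeImage(t2, grid, "MR"), VolumeImage(t1, grid, "MR")],
        channel_names=list(CHANNEL_NAMES),
        masks={k: BinaryMask(v, grid) for k, v in masks.items()},
        true_field=None,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Atlas population
# ---------------------------------------------------------------------------

def random_deformation(spec: PhantomSpec, rng) -> DeformationField:
    """Gaussian-smoothed random vector field with mean displacement magnitude
    equal to ``deformation_amplitude_mm`` (smooth enough to stay invertible)."""
    grid = spec.grid
    sigma_vox = [spec.deformation_smoothness_mm / s for s in grid.spacing]
    comps = [_smooth_noise(grid.shape, rng, sigma_vox) for _ in range(3)]
    disp = np.stack(comps, axis=-1)
    mean_mag = np.linalg.norm(disp, axis=-1).mean()
    if mean_mag > 0 and spec.deformation_amplitude_mm > 0:
        disp *= spec.deformation_amplitude_mm / mean_mag
    else:
        disp[:] = 0.0
    return DeformationField(disp, grid, spec.deformation_smoothness_mm)


def _deform_case(spec, ct, t2, t1, masks, field, rng, seed) -> PhantomCase:
    grid = spec.grid
    vols = {
        "ct": warp(VolumeImage(ct, grid, "CT"), field, grid),
        "t2": warp(VolumeImage(t2, grid, "MR"), field, grid),
        "t1": warp(VolumeImage(t1, grid, "MR"), field, grid),
    }
    wmasks = {
        k: (warp_mask(BinaryMask(v, grid), field, grid) if k != "fov"
            else BinaryMask(v.copy(), grid))
        for k, v in masks.items()
    }
    ct_n, t2_n, t1_n = _add_appearance(
        spec, vols["ct"].values, vols["t2"].values, vols["t1"].values, rng
    )
    return PhantomCase(
        ct=VolumeImage(ct_n, grid, "CT"),
        mr_channels=[VolumeImage(t2_n, grid, "MR"), VolumeImage(t1_n, grid, "MR")],
        channel_names=list(CHANNEL_NAMES),
        masks=wmasks,
        true_field=field,
        seed=seed,
    )


def generate_atlas_population(spec: PhantomSpec, n: int, seed: int
                              ) -> tuple[AtlasDatabase, PhantomCase]:
    """n atlases + one held-out test subject, all smooth random deformations
    of the same base anatomy (leave-one-out harness).

    Each member's MR and CT share the same deformation, i.e. atlas pairs are
    intra-subject aligned by construction.  The held-out case keeps its true
    CT and masks as evaluation ground truth.
    """
    if n < 3:
        raise SpecError("atlas population needs n >= 3")
    ct, t2, t1, masks = _base_anatomy(spec)
    cases = []
    for i in range(n + 1):
        rng = np.random.default_rng((seed, i))
        fld = random_deformation(spec, rng)
        cases.append(_deform_case(spec, ct, t2, t1, masks, fld, rng, seed))
    atlases = [
        AtlasPair(mr_channels=c.mr_channels, ct=c.ct, id=f"atlas_{i:02d}")
        for i, c in enumerate(cases[:n])
    ]
    db = AtlasDatabase(atlases=atlases, channel_names=list(CHANNEL_NAMES))
    return db, cases[n]


# ---------------------------------------------------------------------------
# Toy dose model
# ---------------------------------------------------------------------------

def toy_dose(ct: VolumeImage, beams: BeamSpec, target: BinaryMask,
             scale: float | None = None) -> VolumeImage:
    """Density-sensitive toy dose: per beam, exponential attenuation in
    water-equivalent depth (midpoint cumulative sum along the beam axis)
    times a Gaussian lateral profile about the axis through the target
    centroid; beams are summed and scaled so the target mean equals the
    prescription.

    ``scale`` fixes the output scaling explicitly (the "plan" normalization):
    when comparing a reference CT with synthetic CTs, derive the scale once
    from the reference geometry with :func:`plan_scale` and reuse it, so
    density errors show up as dose differences instead of being absorbed by
    per-volume renormalization.
    """
    if not target.values.any():
        raise SpecError("toy_dose: empty target")
    grid = ct.grid
    density = hu_to_density(ct.values)
    spacing = np.asarray(grid.spacing)
    centroid_idx = np.array(ndimage.center_of_mass(target.values))
    coords = [
        (np.arange(n) - c) * s
        for n, c, s in zip(grid.shape, centroid_idx, spacing)
    ]
    X = np.meshgrid(*coords, indexing="ij")

    total = np.zeros(grid.shape)
    for d in beams.directions:
        v = np.asarray(d, dtype=float)
        axis = int(np.flatnonzero(v != 0)[0])
        sp = spacing[axis]
        dens = density if v[axis] > 0 else np.flip(density, axis=axis)
        wed = np.cumsum(dens, axis=axis) * sp - 0.5 * dens * sp
        if v[axis] < 0:
            wed = np.flip(wed, axis=axis)
        r2 = sum(X[a] ** 2 for a in range(3) if a != axis)
        lateral = np.exp(-r2 / (2.0 * beams.penumbra_sigma_mm**2))
        total += beams.fluence * np.exp(-beams.mu_per_mm * wed) * lateral

    if scale is None:
        mean_target = total[target.values].mean()
        if mean_target <= 0:
            raise SpecError("toy_dose: beams deliver no dose to the target")
        scale = beams.prescription_gy / mean_target
    total *= scale
    return VolumeImage(total, grid, "DOSE")


def plan_scale(ct: VolumeImage, beams: BeamSpec, target: BinaryMask) -> float:
    """Plan normalization factor: the scaling that brings the target mean to
    the prescription on this (reference) geometry."""
    raw = toy_dose(ct, beams, target, scale=1.0)
    mean_target = raw.values[target.values].mean()
    if mean_target <= 0:
        raise SpecError("plan_scale: beams deliver no dose to the target")
    return beams.prescription_gy / mean_target
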