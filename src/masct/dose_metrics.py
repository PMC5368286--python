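"""Dosimetric comparison: 3-D gamma index (local/global), cumulative DVH and
D-point metrics, percentage point differences, and the field-of-view density
override applied before dose recomputation.

The gamma index combines dose difference (DD, %) and distance to agreement
(DTA, mm): for a reference voxel x,

    gamma(x) = min_r sqrt( |r - x|^2 / DTA^2
                          + (D_eval(r) - D_ref(x))^2 / (dd * D_norm)^2 )

with D_norm the local reference dose ("local" mode) or the global reference
maximum ("global" mode), and r running over a neighbourhood of x in which
the evaluated dose is trilinearly interpolated.  A voxel passes when
gamma <= 1.  The candidate search is coarse-to-fine: a coarse lattice
(step ``interp_step_factor * DTA``, radius ``search_radius_factor * DTA``)
with exact distance-based pruning, followed by a local refinement at a
quarter of the coarse step around each voxel's best candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .errors import UndefinedMetricError, UsageError
from .image import BinaryMask, VolumeImage, require_compatible


@dataclass
class GammaCriteria:
    dd_percent: float = 3.0
    dta_mm: float = 3.0
    mode: str = "local"
    search_radius_factor: float = 3.0
    interp_step_factor: float = 1.0 / 3.0
    fine_step_factor: float = 0.1
    dose_floor_fraction: float = 0.01

    def __post_init__(self):
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise UsageError("dd_percent and dta_mm must be positive")
        if self.mode not in ("local", "global"):
            raise UsageError("mode must be 'local' or 'global'")

    @property
    def label(self) -> str:
        return f"{self.dd_percent:g}%_{self.dta_mm:g}mm_{self.mode}"


@dataclass
class GammaMap:
    """Per-voxel gamma values (NaN where undefined) plus the defined mask."""

    values: np.ndarray
    defined: np.ndarray
    criteria: GammaCriteria
    grid: object
    reference_id: str = ""
    n_floor_excluded: int = 0


def override_outside_fov(volume: VolumeImage, body: BinaryMask, fov: BinaryMask,
                         missing_tissue: BinaryMask | None = None) -> VolumeImage:
    """Density-override preparation for a fair CT-vs-sCT dose comparison.

    Voxels inside the body but outside the MRI FOV become water (0 HU);
    voxels in the missing-tissue mask become air (-1000 HU), taking
    precedence on overlap (worst-case assumption).
    """
    require_compatible(volume, body, fov, what="override_outside_fov")
    out = volume.values.copy()
    out[body.values & ~fov.values] = 0.0
    if missing_tissue is not None:
        require_compatible(volume, missing_tissue, what="override_outside_fov")
        out[missing_tissue.values] = -1000.0
    return volume.with_values(out)


def _offsets_mm(radius: float, step: float) -> np.ndarray:
    """All lattice offsets of pitch ``step`` within a ball of ``radius`` mm,
    sorted by distance from the origin (origin first)."""
    n = int(np.floor(radius / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
    d = np.linalg.norm(offs, axis=1)
    keep = d <= radius + 1e-9
    offs, d = offs[keep], d[keep]
    order = np.argsort(d, kind="stable")
    return offs[order]


def _gamma_coarse(ref_vals, eval_vals, idx, grid, offsets, tol_mm, tol_dose):
    """Vectorized-over-voxels coarse sweep: for each candidate offset (sorted
    by distance) update the per-voxel squared-gamma minimum.  Exact pruning:
    a voxel whose running minimum is below the squared distance term of every
    remaining offset cannot improve and leaves the active set."""
    spacing = np.asarray(grid.spacing)
    R = grid.orientation
    n = idx.shape[0]
    gmin2 = np.full(n, np.inf)
    active = np.arange(n)
    base = idx.astype(float)
    shape_max = np.array(grid.shape) - 1

    for off in offsets:
        d2 = float(off @ off) / tol_mm**2
        active = active[gmin2[active] > d2]
        if active.size == 0:
            break
        coords_idx = base[active] + (R.T @ off) / spacing
        inside = np.all((coords_idx >= 0) & (coords_idx <= shape_max), axis=1)
        sel = active[inside]
        if sel.size == 0:
            continue
        de = ndimage.map_coordinates(eval_vals, coords_idx[inside].T, order=1)
        g2 = d2 + (de - ref_vals[sel]) ** 2 / tol_dose[sel] ** 2
        np.minimum.at(gmin2, sel, g2)
    return gmin2


def _gamma_fine(ref_vals, eval_vals, idx, grid, offsets, dists, tol_mm,
                tol_dose, gmin2, chunk=512):
    """Per-voxel exhaustive sweep over the fine candidate lattice, seeded
    with the coarse minima.  Candidates are visited in distance order and the
    loop stops exactly when the distance term alone exceeds the minimum."""
    spacing = np.asarray(grid.spacing)
    R = grid.orientation
    shape_max = np.array(grid.shape) - 1
    d2_norm = (dists / tol_mm) ** 2
    off_idx = (offsets @ R) / spacing  # candidate offsets in index space

    for v in range(idx.shape[0]):
        best = gmin2[v]
        dref = ref_vals[v]
        tol = tol_dose[v]
        base = idx[v].astype(float)
        for start in range(0, offsets.shape[0], chunk):
            if d2_norm[start] >= best:
                break
            sl = slice(start, start + chunk)
            coords = base + off_idx[sl]
            inside = np.all((coords >= 0) & (coords <= shape_max), axis=1)
            if not inside.any():
                continue
            de = ndimage.map_coordinates(eval_vals, coords[inside].T, order=1)
            g2 = d2_norm[sl][inside] + (de - dref) ** 2 / tol**2
            best = min(best, float(g2.min()))
        gmin2[v] = best
    return gmin2


def gamma_map(ref_dose: VolumeImage, eval_dose: VolumeImage,
              criteria: GammaCriteria, mask: BinaryMask) -> GammaMap:
    """3-D gamma comparison of an evaluated dose against a reference dose.

    Defined on the analysis mask minus voxels below the dose floor
    (``dose_floor_fraction`` of the reference maximum, which also guards the
    local normalization against division by ~0).
    """
    require_compatible(ref_dose, eval_dose, mask, what="gamma_map")
    if not mask.values.any():
        raise UndefinedMetricError("gamma: empty analysis mask")
    rv, ev = ref_dose.values, eval_dose.values
    if rv.min() < -1e-9 or ev.min() < -1e-9:
        raise UsageError("gamma: dose volumes must be non-negative")
    ref_max = float(rv.max())
    floor = criteria.dose_floor_fraction * ref_max
    defined = mask.values & (rv >= floor) & (rv > 0)
    n_excl = int(mask.voxel_count - defined.sum())
    if not defined.any():
        raise UndefinedMetricError("gamma: all voxels excluded by the dose floor")

    idx = np.argwhere(defined)
    ref_pts = rv[defined]
    dd = criteria.dd_percent / 100.0
    if criteria.mode == "local":
        tol_dose = dd * ref_pts
    else:
        tol_dose = np.full(ref_pts.shape, dd * ref_max)

    dta = criteria.dta_mm
    radius = criteria.search_radius_factor * dta
    fine_step = criteria.fine_step_factor * dta
    # coarse step snapped to a multiple of the fine step so the two candidate
    # lattices nest (the sweep then converges exactly on the fine lattice)
    ratio = max(1, round(criteria.interp_step_factor / criteria.fine_step_factor))
    step = ratio * fine_step
    coarse = _offsets_mm(radius, step)
    gmin2 = _gamma_coarse(ref_pts, ev, idx, ref_dose.grid, coarse,
                          dta, tol_dose)
    # exhaustive fine sweep at the convergence step (DTA/10 by default),
    # seeded with the coarse minima so the distance stop triggers early
    fine = _offsets_mm(radius, fine_step)
    fine_d = np.linalg.norm(fine, axis=1)
    gmin2 = _gamma_fine(ref_pts, ev, idx, ref_dose.grid, fine, fine_d,
                        dta, tol_dose, gmin2)

    out = np.full(rv.shape, np.nan)
    out[defined] = np.sqrt(gmin2)
    return GammaMap(out, defined, criteria, ref_dose.grid,
                    n_floor_excluded=n_excl)


def gamma_pass_rate(gmap: GammaMap, mask: BinaryMask | None = None) -> float:
    """Percentage of defined voxels (within ``mask`` if given) with gamma <= 1."""
    sel = gmap.defined if mask is None else (gmap.defined & mask.values)
    n = int(sel.sum())
    if n == 0:
        raise UndefinedMetricError("gamma pass rate: no defined voxels in mask")
    return 100.0 * float((gmap.values[sel] <= 1.0).sum()) / n


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction receiving at least each dose level."""

    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def at(self, dose: float) -> float:
        i = np.searchsorted(self.dose_gy, dose, side="left")
        if i >= self.dose_gy.size:
            return 0.0
        return float(self.volume_fraction[i])


def cumulative_dvh(dose: VolumeImage, structure: BinaryMask,
                   bin_width_gy: float = 0.01) -> DVHCurve:
    """v(d) = fraction of structure voxels with dose >= d, on bin edges of
    width ``bin_width_gy`` from 0 to just above the structure maximum."""
    require_compatible(dose, structure, what="cumulative_dvh")
    if not structure.values.any():
        raise UndefinedMetricError("DVH undefined for an empty structure")
    d = np.sort(dose.values[structure.values])
    edges = np.arange(0.0, d[-1] + 2 * bin_width_gy, bin_width_gy)
    frac = 1.0 - np.searchsorted(d, edges, side="left") / d.size
    return DVHCurve(edges, frac)


def dvh_point(dose: VolumeImage, structure: BinaryMask, metric: str) -> float:
    """D-point metrics on structure voxel doses.

    ``D98``/``D2``: dose received by at least 98% / 2% of the volume,
    computed as the 2nd / 98th linear-interpolated percentile of the voxel
    doses; ``Dmean``: arithmetic mean.
    """
    require_compatible(dose, structure, what="dvh_point")
    vals = dose.values[structure.values]
    if vals.size == 0:
        raise UndefinedMetricError("DVH point undefined for an empty structure")
    metric = metric.strip()
    if metric == "Dmean":
        return float(vals.mean())
    if metric.startswith("D"):
        try:
            x = float(metric[1:].rstrip("%"))
        except ValueError:
            raise UsageError(f"unknown DVH metric {metric!r}") from None
        if not 0 < x < 100:
            raise UsageError("Dx percentage must be in (0, 100)")
        return float(np.percentile(vals, 100.0 - x))
    raise UsageError(f"unknown DVH metric {metric!r}")


def ppd(ref_value_gy: float, eval_value_gy: float) -> float:
    """Percentage point difference 100 * (ref - eval) / ref (positive when
    the evaluated dose is lower than the reference)."""
    if ref_value_gy <= 0:
        raise UndefinedMetricError("PPD undefined for non-positive reference value")
    return 100.0 * (ref_value_gy - eval_value_gy) / ref_value_gy


@dataclass
class DoseReport:
    """Gamma pass rates and per-structure DVH points for one sCT dose."""

    pass_rates: dict        # criteria label -> percent
    dvh_reference: dict     # structure -> {metric: Gy}
    dvh_evaluated: dict     # structure -> {metric: Gy}
    ppd_percent: dict       # structure -> {metric: %}

    def __post_init__(self):
        for struct, pts in self.dvh_reference.items():
            if {"D98", "Dmean", "D2"} <= set(pts):
                if not pts["D98"] <= pts["Dmean"] + 1e-9 or not pts["Dmean"] <= pts["D2"] + 1e-9:
                    raise UndefinedMetricError(
                        f"inconsistent DVH points for {struct}: {pts}"
                    )

    def to_dict(self) -> dict:
        return {
            "pass_rates": self.pass_rates,
            "dvh_reference": self.dvh_reference,
            "dvh_evaluated": self.dvh_evaluated,
            "ppd_percent": self.ppd_percent,
        }
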