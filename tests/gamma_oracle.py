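"""Exhaustive fine-grid gamma oracle, independent of the package's search.

For every defined reference voxel the oracle enumerates ALL candidate points
on a fine lattice (step ``dta/10``, radius ``3*dta``), interpolates the
evaluated dose there, and takes the exact minimum.  Candidates are visited
in shells of increasing distance with an exact stopping rule (once the
squared distance term alone exceeds the current minimum, no further shell
can improve), so the result equals the full enumeration.
"""

import numpy as np
from scipy import ndimage


def _fine_offsets(dta_mm, radius_factor=3.0, step_factor=0.1):
    step = step_factor * dta_mm
    n = int(np.floor(radius_factor * dta_mm / step + 1e-9))
    ax = np.arange(-n, n + 1) * step
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([ox, oy, oz], -1).reshape(-1, 3)
    d = np.linalg.norm(offs, axis=1)
    keep = d <= radius_factor * dta_mm + 1e-9
    offs, d = offs[keep], d[keep]
    order = np.argsort(d, kind="stable")
    return offs[order], d[order]


def gamma_bruteforce(ref_vol, eval_vol, criteria, mask, chunk=2048):
    """Per-voxel exhaustive gamma; returns an array with NaN where undefined."""
    grid = ref_vol.grid
    rv, ev = ref_vol.values, eval_vol.values
    ref_max = rv.max()
    floor = criteria.dose_floor_fraction * ref_max
    defined = mask.values & (rv >= floor) & (rv > 0)

    spacing = np.asarray(grid.spacing)
    shape_max = np.asarray(grid.shape) - 1
    offs, dists = _fine_offsets(criteria.dta_mm)
    off_idx = (offs @ grid.orientation) / spacing
    dta2 = criteria.dta_mm ** 2
    dd = criteria.dd_percent / 100.0

    out = np.full(rv.shape, np.nan)
    for vox in np.argwhere(defined):
        dref = rv[tuple(vox)]
        tol = dd * (dref if criteria.mode == "local" else ref_max)
        best = np.inf
        for start in range(0, offs.shape[0], chunk):
            sl = slice(start, start + chunk)
            if dists[start] ** 2 / dta2 >= best:
                break  # exact: remaining shells cannot improve
            coords = vox + off_idx[sl]
            inside = np.all((coords >= 0) & (coords <= shape_max), axis=1)
            if not inside.any():
                continue
            vals = ndimage.map_coordinates(ev, coords[inside].T, order=1)
            g2 = (dists[sl][inside] ** 2 / dta2
                  + (vals - dref) ** 2 / tol ** 2)
            best = min(best, g2.min())
        out[tuple(vox)] = np.sqrt(best)
    return out, defined
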