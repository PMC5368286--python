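"""Multi-atlas CT synthesis: local similarity, spatially-varying weights,
weighted fusion, and the iterative multi-channel refinement loop.

The pipeline mirrors the classical atlas-propagation scheme for deriving a
synthetic CT (sCT) from MR images: every atlas MR is registered to the test
subject's MR (robust affine + B-spline FFD), the paired atlas CT is carried
along through the same transform, per-atlas local normalized cross
correlation (LNCC) maps against the target are converted to rank-based
spatially-varying weights, and the mapped CTs are fused voxelwise.  An
iterative refinement re-registers each atlas CT/MR pair to the current
(sCT, target MR) channel set and recomputes the similarity on both channels,
which sharpens the synthesis where MR contrast alone is ambiguous (bone/air).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .errors import UsageError
from .image import BinaryMask, GridSpec, VolumeImage, require_compatible, resample
from .registration import (
    AffineTransform,
    DeformationField,
    RegistrationConfig,
    affine_register,
    nonrigid_register,
    warp,
)

log = logging.getLogger(__name__)


@dataclass
class AtlasPair:
    """Intra-subject aligned MR channel(s) + planning CT of one database subject."""

    mr_channels: list[VolumeImage]
    ct: VolumeImage
    id: str

    def __post_init__(self):
        if len(self.mr_channels) < 1:
            raise UsageError(f"atlas {self.id!r} needs at least one MR channel")
        require_compatible(self.ct, *self.mr_channels,
                           what=f"atlas {self.id!r} members")


@dataclass
class AtlasDatabase:
    atlases: list[AtlasPair]
    channel_names: list[str]

    def __post_init__(self):
        for a in self.atlases:
            if len(a.mr_channels) != len(self.channel_names):
                raise UsageError(
                    f"atlas {a.id!r} exposes {len(a.mr_channels)} channels, "
                    f"database declares {self.channel_names}"
                )

    def __len__(self) -> int:
        return len(self.atlases)


@dataclass
class SimilarityMap:
    """LNCC values in [-1, 1] on the target grid, with an undefined flag where
    the local variance vanished."""

    values: np.ndarray
    defined: np.ndarray
    atlas_id: str
    kernel_sigma_mm: float


@dataclass
class WeightMaps:
    """Per-atlas non-negative weights; inside ``normalization_mask`` they sum
    to 1 at every voxel."""

    weights: list[np.ndarray]
    normalization_mask: np.ndarray
    atlas_ids: list[str]


@dataclass
class SynthesisResult:
    sct: VolumeImage
    weights: WeightMaps
    mapped_cts: list[VolumeImage] | None
    mapped_mrs: list[list[VolumeImage]] | None
    fields: list[DeformationField] | None
    affines: dict | None
    atlas_ids: list[str]
    iteration: int


@dataclass
class FusionConfig:
    """Synthesis hyper-parameters.

    ``sigma_mm``: Gaussian window of the LNCC similarity.  ``beta``/``top_k``:
    rank-based exponential weighting, w ~ exp(-beta * rank) over the top_k
    locally most similar atlases (top_k None = all).  ``similarity_channel``:
    MR channel driving iteration-0 similarity (T2-like by convention).
    """

    sigma_mm: float = 3.0
    beta: float = 0.5
    top_k: int | None = None
    similarity_channel: int = 0
    registration: RegistrationConfig = dc_field(default_factory=RegistrationConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# Local similarity
# ---------------------------------------------------------------------------

def lncc_map(target: VolumeImage, mapped_atlas: VolumeImage, sigma_mm: float = 3.0,
             epsilon_fraction: float = 1e-6) -> SimilarityMap:
    """Local normalized cross-correlation under a Gaussian window.

    Windowed means/variances/covariance are computed with a Gaussian kernel
    of physical width ``sigma_mm`` (normalized convolution, so boundary
    statistics use only in-domain voxels).  Voxels where either local
    standard deviation falls below ``epsilon_fraction`` of the image dynamic
    range are flagged undefined and assigned similarity 0.
    """
    require_compatible(target, mapped_atlas, what="lncc_map")
    if sigma_mm <= 0:
        raise UsageError("sigma_mm must be positive")
    t = target.values
    a = mapped_atlas.values
    sigma_vox = [sigma_mm / s for s in target.grid.spacing]

    def gf(x):
        return ndimage.gaussian_filter(x, sigma_vox, mode="constant", cval=0.0)

    mass = gf(np.ones_like(t))
    mt = gf(t) / mass
    ma = gf(a) / mass
    var_t = np.maximum(gf(t * t) / mass - mt**2, 0.0)
    var_a = np.maximum(gf(a * a) / mass - ma**2, 0.0)
    cov = gf(t * a) / mass - mt * ma

    eps_t = epsilon_fraction * max(np.ptp(t), 1e-300)
    eps_a = epsilon_fraction * max(np.ptp(a), 1e-300)
    defined = (np.sqrt(var_t) >= eps_t) & (np.sqrt(var_a) >= eps_a)
    vals = np.zeros_like(t)
    denom = np.sqrt(var_t * var_a)
    np.divide(cov, denom, out=vals, where=defined)
    np.clip(vals, -1.0, 1.0, out=vals)
    vals[~defined] = 0.0
    return SimilarityMap(vals, defined, getattr(mapped_atlas, "atlas_id", ""), sigma_mm)


# ---------------------------------------------------------------------------
# Weights and fusion
# ---------------------------------------------------------------------------

def weights_from_similarity(sims: list[SimilarityMap], beta: float = 0.5,
                            top_k: int | None = None) -> WeightMaps:
    """Rank-based exponential weights.

    At each voxel atlases are ranked by similarity (descending, ties broken
    by atlas index), the top_k receive weight proportional to exp(-beta*rank)
    and the rest 0.  Voxels where every atlas is undefined are excluded from
    the normalization mask.  Because a rank-r atlas always receives the same
    normalized weight exp(-beta*r) / sum_r' exp(-beta*r'), the result is
    invariant to atlas ordering whenever similarities are distinct.
    """
    n = len(sims)
    if n < 1:
        raise UsageError("need at least one similarity map")
    if beta < 0:
        raise UsageError("beta must be >= 0")
    k = n if top_k is None else int(top_k)
    if not 1 <= k <= n:
        raise UsageError(f"top_k must be in [1, {n}]")

    stack = np.stack([s.values for s in sims])
    defined_any = np.any([s.defined for s in sims], axis=0)
    # argsort descending; stable sort keeps atlas-index order on ties
    order = np.argsort(-stack, axis=0, kind="stable")
    ranks = np.argsort(order, axis=0, kind="stable")

    rank_w = np.exp(-beta * np.arange(n))
    rank_w[k:] = 0.0
    denom = rank_w[:k].sum()
    w = rank_w[ranks] / denom
    w[:, ~defined_any] = 0.0
    return WeightMaps(
        weights=[w[j] for j in range(n)],
        normalization_mask=defined_any,
        atlas_ids=[s.atlas_id for s in sims],
    )


def fuse(mapped_cts: list[VolumeImage], weights: WeightMaps,
         fill_hu: float = -1000.0) -> VolumeImage:
    """Voxelwise convex combination of the mapped CTs.

    Contributions are sorted before summation so the output is bit-for-bit
    independent of atlas ordering.  Outside the normalization mask the output
    is ``fill_hu``.
    """
    if len(mapped_cts) != len(weights.weights):
        raise UsageError(
            f"{len(mapped_cts)} mapped CTs but {len(weights.weights)} weight maps"
        )
    require_compatible(*mapped_cts, what="fuse")
    contrib = np.stack([w * ct.values for w, ct in zip(weights.weights, mapped_cts)])
    contrib.sort(axis=0)
    out = contrib.sum(axis=0)
    out[~weights.normalization_mask] = fill_hu
    return VolumeImage(out, mapped_cts[0].grid, "CT")


# ---------------------------------------------------------------------------
# End-to-end synthesis
# ---------------------------------------------------------------------------

def _register_and_map(target_mrs, atlas: AtlasPair, config: FusionConfig,
                      fixed_extra=None, moving_extra=None,
                      channel_weights=None, affine=None, init_field=None):
    """Affine + B-spline registration of one atlas onto the target, returning
    (affine, field, mapped MR channels, mapped CT).  ``init_field`` warm-
    starts the non-rigid stage from a previous iteration's field."""
    grid = target_mrs[0].grid
    reg_cfg = replace(config.registration, channel_weights=channel_weights)
    sim_ch = config.similarity_channel
    aff = affine if affine is not None else affine_register(
        target_mrs[sim_ch], atlas.mr_channels[sim_ch], reg_cfg)
    fixed = list(target_mrs) if fixed_extra is None else list(fixed_extra)
    moving = list(atlas.mr_channels) if moving_extra is None else list(moving_extra)
    init = init_field if init_field is not None else aff
    field = nonrigid_register(fixed, moving, init, reg_cfg)
    mapped_mrs = [warp(ch, field, grid) for ch in atlas.mr_channels]
    mapped_ct = warp(atlas.ct, field, grid)
    return aff, field, mapped_mrs, mapped_ct


def synthesize(target_mrs: list[VolumeImage], db: AtlasDatabase,
               config: FusionConfig | None = None,
               keep_mapped: bool = True) -> SynthesisResult:
    """Iteration-0 multi-atlas synthesis.

    For every atlas: robust affine + B-spline registration of its MR to the
    target MR, warp of MR and CT onto the target grid, LNCC similarity on the
    designated channel, rank-exponential spatial weighting, voxelwise fusion.
    Atlases that fail registration are dropped with a warning as long as at
    least two remain.
    """
    config = config or FusionConfig()
    if len(db) < 2:
        raise UsageError("atlas database must contain at least 2 atlases")
    if len(target_mrs) != len(db.channel_names):
        raise UsageError(
            f"target provides {len(target_mrs)} channels, database declares "
            f"{db.channel_names}"
        )
    require_compatible(*target_mrs, what="target MR channels")

    ch = config.similarity_channel
    fields, mapped_mrs, mapped_cts, ids = [], [], [], []
    affines = {}
    for atlas in db.atlases:
        try:
            # iteration 0 registers on the designated MR channel alone;
            # multi-channel registration enters at refinement
            aff, field, mrs, ct = _register_and_map(
                target_mrs, atlas, config,
                fixed_extra=[target_mrs[ch]],
                moving_extra=[atlas.mr_channels[ch]],
            )
        except Exception as exc:  # registration failure: drop atlas, continue
            log.warning("atlas %s dropped: %s", atlas.id, exc)
            continue
        affines[atlas.id] = aff
        fields.append(field)
        mapped_mrs.append(mrs)
        mapped_cts.append(ct)
        ids.append(atlas.id)
    if len(mapped_cts) < 2:
        raise UsageError(
            f"only {len(mapped_cts)} atlases survived registration; need >= 2"
        )

    sims = []
    for i, mrs in enumerate(mapped_mrs):
        s = lncc_map(target_mrs[ch], mrs[ch], config.sigma_mm)
        s.atlas_id = ids[i]
        sims.append(s)
    weights = weights_from_similarity(sims, config.beta, config.top_k)
    sct = fuse(mapped_cts, weights)
    return SynthesisResult(
        sct=sct, weights=weights,
        mapped_cts=mapped_cts if keep_mapped else None,
        mapped_mrs=mapped_mrs if keep_mapped else None,
        fields=fields if keep_mapped else None,
        affines=affines,
        atlas_ids=ids, iteration=0,
    )


def refine(result: SynthesisResult, target_mrs: list[VolumeImage],
           db: AtlasDatabase, n_iter: int = 1,
           config: FusionConfig | None = None) -> SynthesisResult:
    """Iterative multi-channel refinement.

    Each iteration re-registers every atlas (CT + MR channels) to the current
    (sCT, target MR) channel set, recomputes the similarity as the mean of
    LNCC(sCT, mapped CT) and LNCC(target MR, mapped MR), and re-fuses.
    """
    config = config or FusionConfig()
    if n_iter < 1:
        raise UsageError("n_iter must be >= 1; call synthesize for iteration 0")
    ids = set(result.atlas_ids)
    atlases = [a for a in db.atlases if a.id in ids]
    ch = config.similarity_channel
    current = result

    for it in range(n_iter):
        fields, mapped_mrs, mapped_cts, kept = [], [], [], []
        # multi-channel: current sCT paired with atlas CT, designated MR
        # channel paired with the atlas MR
        fixed = [current.sct, target_mrs[ch]]
        affines = current.affines or {}
        prev_fields = dict(zip(current.atlas_ids, current.fields or []))
        for atlas in atlases:
            moving = [atlas.ct, atlas.mr_channels[ch]]
            try:
                aff, field, mrs, ct = _register_and_map(
                    target_mrs, atlas, config,
                    fixed_extra=fixed, moving_extra=moving,
                    affine=affines.get(atlas.id),
                    init_field=prev_fields.get(atlas.id),
                )
            except Exception as exc:
                log.warning("refinement: atlas %s dropped: %s", atlas.id, exc)
                continue
            affines[atlas.id] = aff
            fields.append(field)
            mapped_mrs.append(mrs)
            mapped_cts.append(ct)
            kept.append(atlas)
        if len(mapped_cts) < 2:
            raise UsageError("refinement left fewer than 2 atlases")
        atlases = kept

        sims = []
        for i, (mrs, ct) in enumerate(zip(mapped_mrs, mapped_cts)):
            s_ct = lncc_map(current.sct, ct, config.sigma_mm)
            s_mr = lncc_map(target_mrs[ch], mrs[ch], config.sigma_mm)
            vals = 0.5 * (s_ct.values + s_mr.values)
            defined = s_ct.defined | s_mr.defined
            sims.append(SimilarityMap(vals, defined, atlases[i].id, config.sigma_mm))
        weights = weights_from_similarity(sims, config.beta, config.top_k)
        sct = fuse(mapped_cts, weights)
        current = SynthesisResult(
            sct=sct, weights=weights, mapped_cts=mapped_cts,
            mapped_mrs=mapped_mrs, fields=fields, affines=affines,
            atlas_ids=[a.id for a in atlases],
            iteration=current.iteration + 1,
        )
    return current


def save_database(db: AtlasDatabase, directory) -> str:
    """Write every atlas as NIfTI volumes plus a YAML manifest; returns the
    manifest path."""
    import pathlib

    import yaml

    from .image import write_nifti

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for atlas in db.atlases:
        entry = {"id": atlas.id, "channels": {}, "ct": f"{atlas.id}_ct.nii.gz"}
        write_nifti(atlas.ct, directory / entry["ct"])
        for name, ch in zip(db.channel_names, atlas.mr_channels):
            fname = f"{atlas.id}_{name.lower()}.nii.gz"
            write_nifti(ch, directory / fname)
            entry["channels"][name] = fname
        entries.append(entry)
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {"channel_names": list(db.channel_names), "atlases": entries}, fh
        )
    return str(manifest)


def load_database(manifest_path) -> AtlasDatabase:
    """Load an atlas database from a YAML manifest (paths relative to it)."""
    import pathlib

    import yaml

    from .image import read_nifti

    manifest_path = pathlib.Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    root = manifest_path.parent
    names = doc["channel_names"]
    atlases = []
    for entry in doc["atlases"]:
        mrs = [read_nifti(root / entry["channels"][n], "MR") for n in names]
        ct = read_nifti(root / entry["ct"], "CT")
        atlases.append(AtlasPair(mr_channels=mrs, ct=ct, id=str(entry["id"])))
    return AtlasDatabase(atlases=atlases, channel_names=list(names))


def map_to_ct_space(result: SynthesisResult,
                    mr_to_ct_field: DeformationField | None,
                    ct_grid: GridSpec) -> VolumeImage:
    """Resample the synthesized CT into the planning-CT space through the
    (inverse) subject MR-to-CT deformation; ``None`` means the spaces are
    already aligned and a plain resample suffices."""
    if mr_to_ct_field is None:
        return resample(result.sct, ct_grid, "trilinear")
    return warp(result.sct, mr_to_ct_field, ct_grid, "trilinear")
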