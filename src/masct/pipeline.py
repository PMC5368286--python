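"""End-to-end phantom workflow: synthesize both sCTs for a held-out subject
and evaluate them geometrically and dosimetrically against the true CT.

The stages mirror the clinical comparison protocol: multi-atlas synthesis
(+ optional iterative refinement) and the bulk-density baseline are built in
the subject's MR space, mapped to CT space, density-overridden outside the
MRI field of view, irradiated with the toy beam model, and compared with the
reference CT dose via gamma pass rates and DVH points.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .bulk import DensityTable, assemble_class_map, build_bulk_sct, segment_air_mr
from .dose_metrics import (
    DoseReport,
    GammaCriteria,
    cumulative_dvh,
    dvh_point,
    gamma_map,
    gamma_pass_rate,
    override_outside_fov,
    ppd,
)
from .errors import MasctError, UsageError
from .fusion import FusionConfig, map_to_ct_space, refine, synthesize
from .geometry_metrics import GeometryReport, RegionThresholds, evaluate_geometry
from .image import BinaryMask, VolumeImage, extract_body_mask
from .phantom import (
    BeamSpec,
    PhantomSpec,
    generate_atlas_population,
    plan_scale,
    toy_dose,
)
from .registration import RegistrationConfig

log = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    h = 2166136261
    for b in f"{seed}:{stage}".encode():
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a full phantom comparison needs, resolvable to one seed."""

    seed: int = 0
    n_atlases: int = 10
    refine_iterations: int = 1
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)
    beams: BeamSpec = field(default_factory=BeamSpec)
    gamma_criteria: tuple = (
        GammaCriteria(3.0, 3.0, "local"),
        GammaCriteria(2.0, 2.0, "local"),
    )
    air_threshold: float = 8.0

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(self)


@dataclass
class FullComparisonReport:
    config: dict
    version: str
    n_atlases_used: int
    geometry: dict      # sct name -> GeometryReport
    dose: dict          # sct name -> DoseReport
    volumes: dict       # sct name -> VolumeImage (overridden HU volumes)
    doses: dict         # name -> dose VolumeImage (includes 'ct')
    gamma_maps: dict    # (sct name, criteria label) -> GammaMap

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "n_atlases_used": self.n_atlases_used,
            "geometry": {k: v.to_dict() for k, v in self.geometry.items()},
            "dose": {k: v.to_dict() for k, v in self.dose.items()},
        }


def _site_of(spec: PhantomSpec) -> str:
    return "head_neck" if spec.site_style == "head_neck_like" else "prostate"


def evaluate_dose_pair(ref_dose: VolumeImage, eval_dose: VolumeImage,
                       analysis_mask: BinaryMask, structures: dict,
                       criteria: tuple) -> tuple[DoseReport, dict]:
    """Gamma pass rates within the analysis mask plus DVH points and PPDs for
    each structure; target gets D98/Dmean/D2, other structures Dmean/D2."""
    pass_rates, gmaps = {}, {}
    for crit in criteria:
        gm = gamma_map(ref_dose, eval_dose, crit, analysis_mask)
        pass_rates[crit.label] = gamma_pass_rate(gm, analysis_mask)
        gmaps[crit.label] = gm
    dvh_ref, dvh_eval, ppds = {}, {}, {}
    for name, struct in structures.items():
        metrics = ("D98", "Dmean", "D2") if name == "target" else ("Dmean", "D2")
        dvh_ref[name] = {m: dvh_point(ref_dose, struct, m) for m in metrics}
        dvh_eval[name] = {m: dvh_point(eval_dose, struct, m) for m in metrics}
        ppds[name] = {
            m: ppd(dvh_ref[name][m], dvh_eval[name][m]) for m in metrics
        }
    return DoseReport(pass_rates, dvh_ref, dvh_eval, ppds), gmaps


def run_full_comparison(config: RunConfig) -> FullComparisonReport:
    """Phantom leave-one-out comparison of sCT_a and sCT_bda against the CT."""
    seed = config.seed
    log.info("generating atlas population (n=%d, seed=%d)", config.n_atlases, seed)
    db, subject = generate_atlas_population(
        config.phantom, config.n_atlases, derive_seed(seed, "phantom")
    )
    ct = subject.ct
    grid = ct.grid
    fov = subject.masks["fov"]

    # --- multi-atlas synthesis in MR space, then to CT space ---------------
    reg_cfg = dataclasses.replace(
        config.fusion.registration, seed=derive_seed(seed, "registration")
    )
    fus_cfg = dataclasses.replace(config.fusion, registration=reg_cfg, seed=seed)
    log.info("multi-atlas synthesis (%d atlases)", len(db))
    result = synthesize(subject.mr_channels, db, fus_cfg)
    if config.refine_iterations > 0:
        log.info("refinement (%d iteration(s))", config.refine_iterations)
        result = refine(result, subject.mr_channels, db,
                        config.refine_iterations, fus_cfg)
    sct_a = map_to_ct_space(result, None, grid)

    # --- bulk density baseline --------------------------------------------
    log.info("bulk density baseline")
    t2 = subject.mr_channels[0]
    body_mr = extract_body_mask(t2, "MR")
    air = segment_air_mr(t2, body_mr, config.air_threshold)
    classes = assemble_class_map(body_mr, subject.masks["bone"], air)
    table = DensityTable(site=_site_of(config.phantom))
    _, sct_bda = build_bulk_sct(classes, table)

    # --- geometric evaluation ---------------------------------------------
    log.info("geometric evaluation")
    ct_external = extract_body_mask(ct, "CT")
    geometry = {}
    for name, sct in (("sct_a", sct_a), ("sct_bda", sct_bda)):
        geometry[name] = evaluate_geometry(
            ct, sct, fov, ct_external, extract_body_mask(sct, "CT"),
            config.thresholds,
        )

    # --- density override + toy dose --------------------------------------
    log.info("density override and dose computation")
    volumes = {"ct": ct, "sct_a": sct_a, "sct_bda": sct_bda}
    overridden = {
        name: override_outside_fov(vol, ct_external, fov)
        for name, vol in volumes.items()
    }
    target = subject.masks["target"]
    # the plan normalization is fixed on the reference (override) CT and the
    # same "plan" is recomputed on each sCT geometry
    scale = plan_scale(overridden["ct"], config.beams, target)
    doses = {
        name: toy_dose(vol, config.beams, target, scale=scale)
        for name, vol in overridden.items()
    }

    # --- dosimetric evaluation --------------------------------------------
    log.info("dosimetric evaluation")
    analysis = BinaryMask(ct_external.values & fov.values, grid)
    structures = {
        "target": BinaryMask(target.values & fov.values, grid),
        "oar": BinaryMask(subject.masks["oar"].values & fov.values, grid),
    }
    dose_reports, all_gmaps = {}, {}
    for name in ("sct_a", "sct_bda"):
        report, gmaps = evaluate_dose_pair(
            doses["ct"], doses[name], analysis, structures, config.gamma_criteria
        )
        dose_reports[name] = report
        for label, gm in gmaps.items():
            all_gmaps[(name, label)] = gm

    return FullComparisonReport(
        config=config.to_dict(),
        version=__version__,
        n_atlases_used=len(result.atlas_ids),
        geometry=geometry,
        dose=dose_reports,
        volumes=overridden,
        doses=doses,
        gamma_maps=all_gmaps,
    )
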