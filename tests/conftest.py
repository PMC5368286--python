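"""Shared fixtures.

The expensive end-to-end computations (leave-one-out synthesis on the
standard phantom, perfect-atlas synthesis) are session-scoped so every test
that inspects them shares one run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from masct.bulk import DensityTable, assemble_class_map, build_bulk_sct, segment_air_mr
from masct.fusion import AtlasDatabase, AtlasPair, FusionConfig, refine, synthesize
from masct.image import BinaryMask, GridSpec, VolumeImage, extract_body_mask
from masct.phantom import (
    BeamSpec,
    PhantomSpec,
    generate_atlas_population,
    generate_phantom,
    plan_scale,
    toy_dose,
)


def make_grid(shape=(16, 16, 16), spacing=(2.0, 2.0, 2.0), origin=(0, 0, 0)):
    return GridSpec(shape, spacing, origin)


@pytest.fixture
def small_grid():
    return make_grid()


@pytest.fixture(scope="session")
def phantom_case():
    """Standard 64^3 head-and-neck-style phantom subject."""
    return generate_phantom(PhantomSpec(), seed=20)


@pytest.fixture(scope="session")
def loo_run():
    """Leave-one-out synthesis on the standard phantom suite: 10 deformed
    atlases, one refinement iteration, plus the bulk-density baseline and
    toy doses for the dosimetric comparisons."""
    spec = PhantomSpec()
    db, subject = generate_atlas_population(spec, 10, seed=101)
    cfg = FusionConfig()
    result0 = synthesize(subject.mr_channels, db, cfg)
    result1 = refine(result0, subject.mr_channels, db, 1, cfg)

    t2 = subject.mr_channels[0]
    body_mr = extract_body_mask(t2, "MR")
    air = segment_air_mr(t2, body_mr)
    classes = assemble_class_map(body_mr, subject.masks["bone"], air)
    _, sct_bda = build_bulk_sct(classes, DensityTable(site="head_neck"))

    beams = BeamSpec()
    target = subject.masks["target"]
    scale = plan_scale(subject.ct, beams, target)
    doses = {
        "ct": toy_dose(subject.ct, beams, target, scale=scale),
        "sct_a": toy_dose(result1.sct, beams, target, scale=scale),
        "sct_bda": toy_dose(sct_bda, beams, target, scale=scale),
    }
    return {
        "spec": spec,
        "db": db,
        "subject": subject,
        "config": cfg,
        "result0": result0,
        "result1": result1,
        "sct_bda": sct_bda,
        "doses": doses,
    }


@pytest.fixture(scope="session")
def perfect_atlas_run():
    """Database of exact copies of the held-out subject (fixed-point case)."""
    subject = generate_phantom(PhantomSpec(), seed=33)
    db = AtlasDatabase(
        [AtlasPair(mr_channels=subject.mr_channels, ct=subject.ct, id=f"copy{i}")
         for i in range(3)],
        channel_names=list(subject.channel_names),
    )
    cfg = FusionConfig()
    result0 = synthesize(subject.mr_channels, db, cfg)
    result1 = refine(result0, subject.mr_channels, db, 1, cfg)
    return {"subject": subject, "db": db, "result0": result0, "result1": result1}


def constant_volume(grid, value, modality="CT"):
    return VolumeImage(np.full(grid.shape, float(value)), grid, modality)


def mask_from(grid, values):
    return BinaryMask(values, grid)
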