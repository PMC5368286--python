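# masct — multi-atlas synthetic CT from MRI

MRI-only radiotherapy planning needs a CT-like image for dose calculation:
MR intensities carry no relationship to electron density, so a *synthetic
CT* (sCT) must be derived from the MR images. `masct` implements the
multi-atlas route to that sCT together with everything needed to judge it —
the bulk-density-assignment baseline, the geometric accuracy metrics, the
dosimetric comparison machinery, and a seeded digital-phantom test bench so
the whole pipeline runs and is tested without clinical data.

It is aimed at medical-image-analysis researchers who want a transparent,
scriptable reference implementation of the atlas-fusion workflow and its
evaluation protocol.

## Method

Given a database of intra-subject-aligned (MR, CT) atlas pairs and a test
subject's MR:

1. each atlas MR is registered to the test MR (robust affine with
   multi-start NMI initialization, then cubic B-spline free-form
   deformation);
2. the atlas CTs are warped through the same transforms;
3. per-atlas local similarity s_j(x) to the test MR is measured by local
   normalized cross-correlation (Gaussian window, σ = 3 mm);
4. spatially-varying weights w_j(x) ∝ exp(−β·rank_j(x)) over the locally
   most similar atlases give the fused sCT_a(x) = Σ_j w_j(x)·CT_j(x);
5. an iterative refinement re-registers every atlas (CT, MR) pair to the
   (current sCT, test MR) channel set and re-fuses with a similarity that
   mixes LNCC(sCT, mapped CT) and LNCC(MR, mapped MR).

The baseline sCT_bda assigns bulk densities to tissue classes — bone
1.53 g/cm³ (head & neck) or 1.22 g/cm³ (prostate), air 0.001 g/cm³
(MR intensity < 8), water elsewhere in the body.

Both sCTs are compared with the true CT by mean absolute error (MAE) in the
external / bone / soft-tissue regions, volume index
VI = (V(A) − V(B))/V(A) + 1 and Dice coefficient for external and bone
contours, and dosimetrically by 3-D local gamma analysis (3 %/3 mm and
2 %/2 mm) and DVH points (D98 %, Dmean, D2 %) with their percentage point
differences (PPD), all within the MRI field of view and after a water
density override outside it. See `docs/methods.md` for details.

## Worked example

Run the complete phantom comparison — generate a deformed atlas population,
synthesize both sCTs for the held-out subject, and evaluate:

```
masct full --seed 1 --n-atlases 10 --iters 1 --out results/full
```

`results/full/geometry.csv` then contains (values from this command):

```
sct,metric,roi,value
sct_a,MAE_HU,external,31.72
sct_a,MAE_HU,bone,95.24
sct_a,MAE_HU,soft_tissue,20.20
sct_bda,MAE_HU,external,85.41
sct_bda,MAE_HU,bone,340.00
sct_bda,MAE_HU,soft_tissue,38.11
```

i.e. the multi-atlas sCT more than halves the external-region HU error of
the bulk-density baseline and cuts the bone-region error to under a third —
fixed bulk densities cannot represent the cortical-shell/marrow structure
that atlas fusion transfers. The bone volume index comes out above 1 for
the baseline (its bone contour is too small) and just below 1 for the
multi-atlas sCT (slightly too large, from fusion blur), with bone Dice 0.91
vs 0.95 in the baseline's and atlas method's favour respectively. `dose.csv` holds the gamma pass rates (3 %/3 mm
and 2 %/2 mm, local) and the DVH-point PPDs for target and organ at risk;
`report.json` echoes the full configuration and seed, and re-running with
the same seed reproduces every file byte for byte.

Individual stages are available as `masct phantom / synthesize / bulk /
eval-geom / gamma / dvh`, and as library functions under `masct.*`.

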