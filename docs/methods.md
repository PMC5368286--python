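# Methods

`masct` implements a multi-atlas workflow for deriving a synthetic CT (sCT)
from MR images, the bulk-density-assignment baseline it is usually compared
against, and the geometric and dosimetric machinery used to judge both.
Because clinical paired MR/CT cohorts cannot ship with a software package,
every stage is exercised end-to-end on seeded digital phantoms; this note
describes the models, the defaults, and what the phantom experiments do and
do not show.

## Multi-atlas synthesis

An *atlas* is an intra-subject-aligned pair (MR channels, planning CT) from
a database subject. For a test subject with MR channels only:

1. **Robust affine initialization.** Each atlas MR is affinely registered to
   the test MR. Robustness comes from initialization: a center-of-mass
   alignment plus a small multi-start over translations (±8 mm per axis),
   scored by normalized mutual information (NMI), with the best candidate
   optimized further. The returned transform is the NMI-best of {optimized,
   initialization, identity}, so the stage can never do worse than no
   registration — important when fields of view differ grossly.
2. **Non-rigid registration.** A cubic B-spline free-form deformation with
   20 mm knot spacing, optimized over a 2-level multi-resolution pyramid
   (shrink factors 4 and 2) with a Mattes mutual-information metric (regular
   20 % sampling, seeded). Smoothness is controlled by the knot spacing and
   the pyramid; Jacobian-determinant positivity over the body is monitored
   in the test suite rather than enforced by an explicit bending-energy
   term, which the optimization engine cannot combine with the metric. A
   result that does not improve NMI over its affine initialization is
   discarded in favour of the initialization (an accepted-step rule that
   also makes registration of already-aligned images exactly inert).
3. **Local similarity and spatial weighting.** The warped atlas MR is
   compared with the test MR by local normalized cross-correlation (LNCC)
   under a Gaussian window of σ = 3 mm, computed by normalized convolution
   so boundary statistics use only in-domain voxels. At each voxel the
   atlases are ranked by similarity and receive weight ∝ exp(−β·rank) over
   the top-k atlases (β = 0.5, k = all by default; ties broken by atlas
   index). Rank-based weights are scale-free in the similarity units and
   make the fusion deterministic and permutation-invariant.
4. **Fusion.** The sCT is the voxelwise convex combination of the mapped
   atlas CTs under those weights (contributions sorted before summation so
   atlas order cannot change the floating-point result).
5. **Iterative refinement.** Each iteration re-registers every atlas
   (CT + MR) pair to the current (sCT, test MR) channel set — per-channel
   B-spline registrations whose dense displacement fields are averaged with
   the channel weights, a composition that keeps zero-weight channels
   exactly inert — and recomputes the similarity as the mean of LNCC(sCT,
   mapped CT) and LNCC(test MR, mapped MR). Each re-registration is
   warm-started from the atlas's previous displacement field, so combined
   with the accepted-step rule an iteration can only refine, never undo,
   the existing alignment. Iteration 0 registers on the
   designated similarity channel alone (T2-like by convention); multiple
   channels enter at refinement, where the provisional sCT supplies the
   contrast that MR lacks in bone and air.

The final sCT lives in the test subject's MR space and can be resampled to
the planning-CT grid through a supplied (inverse) deformation field.

## Bulk density assignment baseline

Tissue classes are mapped to fixed physical densities: bone 1.53 g/cm³
(head-and-neck) or 1.22 g/cm³ (prostate), air 0.001 g/cm³, the rest of the
body water (1.0 g/cm³). The bone mask is a supplied input (ground truth on
phantoms; a manual contour clinically — the package does not simulate a
delineator). Air is segmented by an absolute MR threshold (< 8 by default,
which presumes a comparable intensity scale across scans) followed by a
one-voxel opening. On mask overlap bone takes precedence over air. An HU
volume is derived through a piecewise-linear calibration anchored at
(0.001 g/cm³ → −1000 HU), (1.0 → 0), (1.53 → 883); the bone anchor follows
a conventional CT density-calibration slope and is configurable.

## Evaluation metrics

* **MAE** (HU): mean absolute sCT−CT difference over a region. Regions are
  built from the planning CT within the MRI field of view (FOV): bone is
  CT > 150 HU closed with a 3 mm ball and hole-filled (to include marrow
  and softer bone), soft tissue is CT > −150 HU minus bone. Thresholds are
  strict inequalities; both thresholds and the closing radius are config.
* **VI**: (V(ref) − V(eval))/V(ref) + 1; 1 means equal volumes, > 1 means
  the reference (clinical) contour is larger. Volumes are voxel counts times
  voxel volume, no sub-voxel surface correction.
* **DSC**: 2|A∩B|/(|A|+|B|), with the conventional 0.7 good-overlap flag.
* **3-D gamma**: γ(x) = min over candidates r of
  √(|r−x|²/DTA² + (D_eval(r) − D_ref(x))²/(dd·D_norm)²), D_norm local or
  global. The candidate search covers a radius of 3×DTA: a coarse lattice
  (step ⌊(DTA/3)/(DTA/10)⌉ fine steps) with exact distance-sorted pruning
  seeds the minima, then an exhaustive per-voxel sweep of the fine lattice
  (step DTA/10, the scale at which the discretized minimum is reported)
  finishes each voxel, stopping exactly when the distance term alone
  exceeds the running minimum. Voxels below a dose floor of 1 % of the
  reference maximum are flagged undefined (this also guards the local
  normalization against division by ~0); their count is reported.
  Note that gamma values from lattices that scale with DTA can violate
  per-voxel monotonicity across criteria by up to the lattice resolution
  difference; the continuous quantity is exactly monotone, and pass rates
  on the test suite respect the 3 %/3 mm ≥ 2 %/2 mm ordering.
* **DVH / PPD**: cumulative DVH on 0.01 Gy bins; D98/D2 are the 2nd/98th
  linear-interpolated percentiles of the structure voxel doses (declared
  because discrete Dx conventions differ), Dmean the arithmetic mean. PPD =
  100·(ref − eval)/ref, normalized by the reference DVH-point value
  (positive = evaluated dose lower); normalization by prescription is
  selectable.
* **FOV density override**: before dose comparison, body voxels outside the
  MRI FOV are set to water (0 HU) in reference and evaluated volumes alike,
  and missing-tissue voxels to air (−1000 HU, worst case; air wins on
  overlap), so dose differences reflect only density differences inside the
  FOV.

## Digital phantoms

A phantom subject is an ellipsoidal soft-tissue body (≈35 HU) containing a
fat inclusion (−90 HU), heterogeneous bone — cylindrical structures with a
bright cortical shell (1100 HU) around a marrow core (250 HU), both MR-dark —
optional air cavities (head-and-neck style only), a spherical target and an
ellipsoidal organ at risk, on a 64³ grid of 2.5 mm voxels. Two MR contrasts
(T2-like, T1-like) share the CT's geometry by construction. Appearance
realism: a smooth multiplicative bias field (±15 %) on MR only, additive
Gaussian noise (12 HU CT, 5 a.u. MR). Bone heterogeneity is what makes the
comparison meaningful: a single bulk density cannot represent both shell and
marrow, while atlas fusion transfers the internal structure.

An atlas population deforms one base anatomy with independent random fields
(Gaussian-smoothed white noise, smoothness 15 mm, mean displacement 4 mm —
smooth enough to remain invertible in practice), with fresh noise and bias
per member; the held-out member keeps its true CT and masks, giving a
leave-one-out harness with exact ground truth. The MRI FOV mask crops 25 %
of the cranio-caudal extent so the override logic is exercised.

What the phantoms do *not* emulate: MR physics (relaxometry, distortion),
scanner differences within a database, postural change between MR and CT
sessions, couch structures, and real anatomical variability (the population
is one anatomy under smooth deformation). Passing the phantom suite shows
the pipeline's mechanics and orderings are right, not clinical-grade
accuracy; the MAE/VI/DSC/gamma magnitudes on phantoms are not comparable to
patient values.

The **toy dose model** is a test harness, not a dose engine: axis-aligned
beams with exponential attenuation (μ = 0.004/mm) in water-equivalent depth
(midpoint cumulative sum of CT-derived density along the beam axis — exact
for homogeneous media) and a Gaussian lateral profile (σ = 30 mm) about the
axis through the target centroid. The plan normalization (target mean =
prescription, 65 Gy default) is derived once on the reference geometry and
reused on the sCT geometries, so density errors appear as dose differences.
Oblique beams are not supported.

## Numerical choices and conventions

* World convention: voxel i sits at origin + orientation·(spacing∘i); all
  displacements are in mm in world axes, stored on the fixed grid;
  warping is pull-back (output voxel x reads the input at T(x)).
* Resampling fills out-of-domain voxels per modality (−1000 HU for CT, 0
  otherwise). Grid compatibility tolerance is 1e-6.
* Body contours: CT > −250 HU, MR > Otsu threshold (the clinical tool's
  threshold is unpublished; both defaults are configurable), largest
  connected component, holes filled.
* Morphology uses a ball element of physical radius converted to voxels per
  axis (rounded half-up, minimum 1 voxel); close/open pad the lattice by the
  element radius so extensivity/anti-extensivity hold at the border.
* Field inversion is fixed-point iteration with a mean composition-residual
  tolerance of 0.5× the voxel spacing.
* Determinism: phantom generation and registration sampling are seeded; the
  full pipeline is a pure function of (config, seed) and report files are
  byte-reproducible.

## Problem sizes in the test suite

The standard suite runs at 64³ (2.5 mm voxels) with 10 atlases and one
refinement iteration for the leave-one-out experiment; gamma/oracle
comparisons use 20³ dose grids at the 2.5 mm dose-grid spacing; the
end-to-end CLI determinism check uses 48³ with 3 atlases, since determinism
does not depend on problem size. These sizes are the package's declared
desk-scale study conditions.

## Known limitations

* The non-rigid objective uses Mattes MI as the optimization surrogate for
  NMI (the engine does not expose Studholme NMI as an optimizable metric);
  NMI is used for initialization scoring and accepted-step guarding.
* Multi-channel registration averages per-channel fields rather than
  optimizing a single summed objective.
* No surface-distance metrics (Hausdorff etc.); no DICOM; 3-D scalar
  volumes only.
* The air threshold (< 8) is an absolute intensity and therefore
  scanner-dependent on real data.
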