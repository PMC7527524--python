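# Methods

## The measurement problem

During a gaze shift the eyeball mostly rotates about its own centre, but it
is suspended in orbital fat rather than mounted on an axle, so its centre
also *translates* by a fraction of a millimetre.  `oculotrans` measures that
translation from one volumetric orbital image per gaze direction (central,
right, left, up, down).  The measurement chain is:

1. **Superimposition.**  Head fixation between acquisitions is imperfect, so
   each secondary-gaze volume is rigidly aligned to the central-gaze volume
   using *static tissue only* — the globes, dilated by a safety margin, are
   excluded from the similarity metric so the eye movement under study
   cannot drive the alignment.
2. **Globe segmentation.**  Each globe is extracted by seeded region growing
   from a vitreous seed and reduced to its binary centroid — the unweighted
   arithmetic mean of member voxel centres, converted to millimetres per
   axis (the voxels are anisotropic, 0.7 × 0.7 × 0.6 mm).
3. **Kinematics.**  The centroid of the secondary gaze is mapped through the
   recovered head-motion transform *as a point* (never by resampling a
   mask), and the shift is reported as an in-plane distance `d = √(Δu²+Δv²)`
   and direction `θ = atan2(Δv, Δu)`: axial (x–y) plane for horizontal gaze,
   sagittal (y–z) plane for vertical gaze.
4. **Cohort statistics.**  One eye per subject (alternating right/left down
   a seeded shuffle), mean ± SD with 95 % CIs, pooled-variance t-tests
   between contrasts, and Pearson correlations against ocular biometry.

## Coordinate and angle conventions

One patient frame everywhere: `+x` toward the patient's left, `+y` anterior,
`+z` superior; voxel index `i` maps to coordinate `i · spacing`, so voxel
centres sit at integer multiples of the pitch.  In the axial plane the
direction convention follows the left eye — medial 0°, anterior 90°,
lateral 180°, posterior 270° — and the right eye's medial component is
sign-flipped ("×(−1)") so both eyes share it.  In the sagittal plane
anterior is 0°, up +90°, down −90°.  A one-argument arctangent of Δv/Δu is
quadrant-ambiguous (it cannot distinguish medial-anterior from
lateral-posterior); the two-argument form is used throughout.  Angles are
canonically signed in (−180°, 180°], with a positive-range [0°, 360°)
variant available because both conventions appear in common reporting.
`θ` is undefined (NaN, flagged) exactly when `d = 0`.

## The digital phantom

Real multi-gaze orbital acquisitions of this kind are not redistributable,
so validation rests on a synthetic phantom with exact ground truth.  It is
rendered analytically from ellipsoid primitives with sub-voxel supersampled
partial-volume occupancy (default 3³ samples per voxel):

* **Globes** — per eye an outer ellipsoid (default a sphere of diameter
  25.27 mm, the emmetropic axial length) with a 1 mm dark scleral shell, a
  bright vitreous interior, and a dark lens embedded strictly inside the
  interior near the anterior pole.  The lens centroid doubles as an
  anterior-pole landmark for rotation estimation.
* **Static scene** — orbital fat pads, bony nasal/lateral/apex walls, a
  soft-tissue canal per orbit that passes through the apex bone and leaves
  the field of view (so a region grow seeded in fat escapes the grid — the
  leak failure mode the segmenter must detect), and four point fiducials
  placed asymmetrically to give registration leverage in every degree of
  freedom.
* **Gaze** — each secondary volume rotates the globes about their own
  centres by the fixation-target angle (30° horizontal, 20° vertical) *and*
  translates the centres by a configurable vector; the whole scene is then
  moved by a random rigid head motion (≤ 2°, ≤ 2 mm) and Gaussian noise is
  added (SD 2 % of the vitreous intensity).  Everything is re-rendered
  analytically in the moved frame, so no interpolation artefacts enter the
  ground truth.

The default per-eye translations are the cohort-mean values the package's
own statistics module treats as reference conditions: abducting eye
0.69 mm @ 228.7° and adducting eye 0.68 mm @ −4.2° (axial plane, left-eye
convention — horizontally the globes move *with* the gaze), elevating eye
0.43 mm @ −96.8° and depressing eye 0.44 mm @ 101.8° (sagittal plane —
vertically they move *against* it).  A single per-gaze vector cannot
represent both eyes of one volume (the same physical gaze is abduction for
one eye and adduction for the other), hence the per-(gaze, side)
parametrisation.

Intensities are arbitrary but fixed (vitreous 1.0, fat 0.6, sclera 0.2,
bone 0.05, lens 0.35, fiducials 0.9, posterior soft tissue 0.55);
registration and segmentation are intensity-scale invariant by
construction, and a test asserts it.

What the phantom does **not** emulate: MR physics (k-space, bias fields,
Rician noise — the additive Gaussian model is deliberately simpler),
extraocular muscles and eyelids, optic-nerve deformation, convergence, and
anatomical variability beyond globe size.  Passing the recovery suite
therefore demonstrates that the *measurement chain* is unbiased and precise
under the stated geometry and noise; it does not certify segmentation or
registration performance on clinical images.

## Registration details

Metric: normalised cross-correlation over the static-mask voxels —
intensity-scale invariant and appropriate for same-session, same-modality
volumes (mutual information would buy nothing here).  The static mask is
the Otsu foreground minus the globes dilated by 3 mm (covering globe
translation plus residual motion), minus a 4 mm rim at the grid faces where
tissue enters or leaves the field of view between acquisitions — content
change the rigid model cannot explain and must not be penalised for.

Optimisation: three levels (Gaussian smoothing σ = 2, 1, 0 voxels with
point strides 4, 2, 1), Powell's derivative-free search over six parameters
(extrinsic x-y-z rotations about the grid centre in degrees, translations
in mm), started at the coarsest level from the best of a fixed 3×3×3
translation grid (±3 mm).  Evaluation order is fixed, so results are
bit-reproducible.  Search bounds are ±10°/±10 mm; an optimum on the bounds
yields a failure report, not an exception.

The *reported* residual (1 − masked NCC) is computed on σ = 1 voxel
smoothed intensities: the raw NCC of two noisy acquisitions is bounded by
the noise floor even at perfect alignment (≈ 0.13 at 2 % noise on this
scene), while the smoothed residual is ≈ 0.001 when aligned and ≈ 0.1 at
0.5 mm misalignment.  The default pass threshold of 0.02 sits comfortably
between the two regimes on phantoms; it is configurable for real data.
This quantitative check replaces a manual two-rater agreement step.

## Segmentation details

Region growing uses 6-connectivity with a fractional tolerance (default
0.25 of the seed intensity, emulating a tolerance-based wand selection in
3-D rather than slice-by-slice), followed by one-voxel morphological
closing, hole filling (which absorbs the lens) and largest-component
selection.  Errors: a region touching the grid boundary (leak) or smaller
than 1 ml (misplaced seed).  The segmented set is the globe *interior*;
because the tolerance band cuts the vitreous–sclera partial-volume ramp
slightly above the 50 % point, the mask underestimates the interior volume
by ~1–4 % depending on voxel size relative to globe size — a symmetric
shrink that leaves the centroid unbiased, which is what the displacement
measurement depends on.  An optional `shell_mm` dilation (1 mm) adds the
scleral shell for volume-sensitivity analyses.

The centroid is binary (unweighted), not intensity-weighted: the quantity
of interest is the mean position of the points in the shape.

Rotation is estimated from the signed in-plane angle between the
centroid→lens-pole vectors of the two gazes; any common translation cancels
in the difference vectors.  This estimator is validated only on phantoms
(±1° pure rotation, ±1.5° with translation); how such angles are best
measured on clinical images is left open.

## Statistical choices

* 95 % CIs use z = 1.96, not the t quantile.  This choice reproduces the
  reference elevation/depression CI bounds exactly from their printed
  means/SDs at n = 56 (t₅₅ does not).  The analogous horizontal-gaze CI
  bounds are not recomputable from their printed moments under either
  quantile — presumably computed from unrounded data — and are not used as
  checks.
* Directions are summarised twice: arithmetically on range-wrapped angles
  and circularly (vector-mean direction, circular SD = √(−2 ln R̄)).  The
  two diverge for dispersed samples near the wrap point; both are reported
  and neither is adjudicated.
* Gaze contrasts use the independent-samples pooled-variance t-test, and
  biometry correlations plain Pearson R — replicating the reference
  analysis plan as stated rather than "improving" it (no pairing, no
  mixed-effects, no multiplicity correction).
* The cohort simulator draws biometry and per-contrast distances from a
  joint Gaussian with a configurable correlation structure (axial
  length–ocular volume 0.75, distances inter-correlated 0.4, PSD-repaired),
  wrapped-normal directions, a small per-eye jitter (SD 0.05 mm), and
  distances clipped at 0.01 mm.  The clipping floor is why a cohort
  simulated with zero true translation still shows a small positive mean
  distance — the simulator's analogue of a measurement noise floor.

## Problem sizes and numerical tolerances

Two phantom geometries are used.  The full acquisition grid
(256 × 256 × 67, 25.27 mm globes) is used by `scripts/acceptance.py` and
the segmentation-fidelity test; a desk-scale grid (96 × 96 × 48, 15 mm
globes — large enough for the 5 mm containment margin and the 1 ml
segmentation floor) is used everywhere else, chosen so the whole suite runs
in minutes rather than hours.  Recovery tolerances come from a
discretisation study on these grids: pure 30° rotation yields apparent
translation ≤ 0.15 mm (measured ≈ 10⁻⁵ mm at supersample 3 — the analytic
renderer keeps the binarised mask centrosymmetric); noiseless translation
recovery is within 0.15 mm / 5°; under full head motion + noise the
worst-case distance error over ten seeds stays within 0.3 mm.  Registration
recovers a known head motion to 0.1°/0.1 mm noiseless and 0.3°/0.2 mm at
2 % noise.

Degenerate inputs are errors, not warnings: empty masks, zero-variance
correlations, n < 2 summaries, seeds below the background intensity.  One
deliberate exception: a zero pooled variance with equal means returns
t = 0, p = 1 (identical constant samples are "not different", not an
error).

## Known limitations

* In-plane (2-D) displacement only, as the plane formulas define it; the
  out-of-plane component is reported for transparency but not analysed.
  Torsion is not measured.
* Strictly rigid 6-DOF superimposition; no scaling or deformable component.
* DICOM import is read-only and restricted to single-series canonical axial
  stacks; NIfTI is the primary interchange format.
* The per-slice 2-D wand workflow is intentionally not provided; the 3-D
  region grow visits the same voxel set with fewer failure modes.
* Phantom realism limits are listed above; real-data thresholds (residual
  pass level, wand tolerance) will likely need retuning.
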