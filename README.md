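# oculotrans

Measuring **translatory movement of the eyeball** from multi-gaze volumetric
orbital imaging.

The eye is usually modelled as a ball joint: rotation about a fixed centre,
nothing else.  But the globe is suspended in orbital fat, not mounted on an
axle, and during a gaze shift its centre also *translates* by a fraction of a
millimetre — with the gaze horizontally, against it vertically.  Quantifying
that sub-voxel displacement from one T2-weighted orbital volume per gaze
direction (central, right, left, up, down) is what this package does.  It is
aimed at ocular-kinematics and strabismus researchers who have (or plan) such
acquisitions, and it ships a fully synthetic orbital phantom so every stage
is testable without any patient data.

## Method

For one eye and one secondary gaze, with centroid $(x_1, y_1, z_1)$ in
central gaze and $(x_2, y_2, z_2)$ in the secondary gaze (after rigid
superimposition of the volumes on *static tissue only*):

* horizontal gaze, axial plane:
  $d = \sqrt{(x_2-x_1)^2 + (y_2-y_1)^2}$, $\theta = \operatorname{atan2}(\Delta y, \Delta u)$
  where $\Delta u$ is the **medial** component of $\Delta x$ (the right eye's
  $\Delta x$ is multiplied by $-1$ so both eyes share the left-eye
  convention: medial 0°, anterior 90°, lateral 180°, posterior 270°);
* vertical gaze, sagittal plane:
  $d = \sqrt{(y_2-y_1)^2 + (z_2-z_1)^2}$, $\theta = \operatorname{atan2}(\Delta z, \Delta y)$
  (anterior 0°, up +90°, down −90°).

The centroid is the unweighted mean of segmented-globe voxel centres, per
axis in millimetres (anisotropic spacing).  The secondary centroid is mapped
through the recovered head-motion transform as a *point* — masks are never
resampled — which is what preserves accuracy below the 0.6 mm slice
thickness.  Cohort analysis selects one eye per subject, reports
mean ± SD with 95 % CIs (z = 1.96), compares gazes with pooled-variance
t-tests, and correlates distances with axial length and ocular/orbital
volume (Pearson).  See `docs/methods.md` for conventions, the phantom's
motion model, and every numerical choice.

## Worked example

Generate a desk-scale phantom subject and measure the left eye's
displacement in right gaze:

```python
import oculotrans as ot

cfg = ot.small_test_config(seed=1, gazes=("central", "right"))
volumes, truth = ot.generate_phantom(cfg)

res = ot.end_to_end_displacement(volumes["central"], volumes["right"], side="left")
print(f"d = {res.displacement.d:.2f} mm, theta = {res.displacement.theta_deg:.1f} deg, "
      f"residual = {res.alignment.residual:.4f}")
print("truth:", truth.gaze["right"].translation_mm["left"])
```

```
d = 0.66 mm, theta = -4.3 deg, residual = 0.0029
truth: [-0.67817384 -0.04980197  0.        ]
```

The left eye in right gaze is *adducting*; the generator's default for that
contrast is 0.68 mm toward 4.2° lateral of medial, and the pipeline recovers
0.66 mm @ −4.3° through head motion (here ≈ 1.8°/0.9 mm, corrected by the
static-tissue registration, residual 0.003 ≪ the 0.02 pass threshold) and
2 % acquisition noise.  A full cohort run — per-subject displacement CSV,
biometry, summary and correlation tables, QC overlays, reproducibility
log — is one call (`ot.run_all(ot.RunConfig(...))`) or one shell command:

```sh
oculotrans run-all --config cohort.yaml --out run/
```

The CLI verbs `phantom`, `register`, `segment`, `displace`, `stats` expose
the individual stages.

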