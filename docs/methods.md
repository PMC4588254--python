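# Methods

## Geometry and projection model

The pelvis-specific frame places the origin at the centre of the superior
S1 endplate, with +X toward the patient's left, +Y perpendicular to the
inlet plane (cephalad along the ring) and +Z perpendicular to the outlet
plane (anterior).  The published convention fixes only the planes, not the
axis signs; the signs above are this package's choice and are what the
direction labels (cephalad, lateral, ...) are defined against.

Views are orthographic (parallel-beam): the inlet image is the X/Z plane,
the outlet image the X/Y plane.  This matches the definition of the
standardized views as coordinate planes; beam divergence and perspective
magnification are deliberately out of scope, which is also why pure
translations are recovered exactly (see below).  The AP view has no
canonical axis in the pelvis frame because pelvic obliquity varies between
people (roughly 40–60°); it is modelled as the inlet beam tilted about X by
a configurable `ap_tilt_deg` (default 45°, inside that range), with the
image vertical chosen so superior maps to +v.  Within each view, v grows
superiorly (anteriorly in the inlet view) — documented for CSV authors;
all formulas are difference-based, so the image origin is arbitrary.

Rigid displacements compose an intrinsic X→Y→Z rotation about a pivot with
a translation.  The composition order only matters for combined multi-axis
rotations; simulated studies draw each rotation independently and the
order is part of the configuration surface.

## Calibration

Pixel coordinates are converted to mm per view with
`scale = fh_true_mm / fh_px`, the intact femoral head's true diameter over
its measured pixel diameter.  Calibration is per view, since magnification
may differ between projections.  Because every measured quantity is a
difference of in-image distances, reports are invariant to the rendering
scale (verified at 0.5 vs 2 mm/px).  Mirroring the standardized workflow,
calibration is established once per image — it is not re-measured by each
simulated observer — but `add_marking_noise(recalibrate_from_marks=True)`
propagates observer calibration error for sensitivity studies.

## Measurement formulas and classification

The three translational formulas and three rotational indicators are
implemented exactly as printed (see README).  Decisions taken where the
source description is silent or inconsistent:

* **Units of the ±2 band** — interpreted as millimetres after calibration,
  consistent with the 0–2 mm anatomic-reduction convention the band is
  justified by; the half-width is configurable (`threshold_mm`).
* **Neutral band closure** — inclusive at both ends: an indicator of
  exactly ±2 mm is neutral; 2 + 1e-9 is not.
* **Label conventions** — the canonical table and the descriptive prose
  disagree on which sign is flexion vs extension (sagittal) and varus vs
  valgus (outlet).  The default `table2` convention implements the table's
  inequalities verbatim; `label_convention="text"` swaps those two planes'
  names.  Geometry and numbers are identical under both.
* **Ties** — a translational value of exactly 0 maps to direction "none".
* **Missing landmarks** — formulas fail loudly, naming every absent
  (landmark, side, view) at once; `allow_partial` degrades the affected
  quantities to NaN/"unavailable" instead.

## Ground-truth displacement conventions

`DisplacementSpec` stores translations in world mm and rotations as named
anatomical angles: +rot_x = extension, +rot_y = internal rotation,
+rot_z = varus (table2 naming).  Flexion/extension is mirror-symmetric
between sides, while internal/external and varus/valgus reverse the signed
world rotation between left and right; the conversion is centralised in
`DisplacementSpec.to_transform`.  The rotation pivot is unspecified in the
source method; the default is the centroid of the injured side's five
landmarks, with the anterior SI joint and the femoral head centre
(acetabulum) as alternatives.  Rotation indicators depend only on the
chord orientation of the landmark pairs, not on the pivot, so the
direction classification is pivot-independent — this is tested
exhaustively (6 directions x 3 pivots x 2 sides x 5–20°).

## The template

The bilateral landmark template is a synthetic engineering fixture with
plausible adult-pelvis magnitudes (e.g. ASIS ±115 mm lateral, femoral head
48 mm); it is not measured from any real pelvis and can be overridden via
configuration.  Two geometric properties were designed in:

* landmarks referenced by the translational formulas sit more than 30 mm
  from the midline reference S along the axis each formula reads, so every
  pure translation up to the simulator's 30 mm cap is recovered with zero
  error under the orthographic model;
* each rotation plane's landmark chord has enough depth separation that a
  5° rotation moves its indicator beyond the 2 mm neutral band (worst
  case: the inlet plane, ~4.7 mm at 5°).

## Simulated studies

`simulate_study` draws, per subject: an injured side (fair coin), a
displacement from a two-pattern mixture — translation-dominant
("type C-like", translation SD 12 mm / rotation SD 5°) or
rotation-dominant ("type B-like", translation SD 8 mm / rotation SD 10°) —
of truncated zero-mean Gaussians capped at 30 mm and 20°.  With the
default equal weights the pooled SDs are ≈10 mm and ≈8°, the unstable-
fracture displacement regime the validation study targets, while
individual subjects still look shear-like or rotation-like.

Observer error is independent isotropic Gaussian marking noise per 2D
landmark.  `sd_mm` follows the fiducial-localization-error convention: it
is the RMS of the 2D miss distance, so each coordinate is perturbed with
SD `sd_mm/√2`.  Per-rater noise streams are spawned from the global seed;
the entire study regenerates bit-for-bit.

What the generator does *not* emulate: beam divergence and parallax,
overlapping bony shadows, bowel gas, landmark ambiguity that grows with
displacement, correlated (systematic) observer bias, bilateral injuries,
and fragment comminution.  Passing simulation results therefore validate
the formula system's internal consistency and noise robustness, not its
performance on clinical images.

## Reliability statistics

* **ICC** — two-way random effects, absolute agreement.  The default form
  is single measures, i.e. the reliability of one observer's measurement
  (the published analysis cites the two-way random model without the
  single/average qualifier); average measures is available via
  `icc_form="average"`.  Implemented directly from the two-way ANOVA mean
  squares with the Shrout–Fleiss/McGraw–Wong F-based 95% CI, because the
  off-the-shelf implementation rounds its CI to two decimals; the
  implementation is cross-checked in tests against both a brute-force
  ANOVA oracle (1e-10) and pingouin.
* **Kappa** — Fleiss' multi-rater kappa by default, with the large-sample
  one-sided z-test of the no-agreement null (the published analysis
  reports p-values without naming the test; this is an assumption).  The
  alternative `pairwise_cohen_mean` averages Cohen's kappa over rater
  pairs; it carries a p-value only for exactly two raters, since the
  pairwise estimates are dependent and no standard test applies.  Note
  that 2-rater Fleiss kappa equals Cohen's kappa only when both raters'
  marginal category rates coincide (in general it is Scott's pi).
* **Landis–Koch labels** — <0 poor, then slight/fair/moderate/substantial/
  almost-perfect bands.  The printed scale leaves gaps (0.20→0.21, ...);
  bands are cut 0.005 below each printed lower bound so every printed
  edge value lands in the band whose printed range contains it.
* **Degenerate inputs** — a ratings matrix with no between-subject
  variability (ICC) or a single used category (kappa) raises an explicit
  `DegenerateStatisticError` (CLI exit code 3) rather than propagating
  NaN.

## Known limitations

* **Cross-plane coupling.**  The rotational inequalities were derived for
  single-direction displacement.  A rotation in one plane changes landmark
  coordinates in the others: e.g. an 8° varus rotation of the default
  left template also moves the inlet indicator to +10.5 mm ("internal")
  and the sagittal indicator to −4.6 mm ("flexion").  For combined
  displacements the per-plane classes describe the projected geometry,
  not independent rotation components.  `evaluate_recovery` accounts for
  this by taking the noiseless indicator's class as truth when a plane's
  true angle is exactly zero.
* **Midline-reference noise amplification.**  The transverse formula
  measures distances from S toward opposite sides of the pelvis, so S's
  marking error enters both distances with the same sign and doubles in
  the difference: transverse indicator noise is √6·σ per-axis versus √2·σ
  for vertical/AP.  Transverse is consequently the least reliable
  parameter in simulation, visibly so at 25 subjects.
* Rotation *angles* in degrees are not measurable from the radiographs;
  the method yields mm indicators and direction classes only, and degrees
  exist only in the simulator's ground truth.
* The intact contralateral hemipelvis is assumed truly intact and
  undisplaced, per the method's premise.

## Problem sizes and tolerances

Default study sizes mirror the validation design (25 subjects, 5
observers, 1 mm noise); the direction-classification experiment uses 200
cases.  Geometric assertions use 1e-9 mm (rigid transforms, projections,
translation recovery); statistical oracles 1e-10 (ICC) and 1e-12 (kappa);
the marking-noise RMS Monte-Carlo check uses 10,000 draws at 2% relative
tolerance.
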