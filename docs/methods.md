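# Methods

This note documents the models, conventions and numerical choices behind
thalatract, and what its synthetic validation does and does not show.

## Coordinate conventions

All world coordinates are millimetres in a RAS frame; volumes carry a 4x4
NIfTI affine and voxel centers sit at integer indices. Voxel indexing is
0-based internally; every user-facing coordinate is world mm, so no
0-/1-based ambiguity is exposed. "Right" in the stereotactic construction
is the negative first RAS coordinate (the lateral axis of the AC-PC frame,
`axis1 x axis2`); the `side` argument flips the sign.

## Phantom model

A subject is a cuboid grid (default 32 cubed at 1 mm) containing:

- a spherical thalamus (center (10, 16, 14) mm, radius 6 mm);
- per bundle, a ball-shaped cortical patch (radius 3 mm) well separated
  from the thalamus, and a quadratic Bezier centerline from the bundle's
  thalamic terminus to the patch center. The Bezier control point is offset
  perpendicular to the chord by 15% of its length, so every bundle is
  gently curved and the tracker's curvature handling is always exercised;
- an orientation field: voxels within a tube around each centerline store
  the local unit tangent; all other voxels store no direction and are
  non-propagating (isotropic). Where two tubes overlap, a voxel stores both
  directions (multi-fiber) and streamlines choose between them uniformly.
  Per-voxel angular dispersion is the bundle's `dispersion_deg` (elementwise
  maximum on overlap).

The tube narrows from `bundle_radius_mm` (default 2 mm) outside the
thalamus to a 1.2 mm "mouth" inside it. This models the convergence of a
thalamo-cortical projection onto its nucleus and is what makes the peak of
the connectivity map identifiable: with zero dispersion, transport is
deterministic and every connected seed voxel has probability exactly 1, so
the peak is a tie-set; the narrow mouth confines that tie-set to the
immediate neighbourhood of the bundle terminus, and the deterministic
lexicographic tie-break then lands within one voxel diagonal of the ground
truth. The default bundles run in the +x direction so the
lowest-index tie rule selects the terminus end of the tube.

Ground truth: each subject's `truth_peaks_mm` equals its bundles' thalamic
termini, before voxelization.

Cohorts displace each terminus by an i.i.d. per-axis Gaussian offset with
SD `peak_sd_mm`. Offsets that would leave the thalamus are resampled (up to
100 tries) rather than projected, preserving the Gaussian shape whenever
SD is small against the clearance to the boundary and keeping the
closed-form pairwise prediction E||X-Y|| = 4 sigma / sqrt(pi) valid; if
resampling saturates, the point is projected just inside the boundary and a
warning is logged. Optionally each subject's entire world geometry
(landmarks, thalamus, bundles, truth peaks) is moved by a random rigid
transform about the grid center (bounded rotation angle and translation),
recorded on the subject, so registration can be validated against a known
ground truth. One integer seed per public entry point drives all draws
through a single `numpy.random.Generator`.

The phantom deliberately omits: cortical folding, partial-volume and noise
in the orientation estimates, EPI distortion, any relation between the
grid and real stereotactic space. Passing the validation therefore shows
that the *pipeline machinery* (tracking, peak extraction, normalization,
statistics) recovers injected variability faithfully — not that the
specific millimetre numbers transfer to real diffusion data.

## Tracking model

At each step the tracker looks up the nearest voxel (no interpolation —
averaging antipodal fiber vectors is ill-defined), picks one stored
direction uniformly, flips its sign to keep the angle to the previous step
at most 90 degrees, and perturbs it by a Gaussian deviation on the tangent
plane: two tangent components drawn N(0, sigma) with sigma the voxel's
dispersion (degrees, converted to radians), applied as an exact rotation.
Stopping rules: leaving the brain mask or the grid, entering a
direction-free voxel, exceeding the per-step curvature limit (default 80
degrees), or exhausting `max_steps` (default 2000 per direction).

Streamlines are bidirectional: each sample is propagated along the
initially chosen orientation and again from the seed along its negation,
as seed-based probabilistic tractography conventionally does; one sample
counts once. Step size defaults to half the voxel size; seeds launch from
voxel centers without within-voxel jitter, which keeps the zero-dispersion
limit exactly deterministic and comparable voxel-for-voxel to an
exhaustive path-following oracle.

Counter semantics: per streamline and target, the counter at the seed
voxel increments at most once (first entry into the target mask), so
counts / n_samples is a probability estimate. Lesion-seeded tracking
instead counts, per brain voxel, the number of distinct streamlines that
entered it; with 5000 samples a 10% display threshold is the familiar
500-particle cutoff (5% gives 250).

## Parcellation and tie-breaks

Winner-take-all assigns each seed voxel the arg-max target over counts;
all-zero voxels stay unassigned. Thresholding keeps voxels at or above
`fraction x map-maximum` (inclusive, so the maximum always survives).
Peaks are reported at voxel centers in mm. All ties (arg-max: earlier
listed target; peak: lexicographically lowest voxel index) are resolved
deterministically and logged, since reproducibility requires a rule where
the underlying quantity is genuinely tied.

## Registration

The AC-PC frame is built by Gram–Schmidt: origin AC, axis 1 the unit
AC->PC vector, axis 2 the component of (IH - AC) orthogonal to axis 1
(IH is any midsagittal point off the AC-PC line, e.g. the corpus-callosum
apex), axis 3 their cross product. Subject-to-template normalization is
the closed-form frame-to-frame rotation plus the translation pinning AC —
not a least-squares fit, because AC fixity plus line and plane alignment
determine the 6-DOF transform exactly. No scaling is applied: a subject
with a shorter AC-PC line keeps its own length, its PC landing on the
template AC-PC line. Binary masks are carried into template space by
nearest-neighbour pull-back resampling.

## Statistics

Distances are Euclidean in template mm space. The cohort scatter statistic
is the mean over all C(n,2) pairwise peak distances; the attached SD is the
sample SD (n-1) over those pairwise values, and raw per-pair vectors are
always retained in the report so per-subject summaries can be re-derived
under any convention. Overlap is the Tanimoto coefficient (identical to
Jaccard) of the 10%-of-maximum binarized maps, computed for every subject
pair. Reference points (an atlas peak, a stereotactic target) are inputs,
not shipped constants; the stereotactic construction takes explicit
anterior-of-PC and lateral offsets (worked default 8 mm / 12.7 mm, with an
optional fractional-of-AC-PC-length mode) rather than hard-coding any
proportional rule.

## Problem sizes and tolerances

The validation suite runs cohorts of 9 subjects on 32-cubed grids with 200
samples per seed voxel for the scatter-recovery sweeps (sigma in
{0, 1, 2, 4} mm), 5000 samples for the display-cutoff check, and 200
subjects for closed-form checks; these sizes put Monte-Carlo error
comfortably inside the asserted tolerances (closed-form checks at n = 200
use a 10% band, about three standard errors of the pooled estimator).
Zero-dispersion tracking is compared exactly (voxel-for-voxel) against an
independent deterministic path follower. Rigid-recovery assertions use
1e-6 (inverse recovery), 1e-8 mm (isometry on probe clouds) and 1e-9 mm
(AC fixity). Pipeline scatter recovery is asserted within 20% of the
injected truth for sigma >= 1 and within one voxel diagonal for sigma = 0;
the residual error is dominated by voxel quantization of peaks (~0.3 mm
per axis) and the tie-set geometry of the bundle mouth (~1 mm, largely
common across subjects and hence cancelling in pairwise distances).

## Known limitations

- Probability maps over a deterministic (zero-dispersion) phantom are
  binary, so peak location leans on the documented tie rule; real data
  have graded peaks.
- The tracker is a transparent reference sampler, not a reimplementation
  of any production tractography package: no anatomical constraint masks,
  no within-voxel seed jitter, no orientation interpolation.
- Tanimoto overlaps on a 6 mm phantom "nucleus" are much more sensitive to
  millimetre scatter than overlaps of real, larger thalamic territories;
  their absolute values are not comparable across anatomies, only their
  monotone degradation with scatter is asserted.
- `landmark_discrepancy` is a QC surrogate for cross-modality registration
  checks; intensity-based volume registration is out of scope.
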