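# Methods

## Scope and input contract

`anglemech` operates on tissue-label rasters of a *single* anterior-chamber
angle (one side of the angle per image), encoded 0 = background, 1 = iris,
2 = sclera, 3 = ciliary body.  Segmentation itself is out of scope: any
image-to-mask function whose output passes `validate_mask` can be plugged
in.  Validation requires each tissue class to form exactly one connected
component after removing speckle below 50 px (8-connectivity) and the iris
to be 8-adjacent to the ciliary body; failures are enumerated in a report,
never silently repaired.

All coordinates are 0-based (row, col) with the origin at the top-left
pixel centre; subpixel positions are allowed everywhere.  Physical lengths
always go through the per-axis pixel pitch — the two acquisition geometries
have unequal pitches (half-frame: 9.52 x 9.16 um/px at 1024 x 655;
panorama: 15.14 x 14.50 um/px), so no scalar pitch is ever used.  The scan
ranges are fixed per mode; the pitch is derived from the actual raster, so
non-standard rasters degrade gracefully.

Orientation is normalized before measurement so the angle recess lies in
the left half; the recess side is taken from the centroid of the iris-root
zone (iris pixels adjacent to the ciliary body).  The `flipped` flag keeps
the mirroring reversible, and applying normalization twice is the identity.

## Scleral-spur localization

Label masks carry no grayscale spur landmark, so the spur is recovered
geometrically: candidate points are subpixel sclera-boundary vertices
within 2 px of the ciliary body (the sclerociliary interface), and the spur
is the candidate minimizing physical distance to the iris — anatomically,
the inner end of the ciliary attachment at the angle recess.  Ties break by
smaller row, then smaller column, making the result deterministic.  A
quality score `1 - d_iris/500 um` (clipped to [0, 1]) flags implausible
geometries.  The method tag on `SpurPoint` records the heuristic so a
learning-based detector can be swapped in without touching downstream code.

## Feature definitions

**Circle-thickness (TPI) features.**  A physical circle (500 or 750 um) is
intersected with the subpixel iris contour (marching squares at the 0.5
iso-level; each contour segment is solved exactly as a quadratic).
Crossings are ordered by angle about the centre; among consecutive pairs
whose enclosed arc midpoint lies inside the iris, the pair nearest a
reference point is selected and the physical chord between its crossings is
the local thickness.  Chordal distance (not along-circle arc) is used.  Two
numerical guards matter:

* pairs enclosing less than 10 degrees of arc are tangential grazes, not
  transversal thickness samples, and are dropped when alternatives exist;
* the reference point is the iris root for spur-centred circles and the
  spur for the root-centred circle (the spur itself gives no direction for
  a circle centred on it).

A circle that misses the iris yields a NaN marker; the feature row is still
emitted and classifiers impute the marker from training medians.

**PB features.**  The posterior iris surface is the per-column deepest iris
pixel (the iris of a single-angle image is band-like, i.e. x-monotone after
normalization).  Curvature is the extremal signed perpendicular physical
distance from this surface to its root-to-pupil chord, positive toward the
cornea (anterior bowing) — for an S-shaped surface the larger-magnitude
extremum wins.  Root insertion is the spur-to-root physical distance, the
root being the centroid of the iris-ciliary insertion zone.

**ALCB features.**  The anterior ciliary surface is the maximal connected
arc of the ciliary-body contour whose vertices face anteriorly (outward
normal within 75 degrees of image-up, after cyclic smoothing of the contour
over 9 vertices so marching-squares staircase steps do not dominate) and
either have the iris as nearest non-ciliary tissue within 500 um or nothing
but background above them in their column.  Staircase interruptions up to
4 vertices are bridged by cyclic morphological closing.  The
anterior-facing requirement is essential: without it the steep terminal
edge of the ciliary wedge would inflate the surface length and make a
fully apposed ciliary body score a contact ratio near 0.7 instead of ~1.
Contact is where the surface lies within 2 px of the iris (~19 um at
half-frame pitch — sub-resolution apposition cannot be resolved); arc
lengths are computed on the physically scaled polyline.

**Iris centerline.**  The morphological skeleton of the iris, pruned and
completed: terminal branches shorter than the local half-width are deleted
(the skeleton of a band grows 45-degree branches into its end corners), the
path ends are trimmed where the half-width profile collapses faster than
0.25 px/px over a 5-px window (the signature of a medial-axis corner dive,
while a clinical thickness taper changes an order of magnitude slower), and
the result is extended along its end tangents to the iris boundary.  The
centerline supports curvature diagnostics; the production PB feature uses
the posterior surface directly.

## Classifiers and integration

Each mechanism is a binary problem over the eight-feature row.  Every
model is a pipeline fitted on training rows only: median imputation of NaN
markers, per-feature standardization, then one of five families with
hyperparameters pinned in `data/hyperparams.yaml` (library defaults, except
tree counts raised to 200 and LR iterations to 1000 for convergence; the
SVM's probabilities come from sigmoid calibration with at most 3 folds,
bounded by the rarer class count so tiny cohorts stay trainable).  The
decision threshold is 0.5 with the >= convention, recorded on the model for
adjustability.  Splits are patient-grouped (test fraction 0.25): images of
one patient never straddle the boundary.  Selection ranks candidates by
MCC, then F1, accuracy, sensitivity, and finally the fixed order
RF < GBDT < XGB < SVM < LR — the four listed criteria made total and
deterministic; undefined metrics rank below any defined value.  Whether
selection uses the internal test set or a separate validation fold is the
caller's choice; the pipeline's default selects on the internal held-out
set.

The integrated class is a total function on the boolean cube: PB alone is
pure PB; TPI and/or ALCB without PB is pure non-PB; PB with either non-PB
mechanism is multiple mechanisms; none is "others".

## Evaluation statistics

Accuracy, sensitivity, specificity, PPV, NPV, F1 and MCC are computed from
the 2x2 confusion table with zero denominators flagged as NaN rather than
coerced to 0 (a silent zero could distort model selection).  Rate metrics
carry Wilson-score 95% intervals — the method is not dictated by the
problem, but Wilson behaves well near 1 where these models operate, and the
method name is recorded in every report.  AUC uses the rank (Mann-Whitney)
formulation with half-credit for ties.  Accuracy comparison between two
readers uses the Pearson chi-square statistic on the 2x2 correct/incorrect
table without continuity correction (Yates' correction behind a flag).
Cohen's kappa uses marginal-product expected agreement.  All formulas are
authored here and cross-checked in the test suite against independent
implementations (scikit-learn, statsmodels, scipy) and brute-force
enumeration to 1e-12.

## Synthetic anterior segment

The renderer lays out one angle in physical micrometres (canonical
orientation: recess left): a corneoscleral shell whose inner surface runs
parallel to the iris across a 120-um recess gap, then dives behind the
iris root at slope 2.5 where the ciliary body attaches beneath it; an iris
band from root to pupil whose posterior surface is a circular arc with
signed sagitta `s` and whose thickness varies linearly from root to pupil
(vertical offset); and a ciliary wedge whose upper edge follows the
posterior iris for 1.5 mm, touching it for `contact_fraction x 1.5 mm` and
then opening to a 300-um gap along a quadratic ease-out ramp (fast initial
opening makes the contact zone end crisply; the gap stays below 500 um so
the whole tracked edge remains part of the anterior surface).

Defaults (root thickness 480 um, pupil thickness 360 um, sagitta 150 um,
iris length 4.5 mm, contact fraction 0.3, jitter 0.5 px) describe a
mid-range narrow angle on the standard 1024 x 655 half-frame raster;
panorama rendering uses the same micrometre layout at the coarser pitch.

Ground truth is computed on the *continuous* boundary curves, independently
of rasterization: circle-boundary intersections via shapely on the
micrometre-space iris polygon with the same pair-selection rule as the
measurement; the spur as the analytic arg-min of iris distance along the
sclerociliary interface; the root as the arc-length centroid of the
continuous insertion zone (mirroring the measured pixel-centroid
definition — a fixed corner point would diverge from it when the contact
zone is long); contact and anterior lengths from the gap profile.  Smooth
low-frequency jitter is added to the boundary curves *before* both
ground-truth evaluation and rasterization, so truth stays analytic under
noise and the measure-after-render loop compares two genuinely different
code paths.

Mechanism labels follow fixed generator conventions chosen to produce
separable classes: PB iff sagitta > 200 um, TPI iff analytic IT750 >
500 um, ALCB iff contact fraction > 0.4.  These are *generator*
conventions, not clinical cut-offs — no accepted quantitative criteria
exist for these mechanisms.  Cohort sampling draws class-conditional
parameters with margins around those thresholds (re-drawing, seeded and
bounded, when a label lands outside the intended combination), allocates
class counts by largest remainder, and groups at most four consecutive
shuffled images per synthetic patient, emulating per-quadrant acquisition.

**What passing tests do and do not show.**  The phantom reproduces the
geometry the features measure, but not UBM speckle, segmentation errors
beyond smooth boundary jitter, plateau-iris configurations, closed
(iridotrabecular-contact) angles, or inter-patient anatomical correlation;
synthetic classes are separable by construction, so the benchmark
accuracies (>= 0.95 per mechanism, >= 0.90 integrated on the 400-image
cohort) validate the pipeline's internal consistency, not clinical
performance.

## Problem sizes and runtime

The test suite uses a 100-mask recovery grid (root thickness 300-600 um,
sagitta -100-400 um, contact 0-1) and a 400-image benchmark cohort —
roughly one-ninth of the clinical study scale, chosen so the full suite
runs in about six minutes on one core; rendering plus feature extraction
costs ~0.5 s per image.  Recovery on the grid: median thickness error well
under two pixel pitches, contact ratio within 0.01, curvature within ~2%
relative, spur within 10 px on 100% of masks.  A handful of grid-corner
configurations (sagitta 400 um with a strongly bowed iris) admit two
transversal circle samples whose reference distances nearly tie; the
selection can then differ between the raster and continuous code paths,
which is why recovery criteria are stated on medians.

## Known limitations

* The spur heuristic and the insertion metric are geometric surrogates;
  their upstream definitions in the segmentation literature are not
  reproducible from label masks alone.  Both are tagged in provenance so
  alternatives can be substituted.
* Per-patient aggregation across quadrant images is out of scope; every
  assessment is per image.
* The posterior-surface extractor assumes a band-like (x-monotone) iris,
  which holds for single-angle images but not for full-frame acquisitions.
* Chordal circle thickness slightly exceeds perpendicular thickness when a
  circle crosses the iris obliquely; measurements and ground truth share
  the definition, so recovery is unaffected, but absolute values should be
  compared only against measurements using the same convention.
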