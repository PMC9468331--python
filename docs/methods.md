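# Methods

This note documents the models, conventions and design choices behind
`curvimetry`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not demonstrate.

## The measurement model

Penile curvature is treated as *uniplanar hinging curvature*: the shaft
consists of a proximal and a distal limb, each approximately a straight
cylinder, meeting at a hinge. The curvature angle is the angle between
the two limb mid-axes, expressed as deviation from straight (0° =
straight, 90° = right-angle bend). In a 2-D photograph taken roughly
perpendicular to the curvature plane, each limb projects to a band with
two parallel straight edges; any edge of a limb is parallel to that
limb's axis, so the angle between one edge line per limb equals the
angle between the axes. The estimator therefore reduces the problem to
finding one reliable straight edge per limb and applying the two-line
angle formula

θ = arctan |(m₁ − m₂)/(1 + m₁m₂)|,

with the vertical-line branch θ = arctan(1/|mᵢ|) when one slope is
infinite, both verticals giving 0° and 1 + m₁m₂ = 0 giving 90°. Slopes
are Cartesian (y up); image rows are negated when converting Hough
(ρ, θ) parameters, so a stored line satisfies x·cosθ + y·sinθ = ρ with
slope m = −cosθ/sinθ and θ ∈ [0, π). Reported angles live in [0°, 90°]:
the absolute value in the formula cannot distinguish reflex bends, and
the modeled range of the phantoms is 18°–88°.

Out of scope by design: multiplanar (3-D) curvature, penile torsion,
and the training of the deep localization/segmentation networks (their
published training hyperparameters are recorded verbatim in
`TrainConfig` as configuration only).

## Synthetic phantoms

The generator stands in for photo sessions of nine 3D-printed models
with known curvature (18°–88°). One phantom is parameterized by
`PhantomSpec`:

| parameter | default | meaning |
|---|---|---|
| `curvature_angle_deg` | — | ground-truth angle between limb axes, [0, 90] |
| `shaft_width_px` | 60 | 1.5 cm at the 40 px/cm pixel scale |
| `proximal/distal_limb_len_px` | 110 each | ~5.5 cm total length (models are 5–6 cm) |
| `bend_radius_px` | 6 | fillet of the outer bend ("radial curvature" of the smoothed models) |
| `horizontal_tilt_deg` | 0 | camera pan, capture range −5°..5° |
| `vertical_tilt_deg` | 0 | camera elevation, capture range 0°..20° |
| `image_size_px` | 640×640 | frame size; shape must fit with ≥ 5 px margin |
| `boundary_noise_sigma_px` | 0 | segmentation-raggedness amplitude |
| `background_style` | flat | flat gray or low-frequency textured background |
| `rng_seed` | 0 | bit-exact reproducibility |

Construction order is: planar shape, then perspective, then noise.

1. **Shape.** Each limb is a capsule (segment dilated by width/2,
   round caps); the two capsules share the hinge endpoint with axes
   separated by the curvature angle. The union's outer bend is an arc
   of radius width/2 around the hinge by construction; a morphological
   opening with a disk of `bend_radius_px` additionally fillets any
   sharp convexity. The concave inner junction stays sharp, as in a
   hinged model. Ground truth is exact by construction.
2. **Perspective.** A pinhole camera at 22.5 cm working distance
   (midpoint of the 20–25 cm capture protocol; 900 px at the 40 px/cm
   scale) rotated about the object center by the two tilts induces a
   plane homography; focal length equals the distance so zero tilt is
   the exact identity. The mask is warped bilinearly and re-binarized
   at 0.5. Vertical tilt foreshortens the projection and biases the
   apparent angle — the basis of the tilt-sensitivity experiment.
3. **Boundary noise.** The 0.5-level contour is displaced along its
   normals by white noise smoothed along the contour (correlation
   ~3 samples) and rescaled to σ px, then re-rasterized as a polygon.
   This emulates the locally correlated raggedness of an imperfect
   segmentation while keeping the region simply connected.

The image rendering is deliberately minimal (dark shaft ~60 gray on
light ~200 background, optionally textured): enough contrast structure
for an intensity-based segmenter, no attempt at photo-realism, skin
texture or lighting. Consequences for interpretation: passing tests
shows the *geometry* pipeline recovers angles under projection and
boundary noise; it says nothing about how a trained segmentation
network behaves on real photographs — that stage enters only through
its output mask, whose imperfections the noise model approximates
crudely.

The evaluation panel (`generate_paper_panel`) draws, per sample, both
tilts uniformly from their capture ranges and a child seed from a
master generator, so a panel is one integer seed away from exact
reproduction.

## Mask post-processing

Flood-fill hole closure (background regions not 4-connected to the
border become foreground), a 2×2 median filter, a 3×3 Gaussian with
variance 0.25, re-binarization, and largest-8-connected-component
selection. Conventions the kernel sizes leave open are fixed once:

* the even 2×2 median window is anchored at its top-left pixel and the
  2–2 boolean tie resolves to background, i.e. output = (≥3 of 4 true);
  the number of median passes is a parameter (default 1);
* the Gaussian is the continuous kernel with σ = 0.5 sampled on the
  3×3 grid and normalized to sum 1; re-binarization threshold 0.5;
* both filters use reflect padding, so the all-true mask is a fixed
  point and solid interiors are unchanged;
* holes use 4-connectivity, components 8-connectivity (the standard
  complementary pair, avoiding topological paradoxes).

When post-processing leaves several components, the largest is kept —
a deterministic stand-in for however a clinician would discard stray
fragments; it is a declared convention, not a claim about the best
rule.

## Angle estimator

1. **Corners.** Shi–Tomasi cornerness (minimum structure-tensor
   eigenvalue, Gaussian window σ = 1) on the binary field, restricted
   to a 2-px band around the contour. Raw cornerness alone cannot
   identify the four landmarks: on rasterized masks, 1-px boundary
   raggedness scores *higher* than a rounded cap, and a large disc
   still produces aliasing maxima. Two geometric gates fix this:
   a maximum is admissible only where the contour's local turn (secant
   direction change across an arc of 0.3 shaft widths) exceeds 1.6×
   the contour's average turn over the same arc — a disc turns at a
   uniform rate, so none of its maxima qualify at any radius — and
   admissible maxima are ranked by turn, not by raw response, then
   thinned to a mutual spacing of 0.75 shaft widths so one cap cannot
   contribute two corners. Fewer than four admissible maxima raises a
   degenerate-shape error (disc, near-straight capsule).
2. **Lines.** The Hough transform (1 px × 1° accumulator) runs on the
   inner contour of the mask; peaks above 0.3 × the limb-length
   estimate (half the contour's principal-axis extent) become
   candidates, each refined by a total-least-squares fit to its
   supporting contour pixels (within 2.5 px), which removes the
   accumulator quantization — necessary for sub-degree accuracy and
   for rotation/scale equivariance. Each candidate carries its support
   pixels and their outward normals (from the smoothed mask gradient).
3. **Selection.** The canonical pose (limbs left-right, bend opening
   downward) is derived from the principal axis of the pooled,
   deduplicated support pixels, with the apex side read off the pooled
   mid-axis profile. In this pose the two limb axes sit at ±φ/2 about
   the x-axis, so the *sign* of a candidate's canonical slope
   identifies its limb; candidates within 2° of axis-parallel are
   unassignable. Within the left limb the concave ("inner bottom")
   edge is preferred and within the right limb the convex ("outer
   upper") edge, but only among lines whose votes reach 0.8× the
   limb's best — a weak spurious edge must not displace a strong one —
   and a limb whose best line falls below 0.3× the global best is
   treated as empty. Ties break by votes, then supported span, then
   smaller |ρ|.
4. **Fallbacks** (all deterministic, all flagged in the diagnostics):
   if no corner landmarks exist (near-straight shaft) or corner-guided
   selection fails even after relaxing the Hough threshold to 0.15×,
   candidates are split into their two angular slope families at the
   two largest circular gaps and the strongest line of each family is
   used; a family split narrower than 5° means a straight shaft, for
   which the two strongest (parallel) edges are returned and the angle
   is ≈ 0. If only one slope family survives the default threshold on
   a shape that does have corners, detection is retried at the relaxed
   threshold (one limb's edges can fall below the vote threshold under
   noise).

Design history worth recording: an earlier variant assigned candidates
to limbs by which side of the hinge their support lay. Hinge
localization under boundary noise was the single largest error source
(occasional same-limb pairs reporting ~0°); the slope-sign rule removed
every such failure on 900 panel samples while leaving clean-mask
behavior unchanged. A variant that pinned the hinge at the intersection
of the two slope families was evaluated and rejected — it *increased*
gross failures, because the family split is least reliable exactly when
the hinge is in doubt.

Accuracy at the extremes: the estimator is validated against the
independent limb-axis oracle over 10°–80° (agreement ≤ 3°) and at the
straight case (< 2°); behavior between 0° and ~5° degrades gracefully
through the parallel-edge fallback rather than being specified.

## Evaluation metrics

DSC, IoU and pixel accuracy come from per-pixel confusion counts
(undefined — an error — when both masks are empty). BCE uses natural
log with probabilities clipped to [10⁻⁷, 1−10⁻⁷]. Detection AP sorts
detections by confidence, matches each greedily to the unmatched
ground-truth box of highest IoU ≥ 0.5 (the detector family's
convention; the threshold is a parameter), and integrates the
all-points-interpolated precision envelope over recall; with one class,
mAP equals (mean per-image) AP. The angle report groups estimates by
ground-truth angle (mean ± std, per-group MAE, n) with an overall row
whose MAE pools all samples — not the mean of group MAEs, which differs
for unbalanced groups. The 1.96·√(ψ(1−ψ)/N) interval applies to
proportion-type metrics only; MAE, being unbounded, gets a t-interval
over per-sample absolute errors instead.

## Harness

The pipeline runner crops to the highest-confidence detection box
expanded by 5% of its longer side (protecting the Hough stage from
clipped edges), binarizes the segmenter's probability map at 0.5, and
tags any failure with its stage. The threshold segmenter estimates the
background level from the modal intensity of the crop's border frame —
inside a tight crop the shaft can outnumber the background, so a global
mode would latch onto the object. Cross-validation uses the stricter
held-out-model rule (all images of a physical model stay on one side of
every train/test split), with a seeded 20% validation draw from the
train side; image-level splitting would leak near-duplicate views of
the same model. Augmentation is rigid only (translation ≤ 10% of the
side, rotation ±15°, flips), so the ground-truth angle is invariant;
the op magnitudes are declared here, as only the op types are fixed by
the reference protocol.

## Validation protocol and problem sizes

The angle-recovery benchmark generates 20 phantoms at each of the nine
model angles {18, 33, 40, 50, 58, 60, 75, 86, 88}°, tilts uniform over
the capture ranges, boundary noise σ = 1 px, and requires the overall
MAE of the chain to stay within the 8.53° figure reported for the
physical-model study (the script in `scripts/acceptance.py` also
reports the worst per-angle MAE against that study's 9.87° maximum).
The test suite runs the same protocol at 60 phantoms per angle: the
tilt-sensitivity comparison (per-bin MAE over vertical-tilt bins <7°,
7–15°, 15–20° must be non-decreasing) probes a sub-degree effect
between the two lowest bins, and the larger panel gives that comparison
adequate statistical resolution while making every bound strictly
harder to meet. Typical results are far inside the bounds (overall MAE
≈ 1.1–1.4° across seeds); the margin reflects that synthetic masks
lack real-photo segmentation pathologies, so the synthetic bound is a
necessary, not sufficient, check.

## Known limitations

* The phantom emulates geometry, not photometry: no lighting, skin
  texture, occlusion, or segmentation-network failure modes beyond
  boundary raggedness and punched holes.
* The physical-to-pixel scale of the original photographs is not
  published; 40 px/cm is a declared default, and all estimator
  thresholds are tied to the shaft-width/limb-length estimates to stay
  resolution-independent (verified by the 2× scale-invariance test).
* Wide-angle outer-bend vertices (interior angle ≳ 135°) are blunted by
  rasterization and may rank below cap maxima in the corner set; the
  selection stage does not depend on which four landmarks are returned,
  only on the pose they imply.
* Eq-style per-model measurement means of the physical study depend on
  the authors' photographs and are not reproducible from synthetic
  data; only the error bounds and qualitative trends are checked.
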