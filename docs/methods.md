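# Methods

This note documents the models, conventions and design choices behind
`gridsight`, in the spirit of a methods appendix: what is simulated, what
is estimated, which knobs matter, and what the synthetic results do and do
not show about real data.

## Coordinate and pixel conventions

* Pixels are 0-based with `(0, 0)` at the **center** of the top-left
  pixel; +x right, +y down. Bounding boxes are `(x_min, y_min, w, h)`,
  half-open. These conventions are used for images, labels and all
  bookkeeping, so label round-trips are exact.
* The world frame is the left rectified camera frame (right-handed, +z
  forward). The relative-pose protocol never needs an absolute frame.
* Lengths are meters; image quantities are pixels.

## Camera model

Pinhole intrinsics `(fx, fy, cx, cy)` with radial `(k1, k2, k3)` +
tangential `(p1, p2)` distortion applied in normalized coordinates — the
dominant convention for these lenses. Undistortion inverts the polynomial
by fixed-point iteration (20 iterations / 1e-10 convergence; round-trip
error < 1e-3 px for |k1| ≤ 0.3). Rectification rotates both views onto a
common plane whose x-axis is the baseline (Fusiello-style); images are
remapped by bilinear sampling and the identical mapping is applied to
labels, so a rig that is already an ideal rectified pair passes images
through untouched. Triangulation uses the rectified closed form
`z = f·b/(x_L − x_R)`, with the row coordinate averaged over views;
non-positive disparity is a degenerate-geometry error.

**Default virtual rig.** The headset's grayscale cameras are 640×480 but
their calibration is not public, so the package ships a virtual rig:
fronto-parallel, baseline 0.098 m, zero distortion, `f = 550 px`. The
focal length is the one genuinely free parameter and was chosen from two
printed facts about the real setup: a 32 cm-wide working area "just fits"
the view at 40 cm (stereo overlap at 40 cm is `2·z·(W/2)/f − b` = 36.7 cm
⊃ 32 cm + grid, with nothing to spare), and grid crops then span 54 px at
40 cm to 24 px at 90 cm — the 22–60 px operating band of the real
detector. Distortion-on and ideal-pinhole modes are both exposed; the
experiment default is the ideal mode (no resampling loss), with the
distorted path exercised by its own tests.

## Grid geometry and deformation

`GridSpec` defaults: 8×8 electrodes, 5 mm pitch, 4 mm disks, 4 tails.
Electrode 1 sits at the grid-frame origin, numbering is row-major, and
the tails attach one disk diameter beyond the last row, one pitch apart
and centered — one keypoint per cable. Any fixed convention works if used
consistently; this one is documented in the README with a diagram.

The deformation model emulates a silicone sheet draped on a curved
surface: a cylindrical bend (axis angle + signed curvature, an exact
isometry by arc-length construction) plus a random smooth height field
(2D polynomial of degree ≤ 3, amplitude-normalized), whose first-order
in-plane stretch is removed by iterative rescaling. Parameters are
validated against a ±2 % nearest-neighbor-distance bound (112 lattice
edges) — the sheet bends but does not stretch. Curvature is capped at
25 m⁻¹ (radius ≥ 4 cm, about the tightest a brain surface would impose).
Deformations are deterministic given a seed.

## Renderer

The renderer produces the *appearance class* that matters to the method —
a pale sheet, brighter metallic disks, four thin cables, low resolution —
not photorealism. Projected disk centers, the sheet silhouette (convex
hull of projected electrodes, buffered by the projected margin) and cable
segments are rasterized at 4× supersampling and box-filtered down;
intensity is ambient + Lambertian shading from one directional light;
Gaussian blur and additive Gaussian noise follow. Background modes: flat,
gradient, textured noise. Keypoint labels are exact projections;
a noiseless render's disk centroids agree with the labels to < 0.3 px.

Default intensities (sheet 0.50, disks 0.85, background 0.05–0.25,
ambient 0.7, blur σ 0.6 px, noise σ 0.01) were set once to give the
contrast ordering of the real grayscale frames. Cables are drawn at sheet
intensity with width 0.7× the disk radius; at 90 cm they are ≈1 px wide
before blur, which is why the classical pose path increasingly fails to
find tails beyond 70 cm (see Limitations).

**Downscaling** uses exact area averaging (interval-overlap weight
matrices) with floor rounding, and labels scale by the *realized* ratio
(80 px at scale 0.33 → 26 px, labels × 26/80). **Upscaling** is
corner-anchored (output pixel *i* samples input *i/f*), so the
crop-to-full-frame bookkeeping `x_full = x_up/f + offset` is exact with
no half-pixel bias; since the same convention is used in both views, any
residual bias would cancel in the disparity anyway.

**Corpus factory.** Base renders are square, side uniform in [80, 260] px,
grid tilted up to 0.7 rad with random roll, random deformation and
appearance; each base is written at scales {1, 0.75, 0.5, 0.33} (so a
corpus holds exactly `n_base × n_scales` image/label pairs, the smallest
26 px). Labels use the normalized single-stage-detector keypoint format
(class, bbox center/size, 68 × (x, y, visibility)), so generated corpora
can train third-party detectors without conversion.

## Detection and cropping

The classical detector thresholds sheet-vs-background contrast (Otsu by
default), applies a small morphological closing — without it, a dimly lit
sheet grazes the threshold and the mask shatters into stripes between
disk columns, truncating the box — then filters connected components by
area and aspect ratio, scoring by interior/exterior contrast. Detections
are sorted by score then area (deterministic ties); non-maximum
suppression is available but off by default. Crops pad the box by 10 % of
its larger side (min 2 px) with exact integer bookkeeping. The stereo
acceptance rule admits a frame pair only when each view has exactly one
detection, reporting the first failing side otherwise.

## 2D pose: candidates and index assignment

Disk candidates are bright Laplacian-of-Gaussian extrema found in two
passes: a coarse scale sweep (σ 2–12) estimates the dominant disk scale
from the strongest responses, then a narrow sweep around it detects every
disk. The two-pass design is load-bearing: in a single wide sweep,
large-scale blobs at the sheet corners swallow the corner disks through
overlap pruning. Centers are refined to subpixel by local intensity
centroid (~0.2 px in the upscaled frame at 40 cm, i.e. ~0.05 px
full-frame). Tail candidates are thin protrusions of the thresholded
sheet silhouette: a disk-structured opening (via two distance transforms)
removes cables from the mask, and residual components that reach far
enough beyond the body — with a relaxed criterion for components clipped
by the crop border — contribute their outermost point. The sheet mask
thresholds between the border background level and the crop median (the
sheet level), not Otsu, because inside a crop Otsu separates disks from
sheet instead of sheet from background.

Assignment fits a projective map from the canonical grid plane to the
crop: hypothesis seeds come from the minimum rotated rectangle of the
strongest `n_electrodes` candidates (all corner orders) plus randomly
sampled quadruples under a fixed budget and seed; each is scored by
inlier count at max(2 px, 0.25 pitch); the best is refined by iterated
least-squares DLT on gated one-to-one matches. Two symmetry facts shape
the logic:

* **Mirror exclusion.** Since the camera always sees the sheet's front
  face, the plane-to-image map has a fixed orientation sign
  (orientation-reversing under our conventions). Mirror hypotheses fit
  the lattice — and, because the default tails are symmetric about the
  center column, the tail set — exactly as well, but would silently
  transpose the numbering; they are rejected by the sign of the fit's
  Jacobian.
* **Rotation disambiguation.** All rotational relabelings (4 for square
  grids, 2 for rectangular) are scored by the distance from observed tail
  candidates to the predicted tail keypoints; no tail evidence means the
  orientation is undecidable and the stage raises an ambiguity error
  rather than guessing.

Electrode keypoints are the matched candidates themselves (Hungarian
assignment, minimum total distance, gate 0.45 pitch); unmatched
electrodes are marked invisible at their predicted positions. A final
quality gate refuses the frame when fewer than half the electrodes are
explained — a mis-registration (from missing or merged blobs) must become
a counted rejection, not a wrongly numbered measurement. Tail keypoints
are homography predictions (the observed endpoints lie farther out along
the cables), flagged visible when corroborated by a nearby candidate.

## Evaluation harness

`run_experiment` renders every scene/frame, runs the configured pipeline,
applies the acceptance rule and the 10 cm median filter (per position —
the grid is static at each position; centers are the mean of valid
triangulated points; strictly-greater-than rejects), then computes
relative-pose errors against the reference position. The reference
estimate is the per-electrode mean over that position's kept frames;
per-frame errors elsewhere are computed against it (frames are not paired
across positions). The reference's self-error is zero by definition.
Per-position σ is reported both across frames and across electrodes; the
false-positive rate counts only median-filter rejections over accepted
frames (pipeline-stage refusals are tallied separately), per depth band.
All counts satisfy considered = accepted + rejected and accepted = kept +
outliers + stage failures. The per-electrode heatmap sums each
electrode's mean error over non-reference positions and normalizes by the
worst electrode.

**Problem sizes.** The default experiment is 30 positions × 30 frames ×
1 run (the acceptance script's configuration; a few minutes on one CPU).
The depth-monotonicity and noise-propagation properties are verified with
direct pixel-noise Monte Carlo through the triangulation and error
formulas (many seeds are cheap there), not by repeating the full rendered
experiment per seed. The first-order check `Δz ≈ z²·σ_d/(f·b)` agrees
with simulation within 25 %.

## Randomness and reproducibility

Every random draw flows from one integer seed through named SHA-256
substreams (`derive_seed(seed, stage, indices...)`), so runs are exactly
reproducible and adding frames or stages never perturbs other draws.
Derived seeds stay below 2³¹.

## What the synthetic results show — and what they do not

The synthetic replication exercises the paper-shaped *logic*: rectified
stereo geometry, the 22–60 px crop regime, keypoint indexing under
rotational symmetry, tail disambiguation, outlier filtering and the
relative-pose statistic. Because the renderer's disks are clean
anti-aliased circles and the classical pose path achieves ~0.05 px
full-frame centroid accuracy, the absolute error levels (≈0.05 mm
relative error at 40 cm) are roughly an order of magnitude below what
trained networks achieve on real frames; the *shape* of the results
(monotone error growth with depth, instability beyond 70 cm, zero
outliers at ≤ 60 cm) matches the real system's behavior. Passing these
tests validates the pipeline's geometry and logic, not real-image
robustness: specularities, shadows, partial occlusion by the skull, HMD
motion and true lens calibration are all outside the renderer's scope.

## Known limitations

* Tail visibility at ≥ 80 cm is marginal (cables ≈ 1 px wide), so the
  classical pose path refuses 30–60 % of far frames; a learned pose model
  plugged into the same contract would not share this failure mode.
* The deformation model is geometric (bend + smooth field), not
  biomechanical; it bounds stretch but does not model tissue contact.
* Occlusion is not modeled: visibility flags reflect frustum/bounds truth
  only.
* The classical detector assumes the grid is the dominant bright
  component; cluttered backgrounds need the external-detector hook.
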