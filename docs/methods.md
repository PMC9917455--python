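# Methods

This note documents the models behind `mcamtools`: what is simulated, what
each pipeline stage assumes, which parameters matter, and what the passing
test suite does and does not demonstrate about real recordings.

## Optical model

Every micro-camera is a thin lens of focal length `f` (default 25 mm,
NA 0.03) at working distance `u` from the object plane, with linear
magnification `m = f/(u − f)`. A world point `p` seen by the camera whose
optical axis crosses the object plane at `c` projects to sensor coordinate
`−m(u′)·(p − c)` about the image center, where `u′` is the point's own
object distance; the sign encodes the real-image inversion, which the
stitcher undoes by rotating raw frames 180°. Perspective parallax *within*
one camera is neglected (the local model is telecentric-like, exact on
axis); parallax enters only *between* cameras through the baseline. This is
deliberately the same approximation the depth estimator inverts, so the
simulator and the analysis agree to machine precision on geometry, and the
residual error measured in tests comes from image formation and matching,
not from model mismatch.

Derived quantities:

* per-camera object-space FOV = sensor size / m; array span =
  `(n−1)·pitch + FOV` per axis;
* overlap fraction per axis = `(FOV − pitch)/FOV`, which may be negative
  (a coverage gap) and is reported as such — with the default 19 mm pitch
  and `u = 150 mm` the long axis overlaps 37 % and the short axis has a
  ~12 % gap, so the bundled `mcam96` preset uses `u = 165 mm`, where both
  axes overlap (43 % / 0.4 %) and every point is covered;
* axial Rayleigh depth of field `λ/(2·NA²)` with the default mid-visible
  λ = 0.50 µm, giving 0.278 mm at NA 0.03; lateral Rayleigh `0.61·λ/NA`;
* binocular disparity between adjacent parallel-axis cameras
  `s = m(u)·B`, inverted as `u = f(1 + B/s)`; near `u = 150 mm` one 1.4 µm
  pixel of disparity corresponds to ≈ 46 µm of depth.

## Scene simulator

`SceneSpec` describes a world rectangle centered on the array: a background
(level, band-limited texture, high-contrast calibration features), a global
illumination gain, and organisms with full 3-D poses. Organisms are drawn
procedurally in their local frame:

* **fish** — an articulated spine (per-joint bend angles, head at +x) with a
  tapered half-width profile, two dark elliptical eyes whose major-axis
  orientations are the ground-truth eye angles, and a fixed per-identity
  speckle field emulating the idiosyncratic melanophore pigmentation that
  makes individuals distinguishable. The speckle is anchored to the body
  frame, so the same individual shows the same pattern in every camera and
  frame. Fish blotches are coarse (scale 0.28 × body width) so they survive
  small identity crops; beads and worms carry fine speckle
  (0.12 × width) to provide dense corner features for stereo matching.
* **worm** — a thin undulating capsule; **blob** — a uniform dark ellipse;
  **point_bead** — a speckled disc used as depth/registration target.

Image formation: background sampled from a fixed-resolution world raster
(deterministic per seed, hence consistent across cameras), organisms
composited with per-object magnification `m(u0 − z)`, defocus as a Gaussian
blur of object-space sigma `0.5·|z|·NA` (a linear small-defocus model;
coefficient configurable), cos⁴ vignetting in field angle (with a
`vignetting_scale` knob because desk-scale sensors subtend tiny field
angles), optional RGGB sampling, Poisson shot noise at a full-scale photon
count of 30 000 plus 1 DN read noise, and 8/16-bit quantization. With these
defaults a bright field has ≈ 1 % pixel noise, consistent with a
well-exposed CMOS sensor after the gains of this class of instrument. All
randomness derives from one integer seed; equal seeds give bit-identical
framesets.

The cohort model (`simulate_session`) moves organisms by a heading
diffusion (0.8 rad/√s) with gamma-distributed speeds (mean 5 mm/s, CV 0.35
— larval-zebrafish-like at 1 Hz sampling), reflecting walls, an optional
±2.5 mm z random walk, an Ornstein–Uhlenbeck tail-bend process, and an
optional minimum-separation constraint enforced by symmetric pair
repulsion. Identities persist across frames.

**What the simulator does not emulate:** photorealistic appearance,
occlusion shadows, water-surface refraction, illumination drift,
rolling-shutter timing, lens distortion or aberrations beyond defocus blur.
Tests passing on these scenes validate the *algorithms and their geometry*,
not robustness to every artifact of real video.

## Pipeline stages

**Flat-field correction.** Per camera, the pixelwise mean of five simulated
out-of-focus diffuser images is normalized to unit mean and used as a
division-only gain map (no dark-frame term; a hook exists). Near-zero pixels
are floored at 10⁻³ of the camera mean and counted as dead. The reference
is invariant to global brightness rescaling, and self-correction flattens a
cos⁴ vignette to the sensor noise floor (block-mean residual ≤ 2 %).

**Stitching.** Calibration uses a feature-rich target scene. All
rook-adjacent pairs are registered by phase correlation on the predicted
overlap crops — Tukey (α = 0.4) tapering, cross-power spectrum whitened
with a 3 % magnitude floor (pure phase normalization lets noise-dominated
frequencies swamp band-limited scenes), wrap-aware peak search within
±30 px, 3-point quadratic sub-pixel refinement, confidence = ratio of
first to second correlation peak. Global per-camera translations solve a
confidence-weighted least squares with camera (0,0) anchored; weights are
floored at 0.05 (pairs are never dropped while the confident-pair graph is
connected; a disconnected camera is an error naming it). The template is
translation-only — sensor rotations would surface in the per-pair residual
report, flagged above 2 px. Mosaics place 180°-rotated frames at their
offsets with bilinear sub-pixel shifts and linear feather weights
normalized to a partition of unity. Out-of-plane objects can ghost in
overlap zones (translation-only model); this is a documented limitation.

**Tiled detection.** Tiles of default 1024 px with stride `tile − 2·margin`
cover the mosaic exactly (final row/column clamped to the edge). Any
detector satisfying `tile → (boxes, scores[, labels])` can be plugged in;
the shipped reference detector is a multi-scale difference of Gaussians
(inner σ ladder ×1.6 across the requested scale range, outer = 3σ so
extended bodies respond at full contrast), polarity-aware thresholding,
morphological closing (radius ≈ hi/3, joining the response fragments of one
elongated organism), connected components, and scores normalized per tile.
Duplicate suppression is two-stage: each tile only reports boxes whose
centers lie in its *ownership region* (tiles own centers up to the midpoint
of each overlap — this is what guarantees exactly one detection for a
boundary-straddling object), and a global per-label greedy NMS (IoU 0.5
default, ties to the lower index) removes the rest. Per-tile detector
failures are recorded and skipped; only total failure raises.

**Stereo depth.** Keypoints are Shi–Tomasi corner maxima (the spurious
response strip at crop borders is masked); descriptors are 256 binary
intensity comparisons of the σ = 1.5 smoothed image on a fixed
pseudo-random pattern within a 12 px patch. Matching is mutual-best by
Hamming distance with a max distance of 64 and a 0.8 best/second ratio
test. The per-match displacement along the baseline axis is averaged after
median-absolute-deviation rejection at k = 3 scaled MADs (applied to the
orthogonal component too, which carries no disparity and is pure noise; the
MAD scale is floored at 0.35 px so zero-spread sets keep exact members);
fewer than three survivors is an error. Depth inverts the thin-lens
relation, and `z = u0 − u` with z positive toward the cameras. 3-D tracking
links detections by optimal gated assignment, picks the adjacent same-row
camera pair whose footprints (from the stitching template) best cover the
detection, and runs the pair pipeline per frame; detections outside any
two-camera zone keep their xy with z flagged unavailable.

**Identity embedding.** The embedder is three blocks of two 3×3
convolutions + ReLU with 2×2 max-pooling (channels 8/16/32), two fully
connected layers, and L2-normalized 64-d output, trained with the mean
Euclidean triplet loss (margin 0.2; a squared-distance variant is
available) using within-batch triplet sampling and Adam (10⁻³), batch 32,
default 62 epochs. Forward and backward passes are hand-written numpy
(float32, einsum over strided 3×3 windows), sized so hundreds of small
crops train in about a minute on one CPU. Datasets are built from
time-stamped per-identity crops: the split is strictly temporal (earliest
80 % of source crops → train), and augmentation is rotation jitter
(±15°), sub-pixel shifts and brightness jitter. Crops are assumed roughly
canonically oriented (in a real pipeline, detection crops are rotated
head-up via the body axis before embedding), which is why the augmentation
jitters rather than randomizes orientation. Embedding collapse (all
training embeddings nearly identical) is detected and flagged.

**Behavior metrics.** Occupancy maps are normalized 2-D histograms
(positions outside the arena are clipped with a warning). Tail tracing
thresholds the dark organism against the background median (−15 % margin,
so light body texture stays inside the mask), keeps the largest filled
component, skeletonizes, walks the longest end-to-end skeleton path
(double BFS sweep), orients it head-first by the distance-transform width,
resamples to equal arc lengths and reports chord angles relative to the
head-quarter body axis. Eye measurement takes the two largest components
darker than `min + 0.2·(median − min)` within the head region, orients each
by second moments, and assigns left/right by the cross product with the
heading. Activity is exhaustive-search block-matching flow (16 px blocks,
±4 px search, SSD via integral images) averaged over textured blocks.
Counting labels a binary mask (reference segmenter: Otsu + opening) at 4- or
8-connectivity, discards components under 50 px, and splits
individual/swarm classes at 5× the median component area by default;
densities carry a block-partition SEM (free-parameter grid, default 4×4 —
note that for Poisson-like scatter this SEM is partition-invariant,
≈ √N/area).

## Problem sizes and numerical choices

Tests run on a desk-scale 3×3 array (400×300 px sensors, 10 µm pixels,
13 mm pitch — ~1 Mpx mosaics) for stitching/detection, and on a
full-geometry two-camera pair (f = 25 mm, B = 19 mm, u0 = 150 mm, 1.4 µm
pixels, sensor cropped to a 3600×512 strip) for depth: disparity depends
only on f, B, u and pixel pitch, so cropping the sensor changes nothing but
memory. The depth-accuracy experiment in `scripts/acceptance.py` uses 100
beads (20 × 5 replicates) over ±2.5 mm; the identity experiment uses 8
synthetic identities × 100 augmented crops at 48 px input and 10–15 epochs.
The detection benchmark uses 50 fish over 10 frames with a 3.5 mm
minimum-separation cohort (overlap handling is exercised separately by the
occluder-augmentation and boundary-straddling tests).

Tie-breaks and degenerate inputs are fixed deliberately: NMS ties go to the
lower box index; feather weights renormalize to exactly 1 wherever any
camera contributes; registration requires ≥ 32 px of predicted overlap and
rejects NaNs; disparity must be positive (zero means infinity); empty
occupancy input, zero-area densities, sub-patch feature regions and
organisms inside the focal length all raise.

## Known limitations

* Translation-only stitching; rotated or tilted sensors only show up as
  flagged residuals.
* The depth model is absolute thin-lens; a one-point calibration hook
  (rescaling `B·f` from one target at known z) stands in for a full
  multi-position calibration.
* The reference detector and segmenter are classical stand-ins honoring the
  detector/segmenter contracts; trained networks (the intended production
  detectors for crowded scenes) are out of scope and plug in through the
  same contracts.
* Simulator fidelity limits (listed above) mean quantitative claims
  (e.g. ≈ 25 µm RMS depth error) characterize the algorithms under the
  stated noise model, not any specific hardware.
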