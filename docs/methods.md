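# Methods

## Problem and approach

During stereotactic body radiotherapy (SBRT) of paraspinal lesions, the
target vertebra must stay within a few millimeters of its planned
position for the whole fraction. `vertetrack` monitors this by tracking
the vertebrae of interest in intrafraction kV projections (IMR —
intrafraction motion review images) acquired by the linac's on-board
imager. Rather than matching against planning-CT DRRs, each IMR frame is
matched against the raw projection, at the nearest gantry angle, of a
cone-beam CT scan acquired the same day just before delivery: the
reference then shares the imaging chain's intensity characteristics and
systematic errors, and reflects the actual daily setup.

The reported quantity is a 2D shift (x lateral, y longitudinal) in the
beam's-eye view at the isocenter plane. Motion along the projection axis
is invisible to a single 2D view and is out of scope, as are
rotations — the evaluation harness instead quantifies how much unmodeled
rotation degrades the 2D result.

## Registration model

The match score between the reference projection `Proj_r` and the live
frame `Proj_i` at candidate shift (x, y) is the normalized
cross-correlation restricted to the tracking ROI:

    Obj(x, y) = <T2D(x, y) Proj_r, Proj_i> / (||T2D(x, y) Proj_r|| · ||Proj_i||)

with inner product and Euclidean norms taken over ROI pixels only.
`T2D` translates the reference by the detector-plane equivalent of the
iso-plane shift (multiplication by the magnification SID/SAD, division
by the pixel pitch) with bilinear resampling; out-of-bounds samples take
the nearest edge value. For non-negative images the score lies in
[0, 1] by Cauchy–Schwarz, 1 iff the masked images are proportional. The
plain (non-zero-mean) inner-product form is the default; a zero-mean
(Pearson-style) variant is available behind `RegistrationConfig.zero_mean`
for acquisitions with strong baseline offsets. The ROI mask stays fixed
on the live frame's grid; only the reference is resampled.

The score is maximized by a classical 2D downhill simplex (Nelder–Mead,
standard coefficients: reflection 1, expansion 2, contraction 0.5,
shrink 0.5) on the sign-flipped objective. Specifics beyond the
textbook algorithm:

* **Initial simplex** — vertices at the start point and at one
  `step_init` (default 2 mm) along each axis.
* **Warm start** — the first frame of a session starts at (0, 0);
  every later frame starts at the previous frame's optimum. This keeps
  the simplex near the solution during slow drifts and makes a static
  sequence converge to a bit-identical fixed point from the second
  frame onward.
* **Stopping rule** — at the top of each iteration the relative spread
  of the three scores, `2|Obj_H − Obj_L| / (Obj_H + Obj_L)`, is compared
  with `tol` (default 1e−6); a denominator below 1e−12 also terminates
  (degenerate/flat landscape). The rule is evaluated on the raw scores,
  not the sign-flipped ones.
* **Rebuilds** — if the rule has not fired after `max_iter` (default
  20) iterations, the simplex is re-created at its current best vertex
  with the initial edge length, at most `max_rebuilds` (default 4)
  times. Non-convergence after the last rebuild still returns the best
  vertex, flagged `converged=False` — an operator watching a live
  treatment needs a number either way.
* **Capture range** — any candidate with |x| or |y| above
  `capture_range` (default 20 mm; boundary inclusive) scores the worst
  possible value (0 for the default score), confining the search to the
  capture square. Larger motions are not measured accurately, but the
  score collapse still raises the out-of-tolerance alert, which is the
  clinically relevant outcome.

A consequence of the relative-spread rule worth knowing: on objectives
whose values approach zero near the optimum (not the case for NCC,
which approaches 1) the spread never falls below `tol`, every rebuild
resets the simplex edge to `step_init`, and accuracy plateaus around
1e−3 of the step size. The optimizer is therefore tuned for NCC-like
plateaus near 1, which is its only use here.

## Geometry

Patient coordinates are right-handed and isocenter-centered: x lateral,
y longitudinal (superior), z vertical. The kV source rotates about the
longitudinal axis at SAD 1000 mm (gantry 180° = posterior beam for a
head-first supine patient); the 1024 × 768 flat panel with a
397 × 298 mm active area sits at SID 1500 mm. Pixels are assumed square
(column pitch 0.3877 mm; the row pitch differs by <0.1%). Detector
coordinates are 0-based, pixel-center convention; the central ray hits
((n_cols−1)/2, (n_rows−1)/2). Iso-plane shifts and detector pixel
shifts convert by the exact factor pitch · SAD/SID, and the two
conversions are exact inverses.

Reference pairing: an IMR frame is matched to the reference projection
with minimal circular angular distance, accepted only below 0.75°. A
full 895-projection trajectory has 0.402° spacing, so every frame pairs
within ~0.2°, which contributes negligible registration error. Ties
break toward the smaller angle.

ROI templates are produced by forward-projecting a 3D mask (the
contoured vertebra expanded isotropically by 2 cm) per reference angle:
voxel centers are point-projected, and the resulting detector scatter
is closed with a 3×3 structuring element. Per-angle projection (rather
than a single nominal angle) was a genuinely open choice; it matches
the geometry of each paired reference exactly and costs one cheap
projection per angle.

## Digital phantom and DRR renderer

The synthetic phantom emulates a thorax with a spine: an
elliptic-cylinder soft-tissue body (lateral semi-axis 80 mm, vertical
52 mm) containing five cubic vertebral bodies (25 mm edge,
μ = 0.06 mm⁻¹) with posterior spinous-process flanges, separated by
5 mm soft-tissue disc gaps (μ = 0.02 mm⁻¹), the middle vertebra
centered at the isocenter. The attenuation values are plausible
effective-energy figures for ~100 kV imaging and are configurable; the
defaults were chosen so that one to two vertebrae fill the projected
ROI and so that noiseless in-ROI means land inside the IMR
qualification window [1500, 200000] at the default air-level photon
count of 50 000 per pixel.

DRRs are rendered by casting a ray from the source through each
detector pixel center and accumulating ∫μ dl by the trapezoid rule at a
fixed step of half a voxel (2 mm voxels by default), sampling the
static grid with trilinear interpolation at inverse-posed ray points —
the volume is never resampled. Intensity is `photons · exp(−∫μ dl)`;
optional Poisson noise models quantum mottle (no electronic noise,
scatter, spectra, detector lag or bowtie filter). Fixed-step trapezoid
integration was preferred over exact Siddon traversal: simpler, with
accuracy controlled by one parameter, and registration-scale fidelity
is what matters here. Poses are applied rotation (yaw) → pitch → roll
about the isocenter, then translation; a couch shift moves the phantom
rigidly, which is the same thing in these coordinates.

What the simulator does *not* emulate — scatter, beam hardening,
detector calibration artifacts, anatomy deformation, breathing — means
passing tests demonstrate the correctness and numerical behavior of the
tracking chain, not clinical accuracy on patients. Error figures
measured on a physical phantom with real linac hardware are specific to
that hardware and are not reproduction targets here; the synthetic
analogs bound the same quantities under cleaner conditions.

## Frame qualification

The grabber delivers a raw stream. CBCT frames become references when
the mean ROI intensity strictly exceeds 40 (blank-frame rejection
only). IMR frames must have the beam on, a mean ROI intensity inside
[1500, 200000] (inclusive), and a mean strictly greater than twice the
previous grabbed frame's mean. "Larger than" and "more than twice" are
read strictly, the window inclusively. The previous-frame mean is taken
from the immediately preceding grabbed frame regardless of its verdict.
A hysteresis latch — once a frame is accepted, further frames are
rejected until the mean falls back below the lower window bound —
implements the one-frame-per-kV-pulse contract; it is the minimal
mechanism with that guarantee. The 200 000 upper bound exceeds the
16-bit single-frame range, suggesting accumulated units on the real
grabber; all thresholds are configurable and the simulator scales
intensities to satisfy the defaults.

## Evaluation protocol and statistics

The harness mirrors the commissioning protocol: IMRT delivery uses nine
posterior beams (180°, 160°, 140°, 120°, 100°, 260°, 240°, 220°, 200°)
with three images per beam (MU-triggering abstracted away; the first
image fires at beam-on). VMAT delivery triggers one image at the start
of each partial posterior arc and every 15° of travel; the shipped
default covers the ranges [50°, 179°] and [290°, 181°], each split at
its midpoint into two arcs (18 triggers — the nominal 20-image count of
the protocol is recorded as metadata but does not follow from any
trigger rule we could derive, so it is not asserted).

Ground truth for a 3D couch shift at a given gantry angle is the
beam's-eye-view projection of the shifted isocenter point, demagnified
to the iso plane. Rotation series are scored against the
pure-translation truth to expose the 2D tracker's rotation
sensitivity. The repeatability matrix is 5 translation cases × (no
rotation + {yaw, pitch, roll} × {1°, 2°, 3°}) = 50 tests; with nine
beams and two directions this yields 900 per-triplet standard
deviations. Statistics: sample standard deviation (divisor n−1) over
each three-image triplet; maxima and nearest-rank 95th percentiles of
|error| per axis and pooled.

## Numerical and scale choices

* Desk-scale detector: the acceptance pipelines run at 256 × 192 pixels
  over the full active area (pitch 1.55 mm, iso-plane 1.03 mm). The
  cone-beam geometry is identical to full scale; only sampling density
  changes. The acceptance run measures maximum pure-translation errors
  of a few hundredths of a millimeter at this scale — well below the
  0.5 mm bound — so the reduction does not mask failures.
* Reference trajectories: 90 projections (4° spacing) for the
  acceptance series; the nine IMRT angles are all multiples of 4°, so
  every frame pairs exactly. Property tests use sparser or
  angle-targeted reference sets where only pairing behavior matters.
* The NCC evaluation crops to the ROI bounding box padded by the
  translation reach plus two pixels; within that window the cropped
  computation is exactly equal to translating the full frame (verified
  by a dedicated test).
* Degenerate inputs: an all-zero ROI denominator scores 0; an empty ROI
  raises; a frame/ROI grid mismatch raises; ties in the simplex vertex
  ordering break by stable sort (vertex index).
* Intensities are stored as 16-bit TIFF on disk (values clipped and
  rounded); registration operates on float arrays in memory.

## Known limitations

* 2D only: motion along the projection axis is invisible; rotations are
  quantified as error sources, not estimated.
* The monoenergetic, scatter-free simulator cannot expose
  intensity-dependent failure modes of plain (non-zero-mean) NCC, such
  as gain drift between the CBCT and IMR acquisitions; the zero-mean
  switch exists for that case but defaults off.
* The frame qualifier's doubling rule assumes dark inter-pulse frames;
  a stream without them (e.g. fluoroscopic acquisition) would accept
  only the first frame per run of bright frames.
* Real VMAT deliveries interleave gantry motion during exposure; the
  harness renders each trigger at a static angle.
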