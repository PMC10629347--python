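# Methods

## Model and conventions

**Frames and units.** The world frame is right-handed with its origin at the
arena-floor centre and +z up; all 3D quantities are millimetres. The camera
frame has +z along the optical axis, +x to the image right and +y down;
image coordinates are continuous pixels with the origin at the top-left
pixel corner (no half-pixel offset is applied on I/O). Extrinsics are stored
world→camera, `X_cam = R·X_world + t`; rotations are serialised as Rodrigues
3-vectors in calibration files and kept as matrices in memory. Frames
(time) are 0-based everywhere.

**Camera model.** A pinhole with intrinsic matrix
`K = [[f_u, s, c_u], [0, f_v, c_v], [0, 0, 1]]` and the 5-coefficient
radial-tangential distortion `(k1, k2, p1, p2, k3)` applied to normalised
coordinates before `K`. Undistortion inverts the polynomial by a damped
Newton iteration on the 2×2 system (analytic Jacobian, cap 50 iterations);
over the normalised unit box the round trip is accurate to better than
1e-8 px, which the property tests pin. Fisheye/omnidirectional optics are
out of scope: the model is a documented limitation when applied to very
short focal lengths, and a fisheye-specific distortion would need a
different inversion.

**Triangulation.** Homogeneous linear DLT on undistorted normalised
coordinates, followed by Gauss-Newton refinement of the total squared
*pixel* reprojection error (analytic Jacobian, backtracking line search,
best-iterate-kept). The refinement never increases the reprojection RMS
relative to the linear solution — this is enforced structurally, not hoped
for. Points observed by fewer than `min_views` (default 2) cameras are
marked invalid rather than raising; genuinely degenerate geometry
(coincident optical centres, parallel rays with the homogeneous solution at
infinity, threshold 1e-10) raises a degeneracy error. A RANSAC view-subset
option was considered and deliberately left out of the default path: the
upstream reconstruction being emulated does not document outlier rejection,
so the default is the plain least-squares estimator and outliers are
instead a property of the noise model.

**Resectioning and rig refinement.** Camera recovery from 3D–2D
correspondences uses the projection-matrix DLT (≥6 non-coplanar points;
coplanarity detected from the singular-value spectrum of the centred
points). With unknown intrinsics the 3×4 matrix is RQ-decomposed with sign
normalisation and cheirality fixing; with known intrinsics the pixels are
undistorted first and the pose is polished by 6-dof Gauss-Newton on a
left-multiplicative rotation increment. `refine_rig` applies the same
pose-only polish per camera with intrinsics held fixed; a camera whose step
diverges keeps its initial pose and raises a warning flag, so the total
squared reprojection error is non-increasing by construction. ChArUco corner
*detection* in images is out of scope — point correspondences are the entry
point, which is what the simulator emits.

## Test object

The object is three mutually perpendicular rods meeting at a common origin,
one per axis, each carrying a letter glyph at its tip; only trackable
keypoints are modelled (origin plus one anchor per rod at `rod_length`,
default 40 mm), not the letter meshes. All pairwise distances are evaluated
by default. The bare four-point set is necessarily invariant under the two
cyclic axis permutations; setting `letter_offset > 0` adds one secondary
keypoint per letter in deliberately non-cyclic directions, making the
keypoint set fully chiral — the geometric counterpart of the letters'
unique visual appearance. The symmetry census over the 24 proper
axis-aligned rotations is part of the test suite. Geometry is an input, not
a result: any object can be supplied as JSON (`{name, keypoints, pairs}`,
object-frame mm).

## Simulator: what it emulates, and what it does not

The simulator reproduces the *statistical* structure of a capture session
in a surround-view arena:

* **Rig.** `n_side` cameras (default 3) equally spaced on a horizontal ring
  plus one camera below the transparent floor. Presets: small arena (89 mm
  cylinder) with ring radius 150 mm, and large arena (320 mm plate) with
  ring radius 340 mm. The ring radius of the small arena is not a published
  figure; 150 mm was chosen once so that the arena plus a 40 mm object fills
  roughly half the field of view. Intrinsics default to a 1280×800 sensor
  behind a 2.4 mm lens; the pixel pitch is likewise not published, so 3 µm
  is assumed (giving f = 800 px) and exposed in the configuration — only
  relative geometry matters for the validation properties. All cameras aim
  at the capture-volume centre, `(0, 0, 30)` mm, with side cameras at that
  same height and the bottom camera 120 mm below the floor; these values
  were set so every camera's field of view covers the whole default capture
  volume, which the zero-noise identity property requires and which matches
  how a real arena is laid out.
* **Trajectory.** A smooth seeded rigid motion: rotation accumulating at
  `rotation_rate` (default 1°/frame at 30 fps, i.e. a slow hand-held
  presentation) about a slowly precessing axis, translation a band-limited
  sum of random-phase sinusoids bounded by `translation_amplitude`
  (default 10 mm) around the volume centre. Identical seeds give bitwise
  identical trajectories.
* **Detections.** Per frame/camera/keypoint the object is projected; points
  behind a camera or outside the image are missing, a per-record Bernoulli
  draw with probability `p_miss` models occlusion-like dropout, and visible
  points receive isotropic Gaussian pixel noise (σ = `pixel_sigma`), with a
  small probability of wide outlier noise. Dropout can be overridden per
  camera and per (camera, keypoint), which is how the mouse-like preset
  expresses ventral keypoints (paws) being visible mainly from below:
  p_miss 0.6 for paws in side views against 0.05 for the bottom view, on a
  rigid nine-keypoint body plan at adult-mouse scale. Confidences are 1 for
  rendered and 0 for missing detections by default; an alternative law that
  shrinks confidence with the drawn noise magnitude exists for exercising
  confidence thresholds. One global seed is expanded into independent
  per-stage streams (trajectory / noise / dropout).

What the simulator does **not** model — and therefore what passing tests do
not demonstrate about real data: geometric self-occlusion (dropout is
independent across frames, real occlusion is temporally and spatially
correlated), articulated motion (the mouse stand-in is rigid), detector
biases of a trained network (noise is zero-mean and homoscedastic apart
from outliers), rolling-shutter or synchronisation error, and calibration
error in the rig files themselves (the simulator's calibration is exact;
degraded calibrations can be studied by perturbing poses and refining).

## Validation statistics

* **Camera subsets.** All subsets of size ≥2 are enumerated and grouped into
  symmetry classes `(n side)s[+b]`, because equally spaced side cameras are
  geometrically interchangeable; per-subset results are retained so
  asymmetric rigs degrade gracefully. For a 3-side+bottom rig this yields 11
  subsets in 5 classes. (When only the 10 proper subsets of sizes 2–3 are
  considered, prior descriptions of this analysis mention nine; the package
  enumerates all ten and leaves any exclusion to the user.)
* **Inter-keypoint error** keeps its sign so per-pair bias (mean signed
  error) is estimable next to the variance of the repeated distance
  measurements (sample variance, n−1); boxplots use the absolute error.
  Frames with an invalid endpoint are excluded and surface as a coverage
  fraction rather than being imputed.
* **Deviation from reference** is the unsigned 3D distance to the full-rig
  estimate, computed only where both reconstructions are valid; the
  reference against itself is exactly zero, which doubles as a pipeline
  self-check.
* **Boxplot statistics** use linear interpolation between order statistics
  for the quartiles (no universal convention exists; this choice is pinned
  by oracle tests) and whiskers at the most extreme data inside the
  `Q1 − 1.5·IQR` / `Q3 + 1.5·IQR` fences, with points beyond them counted
  as outliers but excluded from whisker placement.
* **Error vs image centre** pairs each per-frame pair error with the pixel
  distance of the pair's midpoint observation from the principal point,
  averaged over the cameras that saw both endpoints (a worst-view variant
  is a switch, since pooling across views is the ambiguous part of this
  analysis). Spearman ρ uses tie-averaged ranks; the p-value is the
  large-sample normal approximation `z = ρ√(n−1)`. Observations beyond a
  configurable border radius (default 486 px) are counted as outside the
  reliable field.
* **Configuration ANOVA** fits `abs_error ~ C(camera count) * C(bottom
  present)` with type-II sums of squares (the type is not dictated by the
  analysis being emulated; type II is the conventional choice for unbalanced
  factorials) and runs Tukey HSD across symmetry classes. When the factorial
  crossing has empty cells — e.g. when the 4-camera class is included, since
  no 4-camera subset lacks the bottom camera — the interaction is not
  estimable and the model falls back to main effects with a warning. In the
  fitted study the ANOVA therefore runs on the deviation of the proper
  subsets only, where the 2×2 design is complete.

## Model/Results interface

The analysis is organised statsmodels-style: `ValidationStudy(rig,
detections, object_spec, ...)` holds the data and options; `.fit()` runs
triangulation per subset and every statistic once, returning
`ValidationResults` with the per-class stats, `summary()`, `to_report()` /
`save_report()` (JSON) and `plot_boxplots()`. `run_validation(...)` is the
one-call functional wrapper. A study without an object spec (no rigid
ground truth, as with live animals) computes the deviation-from-reference
branch only.

## Numerical choices and problem sizes

Default tolerances: rotation orthonormality 1e-9; triangulation degeneracy
1e-10; Gauss-Newton termination on relative cost improvement < 1e-12 or
step < 1e-14 with iteration caps (20 for points, 60 for poses); Newton
undistortion tolerance 1e-12 with cap 50. The confidence threshold at
triangulation defaults to 0.5 — arbitrary, but pinned, logged and
overridable. The test suite and the acceptance script run simulations of
60–200 frames and 10 seeds per stochastic property; these sizes were chosen
as the smallest at which the Monte-Carlo statements they make (ordering of
class medians, binomial dropout intervals, ANOVA calibration at
500 records/cell over 100 replicates) have comfortable margins.

## Known limitations

Fisheye optics and image-level fiducial detection are out of scope.
Occlusion is statistical, not geometric, so view-dependent error
correlations of real animals are only caricatured by the mouse-like preset.
The 2D temporal filter slot ships a centred rolling median only. Intrinsics
are never estimated from images — they enter via calibration files or
correspondence-based resectioning with distortion assumed known or zero.
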