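# rigval

Validation of multi-camera 3D capture rigs for markerless animal pose
estimation, using rigid test objects of known geometry.

## The problem

Surround-view arenas for small-animal behaviour (typically three cameras at
120° around the subject plus one looking up through a transparent floor)
reconstruct 3D keypoints by triangulating 2D detections from calibrated
cameras. Reprojection error in 2D is a poor guide to 3D accuracy: it is
biased by where the calibration board happened to sit in the volume.
A rigid, 3D-printed test object with known inter-keypoint distances gives a
direct, unbiased accuracy proxy — a lower bound on the 3D error of the rig —
and lets you ask which and how many cameras a given experiment actually
needs.

`rigval` implements this validation end to end:

* **camera geometry** — pinhole model with 5-coefficient radial-tangential
  distortion; projection, Newton undistortion, DLT triangulation with
  Gauss-Newton reprojection refinement, DLT resectioning, and
  bundle-adjustment-style rig polishing;
* **test object** — a parametric rigid object (three perpendicular rods
  meeting at the origin, one letter anchor per axis) with ground-truth pair
  distances;
* **simulator** — a synthetic arena (camera ring + bottom camera, smooth
  seeded object trajectories, Gaussian pixel noise, outliers, and stochastic
  detection dropout as an occlusion proxy) that emits the same files a real
  session would;
* **validation statistics** — for every camera subset, grouped into symmetry
  classes `(n side cameras)s[+b]`:

  * inter-keypoint distance error `e = d̂ − d_true` (mm), decomposed per pair
    into bias `E[e]` and variance `Var[d̂]`;
  * deviation from the full-rig reference `‖X̂_subset − X̂_full‖` (mm), for
    subjects without rigid ground truth;
  * angle error between rigid body vectors (degrees);
  * boxplot summaries with whiskers `Q0 = Q1 − 1.5·IQR`, `Q4 = Q3 + 1.5·IQR`
    clipped to the data (outliers counted, not shown);
  * Spearman rank correlation of error against pixel distance from the image
    centre, with a configurable unreliable-border flag (default 486 px);
  * a two-way type-II ANOVA of deviation on camera count × bottom-camera
    presence, with Tukey HSD post-hoc contrasts.

Units are millimetres in 3D and pixels in 2D throughout.

## Worked example

```python
import rigval

bundle = rigval.simulate_bundle(
    seed=1,
    trajectory=rigval.TrajectoryConfig(n_frames=100),
    noise=rigval.NoiseModel(pixel_sigma=1.0),
)
results = rigval.ValidationStudy(
    bundle.rig, bundle.detections, bundle.object_spec
).fit()
print(results.summary())
```

```
Camera-subset validation
============================================================
reference configuration: cam_0+cam_1+cam_2+cam_3
   class   n_err    median        Q1        Q3   dev med  coverage
------------------------------------------------------------------
      2s    1800    0.1732    0.0801    0.3076    0.2112     1.000
    1s+b    1800    0.1595    0.0758    0.2745    0.1926     1.000
      3s     600    0.1282    0.0567    0.2219    0.1115     1.000
    2s+b    1800    0.1279    0.0606    0.2161    0.1020     1.000
    3s+b     600    0.1036    0.0440    0.1807    0.0000     1.000

bias/variance per pair (reference configuration):
               X|Y: bias +0.0061 mm, variance 0.0246 mm^2 (n=100)
               X|Z: bias +0.0049 mm, variance 0.0203 mm^2 (n=100)
               Y|Z: bias -0.0150 mm, variance 0.0304 mm^2 (n=100)
          origin|X: bias -0.0151 mm, variance 0.0279 mm^2 (n=100)
          origin|Y: bias -0.0099 mm, variance 0.0245 mm^2 (n=100)
          origin|Z: bias -0.0014 mm, variance 0.0211 mm^2 (n=100)

error vs image centre: Spearman rho=-0.005, p=0.912, n=600; 0 beyond 486 px

two-way ANOVA on deviation (camera count x bottom presence):
  camera number: F=768.413, p=7.61e-155
  configuration: F=62.510, p=3.4e-15
  interaction:   F=11.277, p=0.000792
```

Reading the table: each row is a symmetry class of camera subsets (`2s` =
two side cameras, `1s+b` = one side camera plus the bottom camera, ...).
`median`/`Q1`/`Q3` summarise the absolute inter-keypoint distance error
against the object's known geometry; `dev med` is the median 3D deviation
from the full four-camera reconstruction (zero for the full rig itself by
definition); `coverage` is the fraction of frame×keypoint entries with a
valid (≥2-view) estimate. At 1 px detection noise the median error falls
monotonically with camera count — the quantitative version of "more cameras
help" — and the ANOVA confirms that both camera count and bottom-camera
presence drive the deviation.

`results.plot_boxplots()` draws the per-class boxplot figure;
`results.save_report("report.json")` writes the machine-readable report.

## Command line

The same pipeline is available as a CLI over the file formats used by
markerless-tracking toolchains (per-camera detection CSVs with
scorer/bodyparts/coords headers, camera-section calibration TOML,
object-spec JSON, wide 3D CSV):

```sh
rigval simulate --preset small --seed 7 --out session/
rigval triangulate --calibration session/calibration.toml \
    --detections session/detections --cameras cam_0,cam_3 --out pose3d.csv
rigval evaluate --calibration session/calibration.toml \
    --detections session/detections --object session/object.json \
    --out report.json
rigval report --report report.json --figure boxplots.png
```

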