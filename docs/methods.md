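# Methods

This note documents the models, conventions, parameter choices and known
limitations behind antwalks. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate frame and angle conventions

Trajectories are nest-centred: the nest entrance is (0, 0), +x is East and
+y is North, units are cm. Pixel tracking tables are calibrated on ingest
(translate by `nest_pixel`, scale by cm-per-pixel, flip the image y axis so
+y is North); the calibration is left to configuration because recording
geometry varies between setups.

Azimuths are compass-style (degrees clockwise from North: N = 0°,
E = 90°). A final heading is the azimuth of the thorax→head axis on the
last frame inside the recording area, taken **relative to the bearing from
the release point to the nest**, wrapped to [0, 360). Under this
convention an ant released North of the nest with its head pointing East
has heading 270°. Turning angles along a path are signed, positive for a
left turn, in (−π, π]; a pure reversal maps to +π.

Frame gaps in tracking tables are rejected, not interpolated: every metric
assumes a constant inter-frame interval of 1/frame_rate s (default 25 fps).
Raw coordinates are not smoothed by default.

## Path metrics

Steps are thorax displacements between consecutive video frames; no
rediscretization is applied before sinuosity, matching the frame-based
step definition. Mean speed excludes stops, defined as runs of per-frame
speed below `stop_speed_thresh` (default 0.5 cm/s) lasting at least
`stop_min_dur` (default 0.2 s); the protocol defines stop exclusion but no
thresholds, so these are explicit configuration with the defaults recorded
in every report. Orientation angular velocity is the mean magnitude of the
frame-to-frame change of the unwrapped body-axis azimuth — the magnitude,
because a signed mean would cancel left/right gaze oscillation.

Sinuosity is evaluated exactly as the formula
S = 2 [ p((1+c)/(1−c) + b²) ]^(−1/2). Note that although sinuosity is
often described as ranging from 0 (straight) to ~1 (tortuous), the formula
itself is not bounded by 1 when steps are short (p < 1 cm); we follow the
formula and report it unclipped. E^a_max = β/(1−β) is returned as +inf
when β ≥ 1 − 1e−12 (perfectly straight path). Smoothly generated paths
have β very close to 1, so synthetic learning walks show E^a_max in the
thousands; real digitized paths carry frame-level jitter that keeps β, and
hence E^a_max, much lower. Comparisons across conditions are unaffected.

Convex-hull area uses the Qhull convex hull of all thorax positions;
collinear paths get area 0.

## Scanning-bout detection

A scanning bout is on-the-spot rotation with successive held head
directions. Detection has three stages:

1. **Stationarity.** Maximal frame windows whose thorax bounding-box
   diagonal stays within 2·`on_spot_radius` (default radius 0.5 cm) are
   found with a two-pointer sweep; windows shorter than `min_bout_dur`
   (0.5 s) are dropped. Overlapping or near-in-time (≤ `merge_gap`,
   0.3 s) candidates are resolved greedily, longest first, leaving one
   representative interval per on-the-spot episode. The diameter
   criterion, rather than distance-to-centroid of a growing interval, is
   used because a growing-centroid rule lets approach frames anchor the
   window and split genuine bouts.
2. **Denoising.** The body-axis angle is recomputed from head and thorax
   tracks boxcar-smoothed over `pos_smooth_s` (0.28 s), then the angle
   itself is smoothed over `orient_smooth_s` (0.2 s). This matters:
   digitization noise of 0.05 cm on a ~0.4 cm head–thorax axis is ~10° of
   angular noise per frame, which would otherwise swamp any rotation-rate
   threshold at 25 fps.
3. **Fixations.** Within a stationary interval, still segments are runs
   with smoothed rotation rate below `fixation_max_rot_rate` (50 deg/s)
   lasting ≥ `fixation_min_dur` (0.08 s); consecutive segments whose mean
   directions differ by less than `min_fixation_separation` (45°) are the
   same fixation. An interval is a bout when it contains ≥ 2 distinct
   fixations spanning at least the separation threshold.

The field definition of a bout is qualitative, so these thresholds were
calibrated once against the synthetic generator (exact recovery on
noise-free walks; ≥ 90% — measured ~99% — on walks with 0.05 cm / 3°
per-frame jitter) and travel with every output (`ScanParams` is embedded
in the run metadata). The 45° separation reflects that scanning saccades
swing the head by many tens of degrees, while slow walking drift plus gaze
oscillation stays well below it.

## Circular statistics

Angles are degrees at the API, radians internally. κ is estimated by
numerically inverting A(κ) = I₁(κ)/I₀(κ) at the sample mean resultant
length (Brent's method), accurate to ~3% in the mean at n = 100 for
κ ∈ {1, 4}.

- Rayleigh: Z = n r̄², p from the standard series approximation, clamped
  to [0, 1]. Measured type-I error at α = 0.05, n = 20: ~5.0%.
- V test: u = r̄ cos(µ − θ₀)·√(2n), one-sided normal p.
- Mean-direction CI: Fisher's circular-dispersion interval,
  half-width = arcsin(t_{α/2, n−1}·√(δ̂/n)) with
  δ̂ = (1 − ρ̂₂)/(2 r̄²). The t quantile replaces the usual normal z as a
  small-sample correction — with z the interval covers only ~93% at
  (κ = 4, n = 20), with t ~95%. A seeded percentile bootstrap
  (2000 resamples) is available and preferred for diffuse samples
  (r̄ < 0.45, flagged). A sample too diffuse for any interval yields a
  flagged full-circle CI. The "nestward orientation" check is wrap-aware
  inclusion of 0° in this CI.
- Watson–Williams: F with the 1 + 3/(8κ̂) correction, df (1, N−2);
  pooled r̄ < 0.45 is flagged as an assumption violation.
- von Mises LRT: χ² = 2[ℓ(µ̂, κ̂) − ℓ(θ₀, κ̂_constrained)], p from χ²(1).
  This is the mean-direction form (does the mean equal the predicted
  nestward direction?), which is the version whose output pairs a χ²
  statistic with a κ estimate; degenerate near-uniform samples are
  flagged rather than tested.

Watson's U² goodness-of-fit test is deliberately not implemented: the
procedure reported as a "Watson test" in this literature is the
CI-inclusion check above, and that is what we provide.

## rotIDF

Panoramas are equirectangular [0, 1] grayscale grids (rows = elevation
from +90° to −90°, columns = azimuth, luminance conversion
0.299/0.587/0.114 on ingest, per-image normalization). The discrepancy at
shift s is the RMS pixel difference between the reference and the test
image rotated by s degrees (mean absolute difference available by
configuration); shifts run 0..359°, requiring the column count to be a
multiple of 360 (block-mean `downsample` gets camera-resolution images
there). Depth = mean − min of the curve.

Rotational matching recovers the *facing direction in which the reference
was stored*: if the nest panorama is aligned to a test site's nest-ward
bearing (`rotate_panorama`), the best-match shift reads directly as a
heading relative to the nest direction. The pipeline does this per site
using panorama metadata in the config. On the default synthetic scenes the
best bearing lies within 20° of the true nest bearing at all 2 m and 4 m
sites, and mean depth decreases monotonically as the test position moves
0 → 8 m from the nest.

Printed rotIDF levels depend entirely on the intensity scale and content
of the input images; only the identities (self-min 0 at shift 0, shift
recovery, depth = mean − min, symmetry of the minimum) and qualitative
patterns are reproducible without the original field images.

## Group statistics

The design is complete repeated measures, and that is exploited directly
instead of fitting a mixed model: for each planned Helmert contrast
(c₁ = LW vs mean(E1..E3), c₂ = E1 vs mean(E2, E3), c₃ = E2 vs E3, mutually
orthogonal and zero-sum) every ant contributes one within-ant contrast
value, and a one-sample t test asks whether the mean is zero. With a
complete design this is an exact repeated-measures test (its null p-values
are uniform; checked by KS test in the suite) and reports its own
df = n_ants − 1 rather than attempting to match mixed-model denominator
df. Bounded (0, 1) metrics (straightness, sinuosity) are logit-transformed
(clamped to [1e−6, 1−1e−6]) before contrast testing — a true binomial
likelihood is ill-defined for non-count data — and the transform is
flagged in the output. Tukey pairwise comparisons use the within-ant error
term (ant × condition interaction MS, df (k−1)(n−1)) with studentized-range
adjustment. Alpha levels: 0.01 for the multi-metric walk comparisons, 0.05
for circular tests.

## Synthetic generator

The generator emulates the study's inputs with known ground truth; its
defaults are the package's study conditions.

- **Learning walk**: a teardrop loop r(φ) = R sin(φ/2) around the nest
  (leaves and re-enters the origin), laterally squeezed (aspect 0.55) so
  the hull stays slim, with smooth low-order Fourier wobble that vanishes
  at the endpoints. Frames are placed along the curve at the commanded
  speed with AR(1) per-frame variability renormalized over the walk, so
  the realized mean speed matches the commanded one to within frame-count
  rounding (measured ≤ ~1%). Scanning bouts (default 1–3) are spliced in
  at arc positions ≥ 3 cm apart: thorax stationary, 3–5 fixations held
  0.4–0.8 s, separated by 70–130° saccades at ~400 deg/s. Gaze oscillates
  ±8° at 0.8 Hz about the travel direction while walking. Defaults:
  loop radius 8.5 cm (experiment draws 7–10 cm), speed 2.5 cm/s
  (draws 2.2–3.0).
- **Excavation trip**: straight out to a drop distance uniform on
  5–10 cm, immediate turn, straight back; heading jitter is AR(1) about
  the target bearing with stationary spread 1/√turn_kappa rad
  (κ = 500 → outbound straightness > 0.98). Faster than learning walks
  (5 cm/s default, draws 4.5–5.5) with faster gaze oscillation
  (±15° at 2 Hz). No stops, no scans.
- **Headings**: seeded von Mises draws; κ = 3 toward the nest for the 2 m
  conditions, κ = 0 (uniform) for 4 m, n = 20 per condition.
- **Panoramas**: a parametric semi-arid scene — a continuous vegetation
  skyline on a 20 m circle around the nest (height = 3.5 m plus a few
  Fourier modes of world azimuth, rendered with correct parallax) and a
  dozen discrete blocks (near tussocks, distant bushes/trees 8–30 m out).
  The corridors to the standard test positions are kept clear, as the
  field site is cleared around the nest. These scenes are synthetic
  stand-ins for field camera panoramas.

Choosing the loop geometry involved a compromise: the descriptive numbers
for naive learning walks (maximum displacement up to ~20–30 cm but hull
area ~20 cm²) are not jointly attainable by any smooth loop, so the
defaults put the maximum excursion at 7–10 cm — at or above the excavation
drop distances, as observed — and accept hull areas of a few tens of cm².
With the defaults the population means satisfy every headline contrast
direction: area(LW) > area(E), duration(LW) > duration(E),
speed(LW) < speed(E), angular velocity (LW) < (E).

What the generator does **not** emulate: gait-level kinematics, tracking
dropouts and identity switches, non-stationary speed profiles (e.g.
slowing near the nest), sky polarization or 3-D vegetation, pixel noise in
panoramas, and between-ant correlation structure beyond independent
per-ant parameter draws. Passing tests therefore demonstrate correctness
of the computations and qualitative reproduction of the study design under
idealized inputs, not robustness to every artifact of real video tracking.

## Problem sizes and numerics

The end-to-end reproduction uses 200 replicates of the default 20-ant
study; calibration checks use 5000 simulations for type-I error and 2000
for CI coverage; scan-bout recovery uses 100 clean and 200 jittered walks;
κ recovery uses 500 replicates at n = 100. These sizes give Monte-Carlo
standard errors comfortably inside the decision bands while keeping the
whole suite to a few minutes. Degenerate inputs are handled explicitly:
zero-variance samples in the t/ANOVA machinery return p = 1 with a flag
when means agree (p = 0 otherwise), straight paths return sinuosity 0 and
infinite E^a_max with the division guarded, r̄ ≈ 0 circular samples return
flagged full-circle CIs, and multiple global rotIDF minima return the
smallest shift with a warning.

One caution on the two-metre/four-metre heading pattern: with κ = 0 at
4 m and α = 0.05, the probability that *both* 4 m conditions
simultaneously fail to reject in a given replicate is 0.95² ≈ 0.90, so the
joint event hovers at 90% by construction; per-condition rates (~95% and
~100%) are the stable summaries, and the acceptance script reports both.
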