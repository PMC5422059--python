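# Methods

## The problem and the model

A hand-held smartphone records 100 Hz inertial data (gravity-removed linear
acceleration, angular velocity, yaw/pitch/roll, magnetometer) plus sparse
GPS fixes, in one CSV per recording. Two processing modes share one motion
detector but answer different questions:

* Navigation Mode (NM): how far, and in which direction, did the operator
  move between trees? Steps of 0.5–3.75 m at walking speed (~0.44 m/s)
  must be measured to ~0.15 m so trees planted 0.5 m apart can be told
  apart, which raw GPS (±2.5–5 m) cannot do.
* Acquisition Control Mode (ACM): when did the handset start and stop
  moving along a branch (to trim the video), and are the resulting frames
  sharp enough to process?

### Static/movement detection

For each mode-specific channel (NM: linear acceleration X and Y; ACM:
angular velocity Y) the magnitude |is| is split into fixed blocks of
M = 85 samples (0.85 s); each sample takes its block maximum, giving a
piecewise-constant local-maxima envelope. A sample is *moving* when the
envelope exceeds

    THD = mean(Mag) + K · std(Mag)      (population std, whole recording)

floored at min_thd, the largest idle-hand magnitude (K and min_thd per
channel: 1.8/0.44/1.8 and 0.15/0.15/0.05; acceleration in m/s², angular
velocity in rad/s — the working unit assumption, since the constants are
plausible on those scales). NM channels combine by logical OR; walking may
excite either axis. The mean/std are taken over the full recording
(offline batch); per-operator recalibration is a config swap.

Two numerical choices sharpen this rule:

* **Boundary refinement.** The block envelope quantizes run boundaries to
  0.85 s. Within the first and last block of each detected run, the
  boundary is moved to the first/last sample whose *raw* magnitude crosses
  the channel threshold (any channel). Refinement can shrink a run, never
  grow or split it, and uses only quantities the detector already has. It
  brings boundary error from O(M·dt) down to the signal's own onset
  sharpness (a few samples on realistic signals).
* **Debounce.** Runs shorter than min_segment = 0.3 s are relabeled
  static, suppressing single-window spikes.

The mask is stored with moving = True during movement; multiplying the
acceleration by it forces idle signals to zero, which is what prevents
cumulative integration error.

### NM kinematics

Velocity is the rectangular (Euler) integral v[i] = v[i−1] + a[i]·dt at
dt = 10 ms, with acceleration pre-masked; velocity is pinned to exactly 0
on static samples and restarts from 0 at each segment (ZUPT). Inside a
segment the integrated velocity still ends at a spurious v_end; the drift
is modeled as the straight line from 0 at the segment start to v_end at
its final sample and subtracted, so compensated velocity ends at exactly
zero (the line is anchored at 0 at the start — residual numerical noise
there is below 1e-12 by construction). Trapezoidal integration differs at
O(dt²), far below sensor noise, so the simplest rule is used.

Compensated velocities may dip negative near segment ends at walking
speed. They are deliberately not clamped: the resulting systematic
under-measurement is proportional to the step length and is absorbed by a
single global calibration factor (default 1.4735), estimated by
through-origin least squares of true on estimated displacement
(statsmodels OLS without constant; uncentered R²). A validation helper
re-regresses held-out true displacements on calibrated estimates; a slope
of 1 means the factor generalizes.

### Georeferencing

Heading per movement is the circular mean of yaw over the segment's moving
samples (one θ per movement is needed; circular averaging avoids the
0/360 seam). θ = azimuth − declination (default −6.13°, site-specific,
configurable). Device-frame displacement rotates into the plane with
degree trigonometry:

    ΔN = ΔY·cos θ + ΔX·cos(θ+90°),  ΔE = ΔY·sin θ + ΔX·sin(θ+90°)

and positions accumulate as N += ΔN, E += ΔE from the GPS seed. Plane
coordinates are Gauss-Krüger (transverse Mercator at scale 1), implemented
with the Krüger series in the third flattening to n⁴ (sub-millimeter
round trip across a zone; verified against direct meridian-arc quadrature
and an ellipsoid-radius geodesic check). The default zone is the
MAGNA-SIRGAS Bogotá origin (GRS80, 4.5962° N / 74.0775° W, false origin
1 000 000/1 000 000 m): inverting the recorded course origin
(1 043 915.914 N, 831 420.737 E) under it lands in the Colombian coffee
axis near 4.99° N, 75.60° W, which supports the choice; the zone is
config-first and any transverse-Mercator zone can be supplied. Latitudes
at the poles are rejected.

The worst-case georeferencing error is additive: the seed fix error (up to
max_gps_error, default 5 m) plus the INS relative error (0.15 m
calibrated), i.e. 5.15 m total — but unlike GPS-only operation no points
are lost between trees, and relative positions stay at decimeter level.

### ACM trimming and sharpness

The gyro-Y mask yields movement segments; the longest is the scan (the
protocol records one branch per file), others become warnings; an empty
mask raises a re-acquisition error. Scan times map to half-open frame
ranges by frame = round((t − t0_offset)·fps), clipped to the video. Scan
speed classes: low < 5 cm/s ≤ medium ≤ 10 cm/s < high, boundaries
inclusive into medium. Displacement is *not* estimated from acceleration
in ACM — below 5 cm/s the signal is too weak to integrate, detection is
the only deliverable.

Sharpness is scored on the red channel (fruits are red-dominant) inside
three circular ROIs (diameter 100 px) at ¼, ½, ¾ of the width on the
central row. Sobel (3×3, both directions, Σ√(Sx²+Sy²)), Laplacian (3×3
4-neighbor kernel, Σ|L|) use replicate padding so near-border ROIs see no
spurious edges. Canny uses hysteresis limits (σ, 3σ) of the full image
(self-adjusting to illumination), its edge map is encoded {0, 255} and
summed raw — under that encoding the 290 000 threshold corresponds to
≈1 137 edge pixels in a ~7 854 px ROI, a plausible density, which is why
this reading of the ambiguous "sum of the pixels" was adopted. A constant
image (σ = 0) scores 0 without error. A frame is accepted when ANY ROI
index is strictly above the operator's threshold; the default operator is
the Laplacian (cheapest kernel — the three operators separate the same
velocity classes, so the choice is config). Selection scores the
begin/middle/end QC frames first; if all three fail, the video is flagged
for re-acquisition, otherwise the trimmed range is uniformly subsampled to
the retention fraction (default 0.2, nearest-integer count).

## The synthetic generators — what they emulate, and what not

* **Walks.** Each step is a trapezoidal-velocity profile (20 % ramps)
  whose *sampled* velocity is rescaled so its rectangular integral is
  exactly the step length; acceleration is its backward difference. The
  sampled profile is therefore the ground truth with no quadrature bias,
  and the noiseless end-to-end oracle recovers 1.000 m to machine
  precision. The accelerometer sees that profile scaled by a sensitivity
  deficit (default 1/1.4735), plus: speed-proportional gait vibration
  (0.8 m/s² at full speed, 2 Hz — vibration dies with the speed, so its
  integral contributes negligibly to the step displacement), a zero-
  integral biphasic jolt (0.6 m/s², 60 ms) at step start and end (heel
  strike; it gives the detector a sharp onset, as real gait does), white
  sensor noise (σ 0.02 m/s² moving) and a constant per-trace bias up to
  ±1 mg (exactly removed by the drift line — which is why the drift model
  is linear). Idle gaps carry clipped Gaussian noise bounded at ±10 mg
  (σ = bound/3), consistent with the floor min_thd = 0.15 being the
  *maximum* idle magnitude. One GPS fix seeds the trace, optionally
  perturbed uniformly up to a configurable radius.
* **Scans.** Gyro-Y shows 9 Hz hand tremor (0.1 rad/s) plus a train of
  micro-adjustment impulses (0.4–0.7 rad/s, every 0.35–0.65 s) while the
  handset moves; pick-up and set-down transients bound the scan, as they
  do when an operator starts and stops a pass over a branch. The impulse
  train is what makes the signal peaky enough for a μ + 1.8σ threshold to
  sit below the movement envelope — matching the character of real
  hand-held gyro traces. Idle noise σ = 0.01 rad/s stays below the 0.05
  floor.
* **Images.** Red-textured fruit ellipses and green leaf blobs on a
  speckled bark band through the image center, so all three default ROIs
  contain structure; defocus is Gaussian blur, fast scanning is a
  horizontal box blur. Texture contrast is fixed so the designated sharp
  fixture (seed 7) clears the Sobel acceptance threshold and its σ = 8 px
  copy fails all three.

Not emulated: terrain slope and attitude dynamics (no 3-D strapdown; the
pipeline is 2-axis by design), GPS multipath, magnetic disturbances near
machinery, photorealistic canopies, illumination extremes. Passing the
synthetic suites therefore demonstrates the *algorithmic* contracts
(detection, integration, compensation, projection, scoring) under
realistic signal scale and noise — not robustness to every field
condition; the detector constants remain per-operator calibration
quantities in the field.

## Problem sizes and determinism

The evaluation harness uses 40 movements (25/15 split) for calibration
recovery, 200 movements for displacement accuracy, 200 scans for boundary
rates, 100+100 pooled traces for overall detection, and a single 1080p
fixture pair for the sharpness boundary — sizes at which every experiment
completes in seconds while the stochastic rates are stable to well under
their margins. All generators and experiments are pure functions of their
seeds (sub-seeds via `SeedSequence`, kept below 2³¹).

## Known limitations

* The detector is offline (whole-file μ/σ); a streaming variant would need
  a windowed threshold, deliberately out of scope.
* The calibration factor is speed-specific: it was derived at ~0.44 m/s,
  where drift compensation systematically truncates; at higher speeds the
  deficit shrinks and the factor should be re-fitted.
* Projection parameters are config, not inferred; using coordinates from a
  different zone than the active spec silently shifts the track.
* ACM cannot measure scan displacement, only its period; speed classes
  must come from external measurement when needed.
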