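# branchnav

Smartphone sensor fusion for field phenotyping of coffee trees: georeference
individual trees from GPS-seeded inertial dead reckoning, and trim + quality-
screen branch-scan videos so only sharp frames reach downstream fruit
detection.

Consumer GPS places a point with an error of ±2.5–5 m — larger than the
0.5 m planting distance in a dense coffee parcel — so positions taken from
the handset's GPS alone cannot tell neighboring trees apart. `branchnav`
implements a two-mode pipeline for hand-held smartphone recordings (100 Hz
IMU logs, 1080p/30 fps video):

* **Navigation Mode (NM)** — dead reckoning between trees. Static periods
  are detected per channel by comparing a windowed local-maxima envelope of
  the signal magnitude against a dynamic threshold
  `THD = μ(Mag) + K·σ(Mag)`, floored at the idle-noise ceiling. Linear
  acceleration, masked to movement, is integrated to velocity with
  zero-velocity updates (ZUPT); the residual drift inside each movement is
  removed as a straight line `ε̂ = m·t` anchored at zero and at the spurious
  final velocity (`v_comp = v − ε̂`, so every movement ends at exactly 0).
  Displacement is the integral of the compensated velocity, scaled by a
  global calibration factor (default 1.4735, re-estimable by through-origin
  regression). Headings come from the azimuth corrected by the site's
  magnetic declination (`θ = Azimuth − DM`, default DM = −6.13°), steps are
  rotated into Gauss-Krüger plane coordinates
  (`ΔN = ΔY·cos θ + ΔX·cos(θ+90)`, `ΔE = ΔY·sin θ + ΔX·sin(θ+90)`) and
  accumulated from the GPS seed; the calibrated system reaches a ±0.15 m
  relative error per step, ±5.15 m worst-case total including the seed.

* **Acquisition Control Mode (ACM)** — video trimming and frame selection.
  The Y-axis angular velocity drives the same detector to find the single
  branch-scan movement; the video is trimmed to that period
  (`frame = round((t − t₀)·fps)`). Frames are then scored on the red channel
  inside three 100 px circular ROIs with three edge-energy indexes —
  `Idx_sobel = Σ√(Sx²+Sy²)`, `Idx_laplacian = Σ|∇²I|`, and
  `Idx_canny = Σ canny|σ^3σ` (hysteresis limits at 1× and 3× the full-image
  σ) — and accepted when any ROI exceeds the operator's threshold
  (1,100,000 / 54,000 / 290,000). Accepted scans are down-selected to 20 %
  of the trimmed frames; if even the begin/middle/end QC frames are blurred
  the branch is flagged for re-acquisition.

A synthetic-data module generates walk traces, branch-scan traces and
branch-like images with ground truth, so the whole pipeline can be exercised
and scored without field recordings.

## Worked example

```bash
branchnav simulate walk --seed 3 --out demo   # synthetic 7-step walk + truth
branchnav nav --log demo/walk_3.csv --out demo/nav
```

prints

```json
{
  "n_samples": 4497,
  "n_segments": 7,
  "n_track_points": 8,
  "step_lengths_m": [0.467, 0.735, 0.978, 1.510, 2.239, 2.958, 3.767],
  "total_distance_m": 12.654,
  "warnings": []
}
```

(step lengths abbreviated to 3 decimals here for readability)

Seven movements were detected in the log (one per step of the simulated
walk over the 0.5–3.75 m course grid), and the track holds 8 georeferenced
points: the GPS seed plus one INS point per movement. The recovered
calibrated step lengths sit within a few centimeters of the true
0.5/0.75/1/1.5/2.25/3/3.75 m grid. `demo/nav/track.csv` and
`track.geojson` carry each point in both plane (N, E) and WGS84 (lat, lon)
coordinates with provenance; `run_log.json` records the config hash and
seed for bitwise reproduction.

```bash
branchnav budget            # -> 5.15   (5 m GPS seed + 0.15 m INS, meters)
branchnav evaluate --seed 1 # parameter-recovery summary on synthetic data
```

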