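# dyadtrack

3D posture tracking and gaze analysis for pairs of zebrafish (*Danio rerio*)
observed by three orthogonal cameras.

Modern rigs for fine-grained social behavior record a dyad of fish at high
frame rate from a top camera (`XY`) and two side cameras (`YZ`, `XZ`), and run
two detectors per recording: a multi-animal pose estimator that finds three
body points per fish and view (head tip, pectoral-fin center "pec", tail
base), and a top-view centroid tracker that carries individual identity
through the whole video. Neither detector knows how its per-frame outputs
correspond across cameras or to each other. `dyadtrack` implements everything
downstream of the detectors:

- **calibration** — five polynomial mappings fitted by ordinary least squares
  to a submerged 49-bead fixture of known geometry: image triplets → world
  coordinates and back (degree 2), and each pair of views → the third view
  (degree 3). The polynomial absorbs lens and refraction effects without an
  explicit camera model.
- **registration** — per-frame identity assignment across the three views by
  exhaustive search over the 4 candidate pairings (top view fixed as
  reference, each side view permuted), scored by the cross-camera
  reprojection cost: project a skeleton from two views into the third and
  back, and measure the mean pixel distance to the original detections. The
  lowest-cost pairing wins; frames costing more than 10 px are discarded.
- **fusion + reconstruction** — each registered skeleton takes the identity
  of the nearest top-view centroid (cut at 15 px, pec point vs. centroid),
  and body points seen in all three views are lifted to world coordinates
  (cm).
- **qc** — anatomical filters (head–pec ≤ 1.4 cm, pec–tail ≤ 2.5 cm), removal
  of identity swaps / single-fish jumps / single-point jumps by velocity
  thresholding, linear interpolation of gaps up to 7 frames, and
  Savitzky–Golay smoothing (order 2, window 9).
- **behavior** — gaze angles and the windowed gaze asymmetry

  ```
  A_gaze = |N_1→2 − N_2→1| / N_total
  ```

  where `N_i→j` counts frames in which fish *i* is oriented toward fish *j*
  within a ±20° cone and `N_total` the frames (2-minute windows by default)
  where both angles are computable. `A_gaze` ≈ 0 during mutual engagement
  and → 1 once a dominant individual does all the looking. Head-to-head
  distance and 2D gaze-angle histograms complete the analysis.
- **synthetic** — a ground-truthed generator for every input: smooth 3D dyad
  kinematics at 140 Hz in a 25 cm cage, exact polynomial cameras
  (~36 px/cm), the 49-bead fixture, and detector-style corruption (pixel
  noise, dropouts, head/tail confusion, identity-label swaps) with a full
  injection log used as the testing oracle.
- **io** — plain-CSV schemas for tracks, detections, centroids, beads and
  experiment metadata, plus JSON calibration models.

## Worked example

```python
import dyadtrack as dt

cfg = dt.SimConfig(seed=7, n_frames=8000, noise_sigma_px=1.0, pursuit_mode=True)
scene = dt.make_scene(cfg)                     # dyad + cameras + detections
model = dt.fit_calibration(dt.make_bead_fixture(cfg, scene.cameras))
tracks = dt.reconstruct_tracks(scene.frames(), model)   # register→fuse→3D→QC
cov = dt.coverage_summary(tracks)
win = dt.gaze_asymmetry_windows(tracks, window_s=2000 / 140.0)
```

which prints, for this seed:

```
calibration rms residuals: {'to_world': 6.35e-11, 'to_views': 7.59e-13,
 'view_map_XY': 2.25e-12, 'view_map_YZ': 1.09e-12, 'view_map_XZ': 8.47e-13}
frames: 8000, full: 8000, empty: 0
window at   0.0 s: A_gaze = 0.011 (N_1to2=35, N_2to1=13, N_total=2000)
window at  14.3 s: A_gaze = 0.036 (N_1to2=114, N_2to1=42, N_total=2000)
window at  28.6 s: A_gaze = 0.999 (N_1to2=1997, N_2to1=0, N_total=2000)
window at  42.9 s: A_gaze = 0.992 (N_1to2=2000, N_2to1=17, N_total=2000)
```

The residuals are at numerical zero because the synthetic cameras are exact
polynomials of the fitted degree; all 8000 frames reconstruct fully; and the
asymmetry switches from ≈0 to ≈1 at the injected pursuit onset halfway
through the recording — the dominance-establishment signature this statistic
is designed to detect.

The same pipeline is available from the shell:

```
dyadtrack simulate --seed 2 --out-dir data/
dyadtrack calibrate data/beads.csv data/model.json
dyadtrack reconstruct data/detections.csv data/centroids.csv data/model.json --out data/tracks.csv
dyadtrack qc data/tracks.csv --out data/tracks_qc.csv --report data/coverage.json
dyadtrack gaze data/tracks_qc.csv --out data/gaze.csv
```

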