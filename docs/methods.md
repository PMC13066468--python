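# Methods

This note documents the models, numerical choices and limitations behind
`dyadtrack`. Coordinates: world origin at the tank-floor center, right-handed
axes, units cm; pixel origin top-left, v pointing down, units px. The top
camera images (x, y), the side cameras (y, z) and (x, z).

## Polynomial calibration

Five maps connect the three views and the world frame, all fitted by
unregularized ordinary least squares on the full multivariate monomial basis
of total degree ≤ d (constant and all cross terms — cross terms absorb the
perspective and refraction coupling a pure per-axis polynomial cannot):

| map | inputs → outputs | degree |
|---|---|---|
| `to_world` | 6 image coords → (x, y, z) | 2 |
| `to_views` | (x, y, z) → 6 image coords | 2 |
| `view_map_T` (×3) | 4 source-view coords → 2 target coords | 3 |

Bead correspondences from all fixture orientations are pooled into a single
fit per map (the per-orientation world coordinates are known exactly, so
pooling only adds rows).

Numerics. Inputs are standardized (`x' = (x − μ)/σ` per variable) before
monomial expansion; the raw pixel-unit basis spans ~9 orders of magnitude
across degree-3 terms and destroys the conditioning of the normal equations.
`PolyMap.raw_coefficients()` undoes the standardization exactly (binomial
expansion) when coefficients must be compared against a generating model.
A second, structural point: the inputs of `to_world` and of the view maps
are image coordinates of one 3D scene, so they lie on a 3-dimensional
manifold inside R^6 or R^4 and the design matrix is rank deficient *by
construction*. Only the map's action on that manifold is identifiable — and
only that action is ever used. These fits therefore take the minimum-norm
least-squares solution (singular values below 1e-9 of the leading one
treated as the off-manifold null space), while `to_views`, whose inputs are
free 3D points, keeps a strict rank check and raises on genuinely degenerate
geometry (e.g. coplanar beads). Too few beads for a map's coefficient count
raises an explicit underdetermined-fit error naming the map.

Missing data: any non-finite input coordinate yields a missing output point
(propagated, never raised).

## Cross-camera registration

Detection order within a view is arbitrary, so each frame requires choosing
which detection in each view belongs to which identity slot. The top view is
the fixed reference (its detections define slots A and B) and the two side
views are permuted independently: 2 × 2 = 4 candidates for a full two-fish
frame, fewer when detections are missing (a one-detection view contributes
its two possible slot placements; an empty view contributes none).

Cost of a candidate: for each source camera s ∈ {YZ, XZ}, project each
skeleton from (XY, s) into the remaining side view via the view maps, then
from (XY, that prediction) back into s, and take the pixel distance between
the reprojected and the detected body points — averaged over present points,
then the two fish, then the two source cameras. A consistent pairing
reprojects onto itself (cost ≈ 0 up to noise); a swap in either side view
corrupts the chain and inflates the cost. Body points missing anywhere in
the chain are excluded from the average; if only one source camera is
scorable the average is over it alone; a candidate with no scorable point is
unscorable. Equal costs (within 1e-9 px) are broken toward the previous
frame's accepted assignment (temporal coherence suppresses spurious swaps),
then lexicographically. Winners costing more than `reg_cost_max_px` (10 px)
are kept for bookkeeping but their skeletons are nulled and flagged.

## Fusion and reconstruction

Whole-video identity comes from the top-view centroid tracker. Matching is
greedy by ascending pec–centroid pixel distance, one skeleton per centroid;
matches beyond `fuse_cost_max_px` (15 px) are rejected (the skeleton is
nulled and flagged against the nearest label). Greedy equals the optimal
2 × 2 bipartite assignment except in tie patterns, which the tests cover
against brute force. Reconstruction applies `to_world` to each body point
present in all three views; a point missing in any view is missing in 3D.
An optional mode first imputes a single missing view through the view maps,
but it is off by default — the released pipeline reconstructs only observed
pixels, and the default follows it.

## Quality control

Fixed stage order: registration/fusion cuts → anatomy filter → jump
detection → gap interpolation → smoothing. Jump detection must precede
smoothing, which would otherwise spread a teleport across its window and
hide the velocity spike.

* **Anatomy.** Head–pec spans > 1.4 cm or pec–tail spans > 2.5 cm (an adult
  fish is ~2.5 cm) are detector errors; both endpoints of the offending
  segment are nulled (there is no way to tell which endpoint is wrong) and
  flagged. Idempotent by construction.
* **Jumps.** Speeds are displacements between consecutive valid frames
  divided by the frame gap. A *fish* jumps when its whole-body speed — the
  displacement of the centroid of the body points present in both frames —
  exceeds `jump_speed_max_cm`; using the shared-point centroid rather than
  requiring every point to jump makes swap detection robust to the small
  head-to-head or tail-to-tail distances of closely interacting fish. Both
  fish jumping in the same frame is an identity swap (both nulled, flagged
  `ID_SWAP`); one fish alone is a single-fish jump; a single point exceeding
  the bound while its fish does not (typical head/tail misidentification
  during close contact) is nulled alone. `jump_speed_max_cm` defaults to
  1.4 cm/frame ≈ 5 body lengths per 9-frame smoothing window ≈ 200 cm/s:
  several times the fastest burst swims (~50–75 cm/s) yet far below any
  label exchange between fish ≥ 2 cm apart. It is a config value, never
  hard-coded.
* **Gaps and smoothing.** Per scalar coordinate, missing runs of ≤ 7 frames
  with valid samples on both flanks are filled by linear interpolation and
  flagged `INTERPOLATED`; boundary gaps and longer runs stay missing. Then a
  Savitzky–Golay filter (order 2, window 9, polynomial edge handling) runs
  on each contiguous valid segment at least one window long; shorter
  segments pass through. Order 2 reproduces quadratic motion exactly, and a
  unit impulse spreads over exactly 9 frames — both are tested.

Per-gap counting is per coordinate (the most permissive reading); coverage
reports count *full* frames (all three points, both fish, in 3D) and *empty*
frames (no point for either fish), plus per-flag attrition.

## Gaze analysis

The heading vector is pec → head in full 3D (a horizontal-projection mode is
provided; the choice matters little for fish swimming near-horizontally).
The gaze angle of fish i toward fish j is the angle between i's heading and
the vector from i's head to j's head, in [0°, 180°]; the target reference
point is the partner's head (the natural focus of aggressive attention).
A fish is "oriented toward" its partner within a ±20° cone. Windows are
non-overlapping 2 minutes by default (stride configurable); `A_gaze` uses
only frames where both angles are computable and is missing for empty
windows. Histograms are 36 × 36 over [0°, 180°]², normalized over counted
frames. The moving-average smoothing of asymmetry curves is presentation
only, never part of the statistic.

## Synthetic data

The generator emulates the recording rig, not any particular detector
internals: a 25 cm cubic cage inside a 40 × 40 × 44 cm tank, 140 Hz, fish of
body length 2.5 cm (head–pec 0.8 cm, pec–tail 1.7 cm, rigid), imaged at
36 px/cm (body ≈ 90 px) on 1280 × 1024 sensors.

* **Kinematics**: a smoothed correlated random walk — heading diffuses on
  the sphere (vertical component damped), speed jitters around a 7 cm/s
  cruise, cage walls reflect, and a per-frame turn-rate cap (0.25 rad) keeps
  marker motion continuous through bounces, as real bodies are. Soft
  repulsion keeps the pair ≥ 2 cm apart — the separation regime in which
  identity assignment is well-posed. Pursuit mode steers fish 1 toward
  fish 2's head after a switch frame, reproducing one-sided gaze statistics.
* **Cameras**: exact polynomials of the calibrated degrees — orthographic
  projections plus mild quadratic distortion (0.1 px at the volume edge),
  so parameter recovery and round-trip identities hold to numerical
  precision; an optional cubic "model mismatch" mode generates the nonzero
  residuals of a real rig.
* **Corruption**: independently switchable Gaussian pixel noise, per-point
  dropouts, head↔tail confusions, per-view detection-order shuffling, and
  persistent centroid-label swap toggles. Every injection is logged
  (frame, kind, view, fish, point), and the log is the oracle the QC tests
  re-estimate rates against.
* **Beads**: 49 beads on a 7 × 7 grid (3.5 cm pitch) at staggered
  non-coplanar heights, photographed in 4 orientations (rotations about the
  vertical axis) and pooled.

Everything is byte-reproducible per seed.

What passing tests on synthetic data do *not* show: real detections have
structured, correlated errors (occlusions during contact, view-dependent
confusion rates, centroid drift during crossings) that i.i.d. corruption
does not reproduce, and real calibration residuals (~px scale) come from
optics the polynomial only approximates. The synthetic results validate the
*logic* of registration, fusion, QC and the statistics — not field accuracy.

## Problem sizes

Verification runs use 300–10,000 frames for registration accuracy, 50,000
frames for corruption-rate recovery, and 5,000–12,000 frames for pipeline
coverage and gaze dynamics — large enough for binomial intervals of ~1e-3
on the injected rates while keeping the whole suite and the acceptance
script in the minutes range on one CPU.

## Known limitations

* Two animals only; the candidate enumeration generalizes combinatorially
  but is deliberately out of scope.
* No model-based imputation of long gaps; gaps > 7 frames stay missing.
* Behavior when the centroid tracker reports a single merged blob during
  close contact is unspecified upstream; such frames fall through to the
  jump filters.
* The numeric jump-speed threshold and the gaze-angle geometry (3D vs.
  top-view, target point) are package choices where the field's practice
  varies; both are exposed as parameters.
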