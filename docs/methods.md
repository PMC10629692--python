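# Methods

This note documents the models, estimators, conventions and numerical
choices behind `flyhull`, and what the synthetic validation does and does
not establish.

## Frames and angle conventions

The lab frame is right-handed with z up. Images have their origin at the
top-left pixel, x right, y down. The body frame is x_b forward (tail to
head), y_b left, z_b up; yaw/pitch/roll follow the Z–Y′–X″ sequence with
positive pitch nose-up. The stroke plane passes through the body CM with
normal n_sp obtained by rotating x_b by −45° about y_b. Wing stroke angle
φ is the azimuth of the span within the stroke plane measured from
body-backward (so the front stroke is the φ maximum, and φ = 90° points
the span straight sideways); elevation θ = asin(s·n_sp); wing pitch ψ is
the rotation of the chord about the span, zero when the chord lies in the
stroke plane pointing forward and +90° when the leading edge points up
out of the plane. Left/right conventions are mirror-symmetric, and the
forward (pose) and inverse (extraction) maps are exact inverses to 1e−9
degrees, which the test suite sweeps. Absolute zero references are this
package's own; validation quantities are error SDs after removing each
angle's median error, which absorbs any constant convention offset
(computed circularly, so an opposite chord-sign convention — a 180°
offset — is absorbed too).

## Camera model and rig presets

Each camera is a single 3×4 DLT-style projection matrix; no lens
distortion (synthetic data needs none; real data should be
pre-undistorted). Presets aim all cameras at a common point: `cartesian3`
along the lab axes; `pyramidal3` an azimuthally symmetric triplet whose
optical axes are mutually orthogonal, which fixes the elevation at
atan(1/√2) ≈ 35.26°; `pyramidal4` four-fold symmetric at the same
elevation; `hybrid4` the pyramidal triplet plus a vertical camera. The
focal length in pixels is distance/pixel_pitch, so `pixel_pitch` is the
pixel footprint at the working volume. The reference configuration uses
256×256 px at 30 µm per pixel — a 7.7 mm field of view sized to a
hovering fly's ~6.5 mm extent, as one would size real optics to the
tracking volume.

Continuous pixel coordinates are rounded half-away-from-zero; carving
results depend on this and the renderer and carver share it.

## Synthetic fly and renderer

The body is a triaxial ellipsoid (length 2.5 mm, width and height
1.2 mm); each wing is a planar fruit-fly-like outline (span 2.5 mm, max
chord 1.0 mm) hinged at 0.55 body lengths from the tail, laterally and
dorsally offset. An optional linear spanwise twist turns each wing into a
strip-faceted surface for deformation experiments. Wingbeat kinematics
are harmonic: φ = 90° ± 70° at 220 Hz, θ a ±12° double-frequency
oscillation, ψ = 90° ± 45°, left/right mirrored; 73 frames per wingbeat.

Rendering is analytic per-pixel ray casting: the body as a quadric, wing
facets as plane-polygon intersections; a pixel is foreground iff the ray
through its center hits a surface. This yields the same binary images a
z-buffered rasterizer would produce, plus exact per-part depth and
nearest-surface labels used as occlusion ground truth. Rendering is
deterministic; the optional noise toggle is off everywhere in validation.

The silhouette of a zero-thickness wing in a near-edge-on view is a
~1 px line, and rounding a voxel-center projection can step off it. The
only set a visual hull is guaranteed to contain at pixel size p is the
object eroded by ~0.71 p — empty for a plane. The ground-truth
voxelization oracle therefore treats the two parts differently: body
voxels (interior, one-pitch margin) must be contained *exactly*; wing
surface voxels are asserted as a coverage fraction (≥90% on non-occluding
poses), matching what silhouette carving can promise.

## Segmentation

Two-pass occupancy: pixels present in ≥85% of a centered wingbeat window
are provisional body; frames are aligned on the provisional 2D CM
(integer shifts — sub-pixel shifts would break binary masks), occupancy
is re-summed and re-thresholded, and the mask is shifted back. The window
is user-set or estimated as the first prominent peak of the
overlap-normalized autocorrelation of the foreground pixel count (the
first peak, not the argmax: all multiples of the period tie). Edge frames
use a truncated, renormalized window. Because occupancy summing smears
the boundary when the body moves or rotates within the window, the final
mask is regrown by one pixel *inside the instantaneous full-fly
silhouette*, whose edge is exact; this halves the lateral jitter of the
body axis. Wing pixels are the remaining foreground.

## Hull reconstruction

The voxel grid is a cube of side 2.8 wing lengths centered on the body CM
triangulated from the per-view 2D CMs, at a pitch of one pixel footprint
(30 µm); the origin snaps to the pitch lattice so a stationary fly reuses
cached voxel projections (projecting the grid once per camera dominates
carving cost). Voxels projecting outside an image count as not seen and
are excluded. Carving, the eight expanded wing hulls, the four expanded
body hulls, the ≥2-vote majority body hull and the union-minus-body
combined wing hull are evaluated as boolean algebra over cached
projections; because every part mask is a subset of its view's full-fly
mask, all part hulls are evaluated on the full hull's voxels only, which
is algebraically identical to carving the whole grid. Property tests
check every one of these against brute-force per-voxel oracles.

Wings merged into a single connected component in a view share that
view's expanded hull. The 3D split uses k=2 k-means seeded with the
previous frame's wing CMs (first frame: the extreme voxels along a
provisional lateral axis), with left/right identity from the previous
CMs or the lateral sign; a cluster separation under two pitches flags the
frame as merged.

## Wing geometry

The ladder follows strip → tip → span → chord → reprojection → edges →
deformation:

* strip: hull voxels 0.40–0.65 wing lengths from the body CM (one widened
  attempt at 0.35–0.70, flagged);
* tip: farthest voxel, refined to the centroid of the cone base (apex at
  the wing CM, axis along the provisional span, half-angle 30°, base
  beyond 0.8 of the maximal radial extent) — the centroid sits slightly
  inside the outline tip, a constant bias that cancels in angles;
* initial chord: k=2 clustering of the strip, orthogonalized against the
  span; one re-cut of the strip perpendicular to the updated span;
* reprojection: the wing hull's rounded pixels per camera, morphologically
  closed once — these include pixels occluded by the body or other wing
  in that view;
* LE/TE: boundary pixels split by the image line through the projected
  wing CM along the projected span, the leading side given by the
  projected tip velocity (held through stroke reversal, where tip motion
  is pitch-dominated); views with projected span < 3 px are dropped;
  edge masks are dilated 2 px before carving (thin curves from different
  views barely intersect) and restricted to a one-voxel shell of the
  wing hull;
* local chords: the span is divided into equal radial bins (5 by
  default); per bin the chord runs between the *extreme-slab* endpoints
  of the edge bands along the chord axis. The hull of a thin plate is
  pinched exactly at the plate's edges — every camera's back-projected
  silhouette band is bounded by rays through them — so extreme voxels
  localize the true LE/TE, whereas band centroids are displaced inward by
  the dilation and hull wedge;
* final span/chord: a plane-filtered pinch refinement on the wing hull
  (voxels within 3 pitches of the least-squares wing plane; 10 spanwise
  bins; endpoint slabs of 1.2 pitches; chord averaged over stations
  0.20-0.85, away from the curved root and tip arcs; per-bin pinch
  endpoints; the mid-chord points' principal axis re-anchors the span,
  removing the chordwise bias of the strip CM — the planform is
  asymmetric about the hinge–tip line — and the weighted mean endpoint
  difference gives the chord). The iteration needs a starting chord axis
  within ~45°, which the previous frame's chord provides; the same-frame
  edge chord can be contaminated by the other wing near stroke reversal.
  The refinement is rejected (falling back to the earlier stages) when it
  moves the span by >15° or the mid-chord line residual exceeds 2
  pitches.

The chord's global sign is resolved after the event: continuity segments
(broken where consecutive chords rotate >35°/frame, beyond any
physiological pitch rate) each take the sign voted by their
fast-translating frames (leading edge leads: c·v > 0), weighted by speed
capped at the 90th percentile — a robust scale, since one tip-tracking
glitch can make the raw maximum arbitrary.

### Hull-anisotropy correction of the body axis

The visual hull of the body is fatter along directions no camera cuts;
those directions are fixed in the rig frame, so as the body rotates the
head/tail-blob axis is pulled toward a rig-anchored attractor — on the
reference rig an ~11% shrinkage of the estimated yaw, a gain error that a
constant offset cannot absorb. The pipeline removes it by simulation
through the identical carve: a reference spheroid, with semi-axes
estimated from the body hull's own PCA spectrum (for a uniform ellipsoid
the coordinate variance along a principal axis is a²/5), is rendered and
carved at a sample of the estimated orientations; the axis estimator's
error there is interpolated over frames and subtracted. The correction
assumes only that the body is approximately spheroidal; it is on by
default and configurable off.

## Kinematics

y_b is sampled once per back-stroke at the instant each wing's span is
most perpendicular to x_b (averaging ±2 frames), as the mirror average
(s_L − s_R)/2 projected ⊥ x_b; samples are interpolated with a monotone
cubic and held constant outside the sampled range, where body roll is
structurally unresolved (flagged). Body rates use the rotation-vector
central difference log(R_{k+1} R_{k−1}ᵀ)/2Δt expressed in the body frame;
accelerations a further central difference; series are unsmoothed.
Wingbeats are delimited at back-stroke minima of the mean stroke angle
with a minimum separation of half the dominant period.

## Quality flags and validation accounting

Frames are flagged by ground-truth-free criteria: missing/merged wing
hulls, a wing hull outside 0.3–1.8× the event's median size (either half
of a broken partition flags both wings), chord rotations above
30°/frame with short excursions bridged, gimbal poses, and the
lateral-axis extrapolation range. The validation report excludes flagged
frames from each angle's error SD and reports the counts; on the
reference run ~20% of frames are excluded, concentrated at stroke
reversals where the wings nearly touch.

## Reference validation conditions

10 wingbeats × 73 frames, hybrid rig at 256², 30 µm pixels; hovering body
with maneuvering oscillations (yaw ±8° over 10 beats, pitch 45±5° over 8,
roll ±4° over 12 — peak rates ~1000°/s, the scale of free-flight
saccades); default wingbeat kinematics; exact calibration and noise-free
silhouettes. Against this ground truth the pipeline's error SDs are
~1.0° in φ, ~1.2° in θ, ~1.9° in ψ and ≤0.35° in the body angles. Because
the inputs are clean, these numbers measure the geometric information
content of four 256² silhouette views — they do not include calibration
error, sensor noise, legs, or non-planar real wings, so accuracy on real
data will be bounded below by them, not equal to them.

## Known limitations

* Zero-thickness wings make edge-on views geometrically ambiguous at the
  pixel scale (see the voxelization discussion above).
* Spanwise-twist magnitudes from the local chords are reliable only when
  every camera axis is well off the wing plane (>=15 deg): a camera near
  the wing plane removes that view's pinch constraint and the recovered
  twist compresses toward zero. For a prescribed 20 deg linear twist the
  well-conditioned poses recover 20-26 deg, but the median over a full
  wingbeat is ~12 deg; per-wingbeat twist magnitudes should therefore be
  read qualitatively at this resolution.
* Frames around the dorsal/ventral stroke reversals, where the wings
  nearly touch, are the dominant failure mode; they are flagged rather
  than silently interpolated.
* The method assumes two wings and no long appendages; insects with
  prominent legs would add occlusions the expanded hulls do not model.
* Body roll is observable only once per back-stroke; events shorter than
  one wingbeat cannot estimate it.
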