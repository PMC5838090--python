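# Methods

This note documents the models, estimators and design choices behind
`spraymode`, the assumptions they rest on, and what the synthetic
benchmark does and does not demonstrate about real recordings.

## Recording model and units

A recording is described by an `AcquisitionGeometry`: field of view
(mm), image size (px), frame rate (Hz), working distance `d_wd` (mm,
capillary tip to target) and the tip's pixel position along the
propagation axis.  The pixel calibration is the mean of the width- and
height-derived values (µm/px); configurations whose two values disagree
by more than 2% are rejected as non-square-pixel optics.  Axial
coordinates are measured in mm beyond the tip, increasing toward the
target; the image orientation is configurable (`propagation_axis`
`"col"` or `"row"`).  Volumes are picolitres internally (1 pl =
1000 µm³) and nanolitres in group tables; velocities are m/s.

Closed-form calculators: delivery time `t_d = V/(dV/dt)`; sucrose
osmolarity as molarity × 1000 (sucrose does not dissociate; molar mass
342.30 g/mol, so 12.67 g/100 ml → 370 mOsm); detection-limit volumes
from the pixel cutoff area under a spherical or ellipsoidal shape.

## Detection

The background is the per-pixel temporal median of an evenly spaced
frame subsample (≤ 50 frames): a droplet occupies any one pixel in far
fewer than half of the frames, so the median is unaffected by the
spray.  The noise level σ is estimated robustly (1.4826 × MAD) from the
*signed* difference image — the absolute difference has a folded
distribution whose MAD underestimates σ by ~40% — and estimated once
per sequence, the sensor noise being stationary.  Foreground pixels are
`|frame − background| > k·σ` with k = 4 by default; the absolute value
makes the detector polarity-agnostic (bright droplets on dark
background or shadowgraphy).  8-connected components below the 10-pixel
cutoff are discarded.  Each surviving component yields an
intensity-weighted sub-pixel centroid, its pixel area, its extent along
the propagation axis, and a focus proxy: the mean gradient magnitude
over the component's boundary pixels.

At 4σ the per-pixel false-positive rate is ~3 × 10⁻⁵; isolated noise
exceedances never form 10-pixel components, so blank frames yield no
detections.  A thresholded edge crosses the threshold where the edge
profile equals k·σ of contrast; when that sits near 50% of the droplet
contrast the measured area is an unbiased estimate of the projected
area (the synthetic renderer's default contrast/noise is chosen in that
regime; on real data `threshold_k` should be set with the same
consideration).

## Trajectory linking and splitting

Blobs are linked frame-to-frame by greedy nearest-neighbour assignment:
candidate pairs within a gating radius (`max_velocity/frame_rate`,
20 m/s → 2 mm per frame by default) and without backward axial motion
beyond 1 px are taken in order of increasing distance, ties broken by
smaller area difference.  Once a trajectory has two observations it
also gates on **motion coherence**: a candidate's displacement must lie
within [med/2.5 − 5 px, 2.5·med + 5 px] of the trajectory's median
per-frame displacement.  Droplets fly at constant velocity over the
few-millimetre observation span, so an order-of-magnitude displacement
jump is an identity switch (typically a trajectory ending at the target
capturing another droplet's blob), not motion.

In-flight fission is recognised in two ways: (i) when a droplet image
vanishes and ≥ 2 unassigned blobs appear inside its gate, and (ii) when
a continuation plus unassigned in-gate blobs jointly account for the
parent's area.  In both cases a split requires the children's summed
area to lie within ±30% of the parent's (area conservation as a proxy
for volume conservation — two spherical fragments of a 60/40 split
project ~125% of the parent's area, inside the band) and each child to
be at most 80% of the parent's area (fission produces strictly smaller
fragments; without this, two crossing droplets with coincidentally
matching areas get misread as a split).  Children start new
trajectories carrying `parent_id`.

Greedy linking equals the exhaustive minimal-total-distance assignment
in the sparse regime the method is designed for — droplet separations
exceeding twice the per-frame displacement.  In denser scenes greedy
(like any distance-only tracker at this frame rate) becomes genuinely
suboptimal; the oracle-equivalence check is therefore defined over
sparse scenes, and dense sprays are a stated limitation.

## Qualification and records

A trajectory qualifies only if its first appearance lies *before* the
ROI (the band from 25% to 87.5% of the working distance beyond the
tip) and its last appearance *beyond* it; split children inherit the
root ancestor's entry position.  Note the exit test is phase-sensitive
for fast droplets: at 10 kHz a 14 m/s droplet advances 1.43 mm per
frame, so only ~1/3 of such droplets happen to be observed inside the
0.5 mm band between ROI exit and target.  Kinematic qualification is
thus strongly velocity-selective — a property of the evaluation rules,
not of any implementation.

The focal filter keeps trajectories whose *median* observation
sharpness lies within ±40% of the sequence's in-focus reference (the
95th percentile of all blob sharpness); the median is robust to
single-frame dips from noise or transient overlaps.  With the
renderer's defocus model the ±40% band corresponds to roughly ±0.25 mm
about the focal plane — half of the ~0.5 mm focal depth.  On synthetic
data an exact mode filters on the true `|z_offset| ≤ 0.25 mm` instead.

Each qualified trajectory with ≥ 2 observations yields one record:
volume from the first observation (droplets are nearest the focal plane
when emitted), velocity from the displacement between the last two
observations (speed at impact).  Records outside the reliable window —
velocity above 20 m/s or volume at or below the 4.2 pl floor — are
dropped.  Two tracking-artifact guards apply to trajectories with ≥ 3
observations: if the impact velocity differs from the trajectory's
median per-frame speed by more than 2× either way the record is
discarded (a mislinked final frame fabricates the impact velocity), and
if the first observation's area exceeds 1.5× the trajectory's median
area (two droplets overlapping at entry) the volume is taken at the
earliest area-consistent observation instead.

## Volumetry

The droplet is modelled as an ellipsoid of revolution about the
propagation axis: axial semi-axis a = (axial extent)/2, lateral
semi-axis b = A/(πa) so the projected ellipse area matches the measured
area, and V = (4/3)πab².  When the projection is a circle this is
exactly the sphere volume, and the model reproduces both detection
limits (10 px at 5.6 µm/px → 4.2 pl sphere of r = 10 µm, or 2.1 pl
prolate ellipsoid with semi-axes 20 and 5 µm).  V scales as A²/a — it
*decreases* with axial extent at fixed area — and as the cube of the
pixel size.  Measurements with b/a outside [1/10, 10] are flagged as
implausible.  No correction is made for motion blur elongating the
axial extent at high velocity; at 10 kHz with short exposure this is a
documented, uncorrected bias.

## Grouping

Replicate record sets (three sequences per condition in the reference
protocol) are concatenated and clustered with Lloyd's algorithm —
greedy-k-means++ seeding, best of 10 restarts by within-cluster sum of
squares, empty clusters re-seeded from the farthest point, objective
asserted non-increasing per iteration — on z-scored features.  Volume
enters as the equivalent-sphere **diameter** (∝ V^1/3) by default:
droplet sizes are conventionally compared on the diameter scale, and
raw volume makes Euclidean k-means split the heavy right tail of the
dominant group into a spurious cluster while log-volume over-compresses
genuinely separate large-droplet groups (`volume_scale` offers `raw`
and `log` as alternatives).  k is the silhouette argmax over 2…6 (ties
toward smaller k), with a single group reported when the best mean
silhouette is below 0.5 — a reproducible replacement for visual
inspection of silhouette plots.  Groups are reported in descending
fractional volume with sample sds (n−1; 0 for singletons); V_g sums
member volumes exactly and V_% sums to 100 within rounding.

## Synthetic spray generator

`sample_ensemble` draws, per group, log-normal volumes (moment-matched
to the group mean/sd) and truncated-normal velocities (floor
0.2 m/s) until the group's cumulative volume reaches its share of the
total; emission times are uniform (steady-state spray), entry is at the
tip with a Gaussian lateral spread, the distance from the focal plane
is Gaussian (sd 0.15 mm, placing most droplets within the focal depth),
and a configurable fraction of droplets (5% by default) splits once
mid-flight into two children with volume shares summing to one.
`render_frames` draws each droplet as a supersampled anti-aliased
ellipse whose projected area matches its volume under the volumetry
model, advected by `v/frame_rate` per frame and removed at impact,
convolved with a Gaussian of 25 µm sd per mm of defocus, plus Gaussian
sensor noise (sd 16 at a droplet contrast of 130 on 8-bit, i.e.
SNR ≈ 8 and the 4σ threshold near half contrast), quantised to 8 or 16
bits.  A ground-truth table gives per droplet and frame the true
centroid, projected area, volume, velocity and defocus.

`fractions_basis` selects the population the group specification
describes.  With `"emitted"` (default) it applies to every generated
droplet.  With `"evaluable"` droplets are drawn conditioned to be
kinematically evaluable (volume above the detection floor, velocity
within the trackable maximum, emission phase such that the observed
frames traverse the ROI).  Reference spray-mode tables are statistics
of *evaluated* droplets, and because qualification is strongly
velocity-selective (see above) only the evaluable ensemble makes such a
table recoverable by the pipeline: an emitted-basis ensemble would have
its fast group under-represented ~3× among the records before any
measurement error enters.

## Benchmark conditions and what they show

The parameter-recovery benchmark generates the two-group 3.0 kV
reference condition (1.4 ± 1.5 nl at 2.9 ± 1.3 m/s with 95% of the
volume; 0.2 ± 0.4 nl at 14.3 ± 3.5 m/s with 5%) as 0.2 s sequences at
full resolution (992 × 600, 5.6 µm/px, ~330 droplets per sequence,
lateral spread 0.7 mm, splits off so the recovered populations are
exactly the two specified groups), runs the complete pipeline, and
takes medians over 20 seeds.  Typical recovery: k = 2 in every seed,
group centroids within ~5–10% of the generating means, fractional
volumes within ~1 point of 95/5.  Full resolution matters for the small
group: at half resolution the 10-px cutoff corresponds to ~34 pl, which
truncates the 0.2 nl group's distribution and shifts its recoverable
mean by +25% regardless of implementation.  The sequences are kept
sparse because overlapping droplet images merge into single connected
components and break trajectories size-selectively; the method (like
the evaluation rules it implements) assumes separable droplet images.

What passing these checks does *not* show about real recordings:
real sprays have non-Gaussian backgrounds, illumination drift, droplet
oscillation and rotation (the renderer's droplets are rigid ellipsoids
of fixed aspect ratio), correlated sensor noise, lateral velocity
components in the cone, and unknown true volumes.  The benchmark
validates the estimator chain under a known forward model, not the
forward model itself.

## Numerical choices and degenerate inputs

Determinism: every stochastic step (sampling, rendering, k-means
restarts) takes an explicit seed; records are put in a canonical order
before clustering so results are invariant to input permutation;
re-running a pipeline on identical inputs reproduces outputs
byte-for-byte.  Degenerate inputs raise: empty stacks, k > n, fewer
than 3 records for silhouette selection, single-observation
trajectories at velocity evaluation, flow rate ≤ 0, inconsistent
ellipsoid axes (> 5%), anisotropic pixels (> 2%).  Silhouette ties
break toward smaller k; the empty-cluster rule re-seeds from the
farthest point; the Lloyd iteration asserts monotone descent and stops
on label stability.

## Known limitations

- Greedy linking degrades in dense sprays (see above); no global or
  multi-hypothesis assignment is attempted.
- No overlapping-blob separation beyond connected components; merged
  droplet images cost trajectories of large droplets first.
- Axial-extent motion blur is uncorrected; volumes of the fastest
  droplets are biased slightly high in long-exposure recordings.
- Defocused sub-0.5-nl droplets measure ~5–10% small at the default
  threshold (blurred small disks erode at a fixed threshold).
- The sharpness-based focal filter maps onto a metric focal band only
  through the defocus-blur calibration; on real optics the band edge
  should be validated against a focus sweep.
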