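# Methods

This note documents the models and procedures implemented in `lumenflow`,
the parameter choices that matter, what the synthetic scenes do and do not
emulate, and the numerical conventions that make results reproducible.

## Geometry conventions

All modules share one coordinate convention: 0-based pixel coordinates,
pixel centers at integer coordinates, x rightward, y downward (raster
order).  The in-plane pixel size is isotropic and given in µm; times are in
seconds.  A pixel belongs to a polygon when its center lies inside
(even-odd rule); centers falling exactly on an edge are resolved
deterministically by nudging the test point by +10⁻⁹ px in x and y, so
left/top edges count as inside and right/bottom edges as outside.  Z-stacks
are flattened before analysis by maximum or sum projection; which of the two
is used is a required configuration choice, never a hidden default.

## Boundary band and apical compartment

The measurement geometry around a junctional ring is a user-supplied closed
polygon split into a fixed-width peripheral **boundary band** (default
0.5 µm — the junctional compartment) and the remaining **apical** interior.
The band is metric, not a pixel count: a pixel is band if its center lies
within the band width of the ROI perimeter.  Classification far from the
cut uses the Euclidean distance transform of the rasterized ROI (corrected
by half a pixel, since the transform measures distance to the nearest
*outside pixel center*, ~0.5 px beyond the boundary); pixels within ±2 px of
the cut are decided by their exact distance to the polygon boundary.  This
keeps the band isotropic and sub-pixel accurate at any pixel size: on a
disk the band-area fraction matches the annulus closed form
1 − (1 − w/R)² to better than 1%.  The image border counts as perimeter for
ROIs that touch it.  A band width smaller than the pixel pitch yields an
empty band (the correct limit), while a band consuming the whole ROI is an
error.

## Automatic thresholding

Otsu's method maximizes the between-class variance of the two classes
{≤ t, > t} over a 256-bin histogram spanning [min, max] of the analyzed
region (the 8-bit convention; the bin count is configurable).  The returned
threshold is a bin edge.  Ties — including floating-point near-ties, which
occur in flat-objective regions — resolve toward the lowest threshold
within a 10⁻¹⁰ relative tolerance, so independent implementations of the
same objective agree exactly.  A constant image has no two classes and is a
hard error rather than a silent threshold.  Thresholds are computed locally
(within the union bounding box of the analyzed ROIs, per channel), because
a whole-frame histogram is dominated by empty background.

## Scalar statistics

* **Dice–Sørensen**: 2|A∩B| / (|A|+|B|) on thresholded masks, in pixel
  areas.  Two empty masks are 0/0 and raise.
* **B/A ratio**: mean intensity over the band divided by mean over the
  apical mask.  The ratio is invariant to multiplicative gain but *not* to
  additive offsets (no background subtraction is applied by default; any
  subtraction is an explicit pipeline step).
* **Coefficient of variation**: sample standard deviation over mean within
  a mask (≥ 2 pixels, positive mean).
* **Whole-cell normalization**: division by the mean over a whole-cell
  mask; the normalized mean over that mask is exactly 1, so regional means
  read as fold change over the cell average.  B/A is invariant under it.
* **Line profiles**: bilinear interpolation sampled at 1 px arclength
  steps, averaged over an odd pixel width perpendicular to the local
  segment.

## Photoconversion recovery

A conversion event instantly relabels the protein inside a chosen region
from the green to the magenta channel; thereafter turnover replaces
converted protein with fresh unconverted protein at rate r (per second).
The readout is the per-frame ratio of *spatial means* between the converted
and unconverted half-ring regions — means, not sums, so hand-drawn halves
of unequal area compare fairly.  Under pure exchange the green ratio
follows 1 − e^(−r·(t − t_c)); the time to reach fraction q of the reference
(default 0.9) is found by linear interpolation between frames, so the
closed-form t90 = ln(10)/r is recovered to well within one frame interval.
A curve that never crosses returns NaN (a sentinel, not an exception).
Conversion time is an explicit input, never inferred from the data.  Group
comparisons use the trapezoidal area under each experiment's curve and a
classical two-sided pooled two-sample t-test (Welch's correction available
behind a flag, but the pooled test is the default reported).

## Particle image velocimetry

Displacement between consecutive frames is estimated per interrogation
window by mean-subtracted cross-correlation (FFT), integer peak plus a
three-point Gaussian fit through the peak and its neighbours (parabolic fit
as an option and as fallback where logs are undefined).  Frame-pair
cross-correlation is used deliberately: a single-frame autocorrelation has
no displacement sign and cannot produce directed flow maps.  Defaults
follow community practice — 32 px windows, 16 px overlap, search radius of
half a window, minimum first-to-second peak ratio 1.2 (the second peak is
sought outside a 3×3 exclusion zone around the first; both peaks are
measured above the correlation-plane minimum).  A window is **invalid** —
carrying NaN, never a fabricated vector — when it is near-constant, dimmer
than a configurable intensity floor, its peak lies on the search border, or
the peak ratio is below threshold.  For ring scenes the floor convention is
one quarter of the mean frame intensity, which removes empty-background
windows; on pure-noise frame pairs ~99% of windows are invalidated by the
peak-ratio criterion alone.  Verified accuracy on synthetic scenes: integer
shifts are exact at the integer-peak stage; sub-pixel shifts of 0.1–0.5 px
are recovered with RMSE ≤ 0.05 px.

**Radial decomposition.**  Velocities are decomposed about the compartment
center — by convention the centroid of the rasterized apical region —
into signed radial (positive = outward) and tangential components;
radial² + tangential² reconstructs speed² to machine precision.  Windows
at the center itself are invalid for radial purposes.  Temporal
aggregation mirrors how ring dynamics are reported: per-window radial
*displacement* summed over a 360 s span of ten 36-s pairs (both the sum
and the per-pair average are emitted, since either can be colour-encoded),
and the mean radial *velocity* over all valid windows in non-overlapping
2-minute bins.  Arrow maps anchor arrows at window centers with drawn
length twice the actual displacement (display only; the data columns are
unscaled) and colour equal to the signed radial velocity on a symmetric
diverging scale centred at zero (warm = outward, cool = inward, grey =
invalid).

PIV-recovered rotation carries an intrinsic radial bias of order ω·δ (δ the
offset of the dominant texture from the window center); at the rotation
preset's 0.1 rad/frame this is ~9% of the mean speed.  The decomposition
itself is exact; the bias is a property of window-based attribution and is
why decomposition identities are checked on analytic fields.

## Synthetic scenes

Scenes are rendered from point particles ("clusters") at floating-point
positions, convolved with an isotropic Gaussian as a PSF proxy and
integrated over each pixel (erf-based), so sub-pixel motion is encoded
faithfully.  Noise is scaled-Poisson shot noise (variance = gain × mean)
plus additive Gaussian read noise, clipped at zero.  One RNG stream per
scene is seeded from the scene seed, with per-frame substreams derived
deterministically, so scenes are bit-reproducible and partially
re-renderable.

Default conditions mirror the imaged system: 160×160 px at 0.1 µm/px, 36 s
frame interval, a ring of outer radius 4 µm with a 0.8 µm thick junctional
band around a quieter interior, channel 0 carrying 85% of its intensity in
the band (junctional marker) and channel 1 mostly interior (apical marker),
particle-peak SNR well above 5.  Three generator choices matter enough to
state explicitly:

1. **Punctate, heterogeneous rings.**  140 clusters with ±50% brightness
   spread by default.  A dense uniform ring is tangentially
   translation-symmetric, which blinds correlation PIV (the aperture
   problem); real junctional cadherin is punctate and uneven, and that
   texture is what PIV locks onto.
2. **Balanced half-rings.**  Band clusters are placed with
   stratified-random angles and brightness paired antithetically across
   opposite strata, so the two halves of any diameter split carry equal
   total material to ±1 cluster.  The half-ring relative-intensity readout
   presumes comparable halves; without this balance the recovery asymptote
   is biased by sampling noise at desk-scale particle counts (the
   photoconversion preset uses 400 clusters, ±30% spread).
3. **Detachment episodes as contractile pulses.**  In the mutant-like
   regime, scheduled episodes stall ring expansion globally while boundary
   clusters in the episode's angular sub-regions (60–120° sectors) move
   inward at 0.015 µm/s; detached clusters then rest in the apical
   interior, and successive episodes strike different sub-regions.  The
   quiet baseline is outward band expansion at 0.003 µm/s
   (0.004 µm/s in the wild-type-like preset, interior static).  These
   speeds put per-pair displacements (1–5.4 px) squarely in the PIV
   accuracy zone and make every scheduled episode an unambiguous negative
   2-minute bin while quiet bins stay positive.

Photoconversion is modelled as a two-pool system per particle.  By default
each converted particle's green/magenta intensity weights follow the
ensemble expectation of memoryless exchange (magenta fraction
e^(−r·(t−t_c))), which makes pool-level readouts exact at any particle
count; a stochastic mode (`stochastic=True`) flips discrete labels at
exponentially distributed times instead, and converges to the same curves.

The B/A parameter-recovery configuration (`allocation_params`) uses a disk
ROI with the equal-area band width w = R(1 − 1/√2) and keeps clusters a
0.3 µm (3σ) margin away from the band/interior cut and the ROI perimeter,
so PSF blur does not leak intensity between compartments; the measured B/A
then recovers f/(1−f) for an allocated band fraction f to within ~3%.

**What the scenes do not emulate** — and hence what passing tests do not
show about real data: optical anisotropy and depth-dependent PSFs, uneven
illumination and photobleaching, membrane background that moves with the
tissue, cell shape change and ring deformation (rings stay circular; flows
are radially symmetric within sectors), particle birth/death, and any
mechanistic coupling between contractility and motion (flows are
prescribed kinematics, not mechanics).  Statistics validated here on
parameter recovery still face those confounds on microscopy data.

## Pipeline and reproducibility

A run is described by one YAML file, validated before any computation; each
violation names the offending field.  Bundles contain tidy CSVs (RFC-4180,
'.' decimal), PNG maps, a log recording every parameter actually used, the
configuration echoed verbatim, and a SHA-256 manifest.  Runs are
deterministic given config + seed; non-empty output directories are
refused unless forced.  Problem sizes throughout the test-suite and the
acceptance script (160×160 scenes, 11–21 frames, 10–20 seeds per sweep)
were chosen as the smallest at which the recovered parameters are stable
against Monte-Carlo noise.

## Known limitations

* Single-pass PIV only: no iterative window deformation, so strong shear
  within a window invalidates rather than resolves it (visible as dropped
  windows at detachment-sector edges).
* The band partition assumes a simple (non-self-intersecting) ROI polygon;
  touching or overlapping rings must be drawn as separate ROIs.
* Recovery analysis assumes the denominator region keeps positive mean
  signal; fully bleached references are an error, not a value.
* The pooled t-test treats experiments as independent; per-embryo nesting
  (mixed effects) is out of scope.
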