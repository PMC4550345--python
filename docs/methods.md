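# Methods

## Coordinate and intensity conventions

All modules share one convention: x runs along columns, y along rows,
origin at the top-left, y increasing downward, 0-based pixel centers at
integer coordinates. Luminance is real-valued on the [0, 255] scale and is
never requantized to 8 bits inside the pipeline; medians over ROIs would
otherwise pick up rounding bias. 16-bit inputs are rescaled by 255/65535 at
load time.

RGB images collapse to luminance with `red_only` by default: the reader's
610 nm long-pass emission filter confines the quantum-dot signal to the red
sensor channel, so the red plane maximizes signal-to-background. `rec601`
(0.299 R + 0.587 G + 0.114 B) and `equal` ((R+G+B)/3, the ImageJ default)
are available for generic images.

## Layout model

The canonical chip is 6 rows x 8 columns = 48 spots: 6 replicates each of
RBST, IGF1_100 and IGF1_250, and 15 each of POS and NEG. 6x8 is the unique
small rectangle for which 48 spots admit a controls-only outer ring (24
ring spots = 12 POS + 12 NEG) while leaving 3 POS + 3 NEG inside the 24-spot
inner rectangle alongside the 18 biomarker spots. Within those constraints
the exact per-position arrangement is a package choice: POS at all four
corners (well-spread affine anchors), POS/NEG alternating along the ring,
biomarkers in three column-pairs of the first three inner rows, and the six
inner controls alternating along the last inner row. Any other arrangement
satisfying the invariants can be supplied as a YAML/JSON layout file; the
loader validates every invariant and reports the first violation.

Standardized reference geometry: pitch 40 px on both axes, origin (30, 30),
ROI ellipse semi-axes (12, 9) px. The 12:9 aspect mirrors the 400 x 600 um
printed spot shape scaled to the pitch; the semi-axes must stay below half
the pitch so adjacent ROIs cannot overlap.

## Detection

"Illuminating" pixels are selected by a threshold, then grouped by
8-connected component labeling (diagonal-touching pixels of a blurred spot
belong together); components below a minimum area — default 25% of the
ellipse-ROI pixel count, i.e. layout-relative — are discarded. Blob
centroids are unweighted means of member pixel coordinates, and blobs are
ordered by (y, x) so downstream results are independent of labeling order.

Three threshold methods exist: `fixed` (pixel >= value), `otsu`, and the
default `quantile`. The default quantile is adaptive twice over: its floor
is 1 − 1.5x the expected spot fraction (total ROI area over image area),
which tracks how much of the frame the array fills and is invariant to
global brightness shifts from variable LED intensity; it is then raised to
the fraction of pixels below the midpoint between the background level
(image median) and the bright peak (99.5th percentile). The second rule
matters on sparsely lit chips — when only the 15 controls fluoresce, the
occupancy quantile alone lands inside the smooth background and produces
large spurious background components that can out-compete a true corner
anchor. The quantile comparison is strict (>) so a threshold landing
exactly on a flat background level yields an empty mask rather than a full
one.

Anchor matching targets POS positions only (NEG spots are background-level
by design). The four blobs extreme in the four quadrant directions about
the blob-cloud centroid are assigned to the four corner POS positions
preserving orientation; ambiguity (two candidates within 1 px of the same
corner score, or non-distinct candidates) is a hard error rather than a
guess. A provisional affine fitted on those four pairs maps all blobs to
standardized coordinates, where remaining blobs greedily claim the nearest
unclaimed POS reference within 0.4x the minimum pitch — the gate that
keeps bright biomarker spots (a full pitch away) from pairing with POS
references. All 15 POS positions are candidate anchors: the 3 inner POS
add interior support to the quadratic fit. Unmatched references are
allowed, which is what makes the pipeline survive occluded anchors.

## Geometric correction

Both fits map detected image coordinates to reference coordinates.
`estimate_affine` solves the two independent 3-parameter linear
least-squares problems (SVD-based); `fit_quadratic` does the same over the
6-term monomial basis and reduces exactly to the affine when the data are
affine. Resampling inverts the fitted map: closed-form for the affine;
for the quadratic, per-pixel Newton iteration seeded at the affine-part
inverse (tolerance 1e-6, max 20 iterations), with failure of more than 1%
of pixels reported as a non-invertible warp. Interpolation is bilinear by
default (nearest available for exact integer-shift checks); coordinates
mapping outside the input fill with 0, the dark-background assumption of
fluorescence imaging.

The standardized canvas keeps its origin at standardized (0, 0) and extends
0.75 pitch beyond the last grid line, so warped spot centroids land exactly
on the reference centroids and quantification needs no coordinate
bookkeeping. After the affine warp the positive controls are re-detected in
the corrected image before the quadratic fit: residual curvature is small
and unambiguous post-affine, and detection in the corrected frame is what
makes the two-stage scheme self-correcting. The quadratic is fitted on POS
anchors only (guaranteed bright at every signal level).

## Quantification and normalization

Each spot's readout is the median luminance over all integer pixels inside
the ellipse at its reference centroid (even counts average the middle
pair). The median tolerates up to half the ROI being corrupted (saturated
or dead pixels). Aggregates (mean, sample SD with n−1 denominator, n) are
computed per role over the inner rectangle only: ring controls define the
grid, not the readout, so POS/NEG aggregates use the 3+3 inner controls and
each biomarker its 6 replicates. The SD is the between-replicate-spot
dispersion reported as the per-chip error bar.

Normalization subtracts the negative-control mean and divides by the
background-corrected positive-control span, so POS ↦ 1 and NEG ↦ 0 under a
single formula and blank samples can legitimately come out slightly
negative. The formula is invariant to any global gain/offset on the
luminances, which is exactly the property that makes chips comparable. A
chip whose positive-control mean does not exceed the background fails QC
outright (labelling did not work).

Replicate measurements of the same sample (different chip, different day)
are combined as the arithmetic mean reported to 3 decimals, rounding half
away from zero — the only rounding convention consistent with all four
published replicate averages. The mean is computed in decimal arithmetic on
the inputs' shortest decimal representation, because binary floats place
values such as mean(0.004, −0.007) at −0.001499…99 and would flip the
rounded third decimal.

## Synthetic scenes

The generator emulates what the phone camera sees, with exact bookkeeping
of where every spot ended up and what its true normalized value is:

- **Spots**: flat ellipses (contact-printed plateaus) at 1.25x the ROI
  semi-axes, Gaussian-blurred (sd 1.5 px) for realistic edges; per-role
  amplitudes default to POS 180, NEG 4, RBST 120, IGF1_100 60, IGF1_250 90
  luminance units, with per-spot overrides for occlusion experiments.
- **Aberration**: rotation/shear/scale/translation about the grid center
  plus a quadratic bow (dx += b_x (y−c_y)², dy += b_y (x−c_x)²); the
  constructor rejects bows strong enough to make the map non-invertible
  over the frame. The spot ellipses are drawn with their axes transformed
  by the affine linear part, and truth centroids are the exact forward-
  mapped reference centroids.
- **Background and noise**: base 20 plus a linear gradient and a mild
  vignette; additive Gaussian read noise (sd 3 — "night mode" amplification)
  plus signal-proportional Gaussian noise (scale 0.05) approximating shot
  noise; 8-bit quantization last. Signal goes to the red channel with 10%
  green bleed; background leaks partially into green and blue.
- **Ladder**: `scene_ladder(seed, n_chips, truth_range)` renders chips whose
  biomarker truth values span the range evenly, each with a randomized mild
  aberration (shear <= 8 deg, bow displacing corners <= 6 px, rotation
  <= 3 deg, scale 0.95–1.05, translation <= 10 px) — the regime the
  correction is designed for.

What the scenes do not emulate: the true lens point-spread function and its
field dependence, LED spectra and filter transmission, chip autofluorescence
texture, dust and fibers, JPEG compression, and hand-held motion blur.
Passing the recovery tests therefore demonstrates that the geometry and
quantification logic is correct under realistic spot contrast, aberration
and noise magnitudes — not that the pipeline is robust to every artifact a
field-collected image may contain.

## Problem sizes and numerical choices

The end-to-end recovery study uses 20 chips of 440 x 360 px with three
biomarker readouts each (60 truth/recovery pairs), which runs in seconds
while exercising every stage; rank checks on the fit designs use tolerances
scaled to the design magnitude; crop-window coordinates are rounded at 1e-6
before floor/ceil to absorb least-squares round-off; degenerate inputs
(blank images, constant images under Otsu, collinear anchor sources,
rank-deficient quadratic designs, ROIs off the image) raise stage-tagged
errors rather than propagating garbage.

## Known limitations

- One chip per image; no multi-array frames.
- No watershed splitting: merged anchor spots are an error condition, not a
  recoverable case.
- Grids presented upside-down are resolved only through the corner-
  orientation rule; a chip rotated ~90 deg will match corners to the wrong
  references and fail loudly at the residual/QC stage rather than being
  auto-rotated.
- Normalized luminance units are relative per-chip quantities; no absolute
  concentration calibration is attempted, and no treated/untreated decision
  threshold is provided.
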