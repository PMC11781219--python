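# Methods

This note documents the measurement models, the synthetic-data generator,
the numerical conventions, and the design choices where more than one
reasonable implementation existed.

## Coordinate and intensity conventions

Pixel coordinates are 0-based `(row, col)` with pixel centers at integer
coordinates, so pixel `p` covers `[p − 0.5, p + 0.5)`; this convention is
used identically by the renderer, the profiler, the distortion mapping and
the landmark bookkeeping. Images are 8-bit; all internal arithmetic is
float64 with a single quantization at the end of each pipeline stage. RGB
images are collapsed to intensity with Rec. 601 luma weights
(0.299, 0.587, 0.114) before profiling.

## Intensity profiles and extrema

`profile.sample_profile` samples along a user line with bilinear
interpolation. The `round(length) + 1` samples are spread evenly over the
full line — exactly 1 px steps on integer-length lines (where axis-parallel
width-1 profiles equal the raw pixel values), and within half a pixel of
1 px otherwise. Sampling both endpoints makes profiling symmetric under
line reversal, a property the test suite checks. An optional perpendicular
averaging band (`width_px`, default 1) trades noise against resolution;
band samples that leave the image use nearest-edge values.

Extrema come from prominence-filtered local maxima/minima
(`scipy.signal.find_peaks`, default prominence 5 gray levels — small
enough to keep genuine bar contrast near the resolution limit, large
enough to reject few-level noise ripples; exposed everywhere as
`min_prominence`). Where two same-kind extrema survive in a row, only the
more extreme one is kept, so the sequence strictly alternates peak/trough,
which the downstream pairing logic relies on.

## Resolution

A USAF-1951 element contributes three dark bars → three troughs, with two
interior peaks between them. Segmentation assigns consecutive trough
triples to elements in order along the line; fewer troughs than
`3 × n_elements` (blur has merged elements, or the line missed bars) is an
error rather than a silent misassignment, and surplus extrema are reported
as leftovers.

The pass criterion is `peak_level / trough_level ≥ 2`. The per-element
aggregation is the mean of its peaks over the mean of its troughs
(`strategy="mean"`); a stricter `worst-pair` strategy (dimmest peak over
brightest trough) is available because the manual procedure this
replicates is ambiguous about aggregation. Troughs are floored at 1 gray
level so black bars give a finite ratio; an element with no measurable
trough at all passes with a flagged infinite ratio. The reported limit is
the finest element that passed with *all coarser elements also passing*:
once an element fails, nominal passes at finer frequencies are aliasing
artifacts and are counted as anomalies, not limits.

## Depth of field

Pairs are (peak, immediately following trough), starting from the first
*full* peak — the first peak preceded by a trough in the sequence, which
excludes a clipped partial peak when the line starts mid-bar; if no full
peak appears among the first three extrema the user is asked to redraw the
line. A trailing unpaired peak is ignored.

`initial_range` = first full peak − adjacent trough; `range_check` =
`initial_range / 2`. The failure point is the first pair whose difference
drops below `range_check`, confirmed only if the following 20 pairs (the
validation window) are also below threshold; when fewer than 20 pairs
remain, all remaining pairs must be below threshold — the validated-tail
rule is otherwise undefined at the sequence end. Peaks strictly before the
failure pair (the failing peak excluded) divided by the ladder frequency
give DOF in mm; with no failure the count of all paired peaks gives an
explicit lower bound. Excluding the failing peak makes the estimate
half-open: on a ladder whose true contrast crossing sits exactly on a pair
boundary the measurement returns either the true value or one pair
(0.2 mm at 5 lp/mm) less, which is why the recovery tolerance is one line
pair.

## Color accuracy

sRGB↔CIELAB conversions go through scikit-image (IEC 61966-2-1 transfer,
D65 white, 2° observer — D65 matches the 6500 K illumination of the
enclosed test chamber this workflow targets). No chromatic-adaptation
transform is applied; measured and reference values are compared in the
same D65 space, a limitation flagged for users comparing captures across
illuminants. ΔE*ab is CIE76 (plain Euclidean distance); ΔC*ab drops the
L* term. Patch extraction averages the inner 50% (linear fraction,
centered) of each ROI to keep border bleed and gutter pixels out.

Two editable reference CSVs ship with the package: the widely published
CIELAB values of the classic 24-patch chart (neutral row marked
`white_balance` and excluded from the color mean), and a synthetic
18-color + 6-neutral layout standing in for low-cost paper targets whose
vendors publish no values. Some published chart colors sit outside the
sRGB gamut, so a synthetic chart cannot render them exactly;
`as_rendered_reference` passes a table through 8-bit sRGB and back to get
the display-achievable reference used by the closed-loop synthetic tests.
White-balance means are reported separately from color means so either
aggregation can be compared against third-party tools that are ambiguous
about the distinction.

## Distortion

`A1`, `B`, `A2` are Euclidean pixel distances between the paired
top/bottom landmarks; `percent = 100·((A1+A2)/2 − B)/B`, signed (barrel
negative). The printed form of the averaging step in some descriptions of
this statistic is garbled; the average of the two outer extents is the
SMIA-standard definition and is what is implemented. Landmarks are always
explicit user input (JSON or API); an optional helper snaps each point to
the darkest pixel within a 5 px window (ties broken toward the click) to
reduce click error — off by default, and it recovers the *line*, not
necessarily the intersection, since grid lines are uniformly dark.
Integer-pixel clicks bound the percent error by roughly `100 · 2 / B`
percentage points, which is the tolerance the click-quantization test
uses.

## The synthetic chart generator

The generator's purpose is closed-loop validation: every render returns a
`GroundTruth` record (bar centers and frequencies, the six ideal landmark
coordinates pre- and post-distortion, per-patch reference and effective
CIELAB values, the analytic contrast-failure position of a degraded
ladder).

Bar and grid charts are rendered with 4× supersampling and a box
downsample so fractional bar edges are reproducible across platforms.
USAF bars are vertical, all elements of a group laid out coarse→fine along
one row so a single horizontal line crosses every bar; per-element
white/black levels allow charts whose true limit of resolution is fixed by
construction (e.g. fine elements at 1.9:1 contrast). Frequencies beyond
the Nyquist limit of the requested scale are rejected with the offending
(group, element) named. Glass vs paper targets are modeled purely as
reflectance presets (255/0 vs 240/25) feeding one analysis path.

Degradations apply in a fixed order — blur → radial distortion → CIELAB
offset → noise — with the ground truth updated analytically at each step:

* **Blur**: uniform isotropic Gaussian, or a linear sigma ramp along the
  row axis emulating the progressive defocus of a tilted target. The ramp
  is applied as a per-output-row 1-D kernel (gather form) plus a matched
  horizontal pass.
* **Radial distortion**: one-term Brown–Conrady, `r → r(1 + k1·r²)` in
  coordinates normalized by half the image diagonal about the image
  center. Images are resampled through the Newton-inverted mapping; the
  six grid landmarks are mapped *forward* analytically, and a landmark
  leaving the frame is an error. Only the SMIA statistic is measured, so
  one term suffices.
* **CIELAB offset**: the whole image is shifted in Lab and clipped back to
  the sRGB gamut; effective patch values in the truth record become
  `reference + offset`.
* **Noise**: additive Gaussian from `numpy.random.default_rng(seed)`,
  clipped to [0, 255]; identical seed and spec give bit-identical output.

The ladder's ground-truth failure position is computed with a *discrete*
1-D model: the ideal ladder column (same supersampling and quantization as
the renderer) is convolved with the same per-row kernels, pair contrasts
are taken at in-bar sample extrema exactly as the measurement pairs them,
and the half-initial crossing is linearly interpolated between pair
midpoints. A continuous erf-series model
(`blurred_square_wave_contrast`) is kept as an analytic reference, but at
practical sampling rates (~8 px per line pair) discretization attenuates
contrast by several percent, which would bias the truth by more than the
recovery tolerance; the discrete model describes the image actually
rendered. `solve_blur_gradient_for_failure` root-finds the sigma ramp that
places the true failure at a requested position, which is how the recovery
tests construct ladders with failures at 3, 8, and 15 mm.

What the generator does *not* emulate: physically based PSFs, vignetting,
demosaicing, illumination non-uniformity, perspective error from imperfect
chart mounting. Passing the synthetic suite therefore demonstrates
correctness of the measurement algorithms, not robustness to every
real-capture artifact.

## Problem sizes in the validation suite

Validation charts are sized for sub-second rendering while keeping ≥ 8 px
per line pair (USAF group 1 at 36 px/mm; ladders at 40 px/mm with lengths
6–18 mm; a 5×5-line grid with 800 px between outer lines; the 24-patch
chart at 40 px patches). At these scales every tolerance above has
comfortable margin except the deliberately half-open DOF pair count, whose
worst case equals the stated one-line-pair tolerance.

## Batch runner

`report.run_suite` executes each configured test independently; one test's
failure is captured in the report and never aborts the others. Reports
embed the tool version, the exact validated configuration, and SHA-256
checksums of the input images, and round-trip losslessly through JSON; a
CSV summary carries one row per scalar metric. All randomness flows from
the single configured seed, and two runs of the same configuration are
identical apart from the timestamp.
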