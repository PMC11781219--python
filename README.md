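# lapqc

Image-quality validation for laparoscope cameras (and other small optical
imagers) from standard test-chart photographs: **resolution**, **depth of
field**, **color accuracy**, and **geometric distortion**, plus a synthetic
chart generator that makes every metric testable against known ground truth
without any captured images.

## Why

Low-cost laparoscopes built and serviced outside traditional optics labs
still need quantitative quality assurance before clinical use. The usual
workflow — manual intensity-profile reading in a GUI, or commercial
image-quality software — is slow, costly, and hard to reproduce. `lapqc`
implements the four semi-automated analyses as a tested Python library and
CLI. The workflow stays deliberately *semi*-automated: the user supplies
the measurement geometry (a line through a chart group, six landmark
clicks, a patch layout), and the package does all subsequent arithmetic,
so every result is auditable from its inputs.

## The four measurements

**Resolution (USAF-1951 target).** A line drawn through a chart group
yields an intensity profile; each element contributes three dark bars
(troughs) separated by light gaps (peaks). An element resolves while the
peak/trough ratio stays ≥ 2:1; the limit of resolution is the finest
passing element, reported as frequency `f = 2^(group + (element−1)/6)`
lp/mm and line width `500/f` µm.

**Depth of field (5 lp/mm ladder).** Along a tilted ladder of line pairs,
the initial contrast is the first full peak minus its adjacent trough. The
failure point is the first (peak, trough) pair whose difference falls below
half the initial value — confirmed by requiring the next 20 pairs to stay
below threshold, so an isolated anomaly cannot trigger a false failure.
Peaks before the failure point ÷ 5 gives DOF in mm.

**Color accuracy (patch chart).** Per-patch mean RGB → CIELAB (sRGB
decoding, D65/2°), then against a reference table:
`ΔE*ab = √(ΔL*² + Δa*² + Δb*²)` (CIE76) and the luminance-blind
`ΔC*ab = √(Δa*² + Δb*²)`. White-balance patches are reported separately
and excluded from the color means.

**SMIA TV distortion (grid target).** From six user-selected landmarks —
the left, middle and right points of the top and bottom grid lines — the
vertical extents `A1`, `B`, `A2` give
`%distortion = 100 · ((A1+A2)/2 − B) / B`, signed: barrel negative,
pincushion positive.

The `chartgen` module renders all four chart types with machine-readable
ground truth and simulates the optics being measured: Gaussian defocus
(uniform or as a gradient along a tilted target), one-term Brown–Conrady
radial distortion, uniform CIELAB shifts, and sensor noise.

## Worked example

Render a USAF group-2 chart at 60 px/mm, defocused with a 3 px Gaussian
blur, and measure its limit of resolution:

```sh
lapqc generate usaf -o usaf.png --group 2 --px-per-mm 60 --blur 3.0
lapqc resolution usaf.png --line "49,0,49,493" --group 2
```

The report (abridged) shows each element's peak/trough levels and the 2:1
verdicts:

```
element  peak   trough  ratio   passed
G2E1     201.0   55.0   3.65    yes
G2E2     188.0   70.3   2.67    yes
G2E3     174.0   83.3   2.09    yes
G2E4     160.0   94.7   1.69    no
G2E5     149.5  106.7   1.40    no
G2E6     141.0  116.3   1.21    no

limit: G2E3  (5.04 lp/mm, 99.2 µm)
```

With 3 px of blur the camera resolves down to element 3 of group 2 — a
99.2 µm line width; the three finer elements no longer reach 2:1 contrast.

A depth-of-field measurement on a 9 mm ladder rendered with a 0→3.2 px
blur gradient:

```sh
lapqc generate dof_ladder -o dof.png --length-mm 9 --blur-gradient 0,3.2
lapqc dof dof.png --line "0,47.5,392,47.5"
```

```json
{"dof_mm": 4.6, "initial_range": 255.0, "range_check": 127.5,
 "failure_pair_index": 23, "peaks_before_failure": 23, "status": "failed_at"}
```

23 line pairs keep at least half the initial 255-level contrast before the
validated failure point: 23/5 = 4.6 mm of usable depth.

The same pattern works for `lapqc color` (patch layout + reference CSV →
ΔE*ab/ΔC*ab report and a reference-vs-measured swatch image) and
`lapqc distortion` (six landmarks → signed SMIA TV percent), and
`lapqc suite` runs any subset from one YAML config into a JSON + CSV QA
report. All commands are thin wrappers over `lapqc.resolution`,
`lapqc.dof`, `lapqc.colorimetry`, `lapqc.distortion`, `lapqc.chartgen`
and `lapqc.report`, which are importable directly.

## Limitations

Synthetic validation shows the *algorithms* recover known ground truth; it
does not exercise real-sensor effects (demosaicing, vignetting, uneven
illumination, compression). Chart detection is out of scope by design —
geometry is user-supplied. See `docs/methods.md` for models, parameter
choices, and numerical conventions.
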