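"""Synthetic optical test charts with machine-readable ground truth.

This module renders idealized versions of the four chart types used to
validate a laparoscope camera's imaging performance:

* a USAF-1951 three-bar resolution target,
* a square grid target for geometric (SMIA TV) distortion,
* a ColorChecker-style patch chart with known CIELAB values,
* a tilted-target line-pair ladder for depth-of-field measurement.

Each render returns a :class:`GroundTruth` record of what the image truly
contains (bar positions and frequencies, distortion landmark coordinates,
per-patch CIELAB values, the analytic contrast-failure position of a
degraded ladder), so the downstream metric engines can be validated end to
end without any physically captured images.  :func:`apply_degradation`
simulates the optical effects those engines are meant to measure: Gaussian
defocus blur (uniform or as a linear gradient along the optical axis of a
tilted target), one-term Brown-Conrady radial distortion, a uniform CIELAB
shift, and additive sensor noise.

Pixel coordinate convention, used consistently across the whole package:
0-based ``(row, col)``, pixel centers at integer coordinates, so pixel
``p`` covers the continuous interval ``[p - 0.5, p + 0.5)``.

Bar and grid charts are rendered with 4x supersampling followed by a box
downsample, which makes fractional bar edges reproducible across platforms.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, special
from skimage import color as skcolor

__all__ = [
    "UsafElementSpec",
    "UsafChartSpec",
    "GridChartSpec",
    "ColorPatchSpec",
    "ColorCheckerSpec",
    "DofLadderSpec",
    "DegradationSpec",
    "GroundTruth",
    "usaf_frequency_lp_mm",
    "usaf_line_width_um",
    "render_chart",
    "apply_degradation",
    "radial_forward_map",
    "blurred_square_wave_contrast",
    "dof_pair_contrasts",
    "dof_failure_position_mm",
    "solve_blur_gradient_for_failure",
    "usaf_chart",
    "grid_chart",
    "colorchecker_chart",
    "dof_ladder_chart",
    "PAPER_TARGET_LEVELS",
    "GLASS_TARGET_LEVELS",
]

_SS = 4  # supersampling factor for bar/grid rendering


def usaf_frequency_lp_mm(group: int, element: int) -> float:
    """Spatial frequency of a USAF-1951 element in line pairs per mm.

    The standard chart definition: ``2**(group + (element - 1)/6)``.
    """
    return 2.0 ** (group + (element - 1) / 6.0)


def usaf_line_width_um(group: int, element: int) -> float:
    """Width of a single bar of a USAF-1951 element in micrometers (500/f)."""
    return 500.0 / usaf_frequency_lp_mm(group, element)


# Reflectance presets: a chrome-on-glass target reaches the full dynamic
# range; a laminated paper print has a lower-contrast white and a lifted
# black.  Both feed the same analysis path.
GLASS_TARGET_LEVELS = (255, 0)
PAPER_TARGET_LEVELS = (240, 25)


# ---------------------------------------------------------------------------
# chart specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UsafElementSpec:
    """One USAF-1951 (group, element) to render, with its bar/background levels.

    ``white_level``/``black_level`` control the rendered contrast of this
    element only, which lets tests construct charts whose true limit of
    resolution is known by construction (e.g. fine elements drawn at a
    1.9:1 peak/trough ratio).
    """

    group: int
    element: int
    white_level: int = 255
    black_level: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError(f"USAF element must be in 1..6, got {self.element}")
        if not 0 <= self.black_level < self.white_level <= 255:
            raise ValueError("need 0 <= black_level < white_level <= 255")

    @property
    def frequency_lp_mm(self) -> float:
        return usaf_frequency_lp_mm(self.group, self.element)

    @property
    def line_width_um(self) -> float:
        return usaf_line_width_um(self.group, self.element)


@dataclass(frozen=True)
class UsafChartSpec:
    """Vertical-bar USAF chart: elements laid out left to right, coarse first.

    All bars span the same vertical band so a single horizontal line drawn
    at mid-height crosses every bar of every element, mirroring how a user
    draws one line through an entire group.
    """

    width_px: int
    height_px: int
    px_per_mm: float
    elements: tuple[UsafElementSpec, ...]
    margin_px: int = 12
    gap_mm: float = 0.75  # white gap between consecutive element blocks

    kind = "usaf"

    def __post_init__(self) -> None:
        _check_canvas(self)
        if not self.elements:
            raise ValueError("at least one element required")
        keys = [(e.group, e.element) for e in self.elements]
        if len(set(keys)) != len(keys):
            raise ValueError("usaf elements must be unique")
        for e in self.elements:
            # one line pair must span at least 2 px to be representable
            if self.px_per_mm / e.frequency_lp_mm < 2.0:
                raise ValueError(
                    f"element (group {e.group}, element {e.element}) at "
                    f"{e.frequency_lp_mm:.2f} lp/mm exceeds the Nyquist limit "
                    f"for {self.px_per_mm} px/mm"
                )


@dataclass(frozen=True)
class GridChartSpec:
    """Square grid of dark lines on white, for SMIA TV distortion."""

    width_px: int
    height_px: int
    px_per_mm: float
    spacing_px: float
    line_width_px: float = 3.0
    n_vertical: int = 5
    n_horizontal: int = 5
    margin_px: int = 20
    white_level: int = 255
    black_level: int = 0

    kind = "grid"

    def __post_init__(self) -> None:
        _check_canvas(self)
        if self.n_vertical < 3 or self.n_horizontal < 2:
            raise ValueError("grid needs >= 3 vertical and >= 2 horizontal lines")
        if self.spacing_px <= self.line_width_px:
            raise ValueError("spacing must exceed line width")


@dataclass(frozen=True)
class ColorPatchSpec:
    patch_id: str
    role: str  # "color" | "white_balance"
    lab: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.role not in ("color", "white_balance"):
            raise ValueError(f"unknown patch role {self.role!r}")
        if not 0.0 <= self.lab[0] <= 100.0:
            raise ValueError("L* must lie in [0, 100]")


@dataclass(frozen=True)
class ColorCheckerSpec:
    """Grid of uniform color patches with known CIELAB values (RGB render)."""

    width_px: int
    height_px: int
    px_per_mm: float
    rows: int
    cols: int
    patches: tuple[ColorPatchSpec, ...]  # row-major
    patch_px: int = 40
    gutter_px: int = 6
    margin_px: int = 10
    gutter_level: int = 20

    kind = "colorchecker"

    def __post_init__(self) -> None:
        _check_canvas(self)
        if len(self.patches) < 1:
            raise ValueError("at least one patch required")
        if len(self.patches) != self.rows * self.cols:
            raise ValueError("patch count must equal rows*cols")


@dataclass(frozen=True)
class DofLadderSpec:
    """Ladder of dark/light line pairs at a fixed spatial frequency.

    Emulates the 5 lp/mm region of a tilted depth-of-field target: the
    ladder runs along the image rows, each millimeter of ladder containing
    ``lp_per_mm`` (dark bar, light bar) pairs.  A pair starts with its dark
    bar.  An optional linear contrast ramp along the ladder (levels at the
    start vs the end) produces a chart whose half-initial-contrast failure
    position is known in closed form even without any blur.
    """

    width_px: int
    height_px: int
    px_per_mm: float
    length_mm: float
    lp_per_mm: float = 5.0
    margin_px: int = 16
    white_level: int = 255
    black_level: int = 0
    end_white_level: int | None = None  # contrast ramp target at ladder end
    end_black_level: int | None = None

    kind = "dof_ladder"

    def __post_init__(self) -> None:
        _check_canvas(self)
        if self.lp_per_mm <= 0 or self.length_mm <= 0:
            raise ValueError("lp_per_mm and length_mm must be positive")
        if self.px_per_mm / self.lp_per_mm < 2.0:
            raise ValueError(
                f"{self.lp_per_mm} lp/mm exceeds the Nyquist limit for "
                f"{self.px_per_mm} px/mm"
            )

    @property
    def period_px(self) -> float:
        return self.px_per_mm / self.lp_per_mm

    @property
    def n_pairs(self) -> int:
        # whole line pairs contained in the ladder
        return int(round(self.length_mm * self.lp_per_mm))


def _check_canvas(spec) -> None:
    if spec.width_px <= 0 or spec.height_px <= 0:
        raise ValueError("canvas dimensions must be positive")
    if spec.px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")


# ---------------------------------------------------------------------------
# degradation specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegradationSpec:
    """Parametric optical degradations, applied in the fixed order
    blur -> radial distortion -> CIELAB offset -> noise.

    ``blur_sigma_px``
        isotropic Gaussian defocus blur (0 disables).
    ``blur_gradient``
        ``(sigma_start, sigma_end)`` linear blur ramp along the row axis
        (row 0 -> last row), simulating the progressive defocus of a tilted
        target; mutually exclusive with ``blur_sigma_px``.
    ``k1``
        one-term Brown-Conrady radial distortion coefficient in coordinates
        normalized by half the image diagonal, centered at the image
        center; negative = barrel, positive = pincushion.
    ``lab_offset``
        ``(dL, da, db)`` added uniformly in CIELAB (RGB images only).
    ``noise_sigma``
        additive Gaussian sensor noise in gray levels, clipped to [0, 255].
    """

    blur_sigma_px: float = 0.0
    blur_gradient: tuple[float, float] | None = None
    k1: float = 0.0
    lab_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma_px < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise sigmas must be >= 0")
        if self.blur_gradient is not None:
            s0, s1 = self.blur_gradient
            if s0 < 0 or s1 < 0:
                raise ValueError("blur gradient sigmas must be >= 0")
            if self.blur_sigma_px > 0:
                raise ValueError("give either blur_sigma_px or blur_gradient")

    @property
    def is_identity(self) -> bool:
        return (
            self.blur_sigma_px == 0
            and self.blur_gradient is None
            and self.k1 == 0
            and self.lab_offset == (0.0, 0.0, 0.0)
            and self.noise_sigma == 0
        )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class UsafElementTruth:
    group: int
    element: int
    frequency_lp_mm: float
    line_width_um: float
    bar_center_cols: list[float]  # 3 dark-bar centers
    span_cols: tuple[float, float]  # block extent incl. white surround
    bar_rows: tuple[float, float]
    white_level: int
    black_level: int


@dataclass
class PatchTruth:
    patch_id: str
    role: str
    lab_ref: tuple[float, float, float]
    lab_effective: tuple[float, float, float]
    rgb_rendered: tuple[int, int, int]
    roi: tuple[int, int, int, int]  # r0, c0, r1, c1 (exclusive)


@dataclass
class DofTruth:
    lp_per_mm: float
    length_mm: float
    n_pairs: int
    ladder_rows: tuple[float, float]  # start/end row of the ladder
    profile_col: float  # suggested column for the measurement line
    levels_start: tuple[int, int]  # (white, black) at ladder start
    levels_end: tuple[int, int]
    failure_mm: float | None = None  # analytic half-contrast crossing


@dataclass
class GroundTruth:
    """What a rendered (and possibly degraded) chart truly contains."""

    kind: str
    chart: dict
    degradation: dict | None = None
    usaf_elements: list[UsafElementTruth] | None = None
    landmarks_pre: dict[str, tuple[float, float]] | None = None
    landmarks_post: dict[str, tuple[float, float]] | None = None
    patches: list[PatchTruth] | None = None
    dof: DofTruth | None = None

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        out = cls(kind=raw["kind"], chart=raw["chart"], degradation=raw.get("degradation"))
        if raw.get("usaf_elements") is not None:
            out.usaf_elements = [
                UsafElementTruth(
                    **{
                        **e,
                        "span_cols": tuple(e["span_cols"]),
                        "bar_rows": tuple(e["bar_rows"]),
                    }
                )
                for e in raw["usaf_elements"]
            ]
        for key in ("landmarks_pre", "landmarks_post"):
            if raw.get(key) is not None:
                setattr(out, key, {k: tuple(v) for k, v in raw[key].items()})
        if raw.get("patches") is not None:
            out.patches = [
                PatchTruth(
                    **{
                        **p,
                        "lab_ref": tuple(p["lab_ref"]),
                        "lab_effective": tuple(p["lab_effective"]),
                        "rgb_rendered": tuple(p["rgb_rendered"]),
                        "roi": tuple(p["roi"]),
                    }
                )
                for p in raw["patches"]
            ]
        if raw.get("dof") is not None:
            d = raw["dof"]
            out.dof = DofTruth(
                **{
                    **d,
                    "ladder_rows": tuple(d["ladder_rows"]),
                    "levels_start": tuple(d["levels_start"]),
                    "levels_end": tuple(d["levels_end"]),
                }
            )
        return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ss_coords(n_px: int) -> np.ndarray:
    """Continuous coordinates of supersample centers for n_px full-res pixels."""
    q = np.arange(n_px * _SS)
    return (q + 0.5) / _SS - 0.5


def _downsample(img_ss: np.ndarray) -> np.ndarray:
    h, w = img_ss.shape[0] // _SS, img_ss.shape[1] // _SS
    return img_ss.reshape(h, _SS, w, _SS).mean(axis=(1, 3))


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_chart(spec) -> tuple[np.ndarray, GroundTruth]:
    """Render an undegraded chart.

    Returns an 8-bit image (grayscale ``(H, W)`` for usaf/grid/dof_ladder,
    RGB ``(H, W, 3)`` for colorchecker) and its :class:`GroundTruth`.
    """
    if isinstance(spec, UsafChartSpec):
        return _render_usaf(spec)
    if isinstance(spec, GridChartSpec):
        return _render_grid(spec)
    if isinstance(spec, ColorCheckerSpec):
        return _render_colorchecker(spec)
    if isinstance(spec, DofLadderSpec):
        return _render_dof_ladder(spec)
    raise TypeError(f"unknown chart spec type {type(spec).__name__}")


def _spec_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    d["kind"] = spec.kind
    return d


def _render_usaf(spec: UsafChartSpec) -> tuple[np.ndarray, GroundTruth]:
    cols = _ss_coords(spec.width_px)
    canvas = np.full((spec.height_px * _SS, spec.width_px * _SS), 255.0)
    rows = _ss_coords(spec.height_px)
    r0, r1 = float(spec.margin_px), float(spec.height_px - 1 - spec.margin_px)
    row_mask = (rows >= r0) & (rows < r1)

    truths: list[UsafElementTruth] = []
    x = float(spec.margin_px)
    gap_px = spec.gap_mm * spec.px_per_mm
    for el in spec.elements:
        w = spec.px_per_mm * 0.5 / el.frequency_lp_mm  # single bar width, px
        x0 = x + w  # first bar edge (one bar-width of surround on each side)
        block = (cols >= x) & (cols < x0 + 5 * w + w)
        _fill(canvas, row_mask, block, el.white_level)
        centers = []
        for k in range(3):
            a = x0 + 2 * k * w
            bar = (cols >= a) & (cols < a + w)
            _fill(canvas, row_mask, bar, el.black_level)
            centers.append(a + w / 2.0)
        truths.append(
            UsafElementTruth(
                group=el.group,
                element=el.element,
                frequency_lp_mm=el.frequency_lp_mm,
                line_width_um=el.line_width_um,
                bar_center_cols=centers,
                span_cols=(x, x0 + 6 * w),
                bar_rows=(r0, r1),
                white_level=el.white_level,
                black_level=el.black_level,
            )
        )
        x = x0 + 6 * w + gap_px
    if x - gap_px + spec.margin_px > spec.width_px:
        raise ValueError(
            f"canvas width {spec.width_px} px too small for layout "
            f"(needs {math.ceil(x - gap_px + spec.margin_px)} px)"
        )
    img = _quantize(_downsample(canvas))
    return img, GroundTruth(kind="usaf", chart=_spec_dict(spec), usaf_elements=truths)


def _fill(canvas_ss: np.ndarray, row_mask: np.ndarray, col_mask: np.ndarray, level: float) -> None:
    canvas_ss[np.ix_(row_mask, col_mask)] = float(level)


def _render_grid(spec: GridChartSpec) -> tuple[np.ndarray, GroundTruth]:
    rows = _ss_coords(spec.height_px)
    cols = _ss_coords(spec.width_px)
    canvas = np.full((spec.height_px * _SS, spec.width_px * _SS), float(spec.white_level))
    hw = spec.line_width_px / 2.0

    v_pos = [spec.margin_px + k * spec.spacing_px for k in range(spec.n_vertical)]
    h_pos = [spec.margin_px + k * spec.spacing_px for k in range(spec.n_horizontal)]
    if v_pos[-1] + hw + 1 > spec.width_px or h_pos[-1] + hw + 1 > spec.height_px:
        raise ValueError("grid lines exceed canvas; enlarge canvas or shrink spacing")
    for c in v_pos:
        canvas[:, (cols >= c - hw) & (cols < c + hw)] = float(spec.black_level)
    for r in h_pos:
        canvas[(rows >= r - hw) & (rows < r + hw), :] = float(spec.black_level)

    mid = v_pos[len(v_pos) // 2]
    top, bottom = h_pos[0], h_pos[-1]
    landmarks = {
        "top_left": (top, v_pos[0]),
        "top_mid": (top, mid),
        "top_right": (top, v_pos[-1]),
        "bottom_left": (bottom, v_pos[0]),
        "bottom_mid": (bottom, mid),
        "bottom_right": (bottom, v_pos[-1]),
    }
    img = _quantize(_downsample(canvas))
    truth = GroundTruth(
        kind="grid",
        chart=_spec_dict(spec),
        landmarks_pre=landmarks,
        landmarks_post=dict(landmarks),  # identity until distortion is applied
    )
    return img, truth


def lab_to_srgb8(lab: Sequence[float]) -> tuple[int, int, int]:
    """CIELAB (D65/2deg) -> 8-bit sRGB with gamut clipping."""
    rgb = skcolor.lab2rgb(np.asarray(lab, dtype=float).reshape(1, 1, 3))
    return tuple(int(v) for v in np.rint(np.clip(rgb[0, 0], 0, 1) * 255))


def _render_colorchecker(spec: ColorCheckerSpec) -> tuple[np.ndarray, GroundTruth]:
    img = np.full((spec.height_px, spec.width_px, 3), float(spec.gutter_level))
    patches: list[PatchTruth] = []
    pitch = spec.patch_px + spec.gutter_px
    need_h = spec.margin_px * 2 + spec.rows * pitch - spec.gutter_px
    need_w = spec.margin_px * 2 + spec.cols * pitch - spec.gutter_px
    if need_h > spec.height_px or need_w > spec.width_px:
        raise ValueError(f"canvas too small for patch layout (needs {need_h}x{need_w})")
    for i, p in enumerate(spec.patches):
        r, c = divmod(i, spec.cols)
        r0 = spec.margin_px + r * pitch
        c0 = spec.margin_px + c * pitch
        rgb = lab_to_srgb8(p.lab)
        img[r0 : r0 + spec.patch_px, c0 : c0 + spec.patch_px] = rgb
        patches.append(
            PatchTruth(
                patch_id=p.patch_id,
                role=p.role,
                lab_ref=tuple(p.lab),
                lab_effective=tuple(p.lab),
                rgb_rendered=rgb,
                roi=(r0, c0, r0 + spec.patch_px, c0 + spec.patch_px),
            )
        )
    return _quantize(img), GroundTruth(kind="colorchecker", chart=_spec_dict(spec), patches=patches)


def _dof_levels_at(spec: DofLadderSpec, mm: np.ndarray | float):
    """(white, black) rendered levels at position mm along the ladder."""
    w1 = spec.white_level if spec.end_white_level is None else spec.end_white_level
    b1 = spec.black_level if spec.end_black_level is None else spec.end_black_level
    t = np.clip(np.asarray(mm, dtype=float) / spec.length_mm, 0.0, 1.0)
    white = spec.white_level + (w1 - spec.white_level) * t
    black = spec.black_level + (b1 - spec.black_level) * t
    return white, black


def _render_dof_ladder(spec: DofLadderSpec) -> tuple[np.ndarray, GroundTruth]:
    rows = _ss_coords(spec.height_px)
    cols = _ss_coords(spec.width_px)
    canvas = np.full((spec.height_px * _SS, spec.width_px * _SS), 255.0)

    r_start = float(spec.margin_px)
    length_px = spec.length_mm * spec.px_per_mm
    r_end = r_start + length_px
    if r_end + spec.margin_px > spec.height_px:
        raise ValueError("canvas height too small for ladder length")
    c0, c1 = float(spec.margin_px), float(spec.width_px - 1 - spec.margin_px)
    col_mask = (cols >= c0) & (cols < c1)

    mm = (rows - r_start) / spec.px_per_mm
    inside = (rows >= r_start) & (rows < r_end)
    phase = np.mod(mm * spec.lp_per_mm, 1.0)
    dark = phase < 0.5  # each pair starts with its dark bar
    white, black = _dof_levels_at(spec, mm)
    level = np.where(dark, black, white)
    canvas[np.ix_(inside, col_mask)] = level[inside, None]

    truth = GroundTruth(
        kind="dof_ladder",
        chart=_spec_dict(spec),
        dof=DofTruth(
            lp_per_mm=spec.lp_per_mm,
            length_mm=spec.length_mm,
            n_pairs=spec.n_pairs,
            ladder_rows=(r_start, r_end),
            profile_col=(c0 + c1) / 2.0,
            levels_start=(spec.white_level, spec.black_level),
            levels_end=(
                spec.white_level if spec.end_white_level is None else spec.end_white_level,
                spec.black_level if spec.end_black_level is None else spec.end_black_level,
            ),
        ),
    )
    truth.dof.failure_mm = dof_failure_position_mm(spec, sigma_of_row=None)
    return _quantize(_downsample(canvas)), truth


# ---------------------------------------------------------------------------
# analytic models used for ground truth
# ---------------------------------------------------------------------------


def blurred_square_wave_contrast(period_px: float, sigma_px: float) -> float:
    """Peak-minus-trough amplitude of a unit square wave after Gaussian blur.

    For a 50%-duty square wave of period ``p`` blurred with a Gaussian of
    standard deviation ``sigma``, the value at a light-bar center is
    ``m = sum_k Phi((p/4 - k p)/sigma) - Phi((-p/4 - k p)/sigma)`` and by
    symmetry the dark-bar center sits at ``1 - m``, so the remaining
    peak-to-trough contrast is ``2 m - 1`` (1 = unblurred, -> 0 as sigma
    grows).
    """
    if sigma_px <= 0:
        return 1.0
    p, s = float(period_px), float(sigma_px)
    ks = np.arange(-8, 9)
    upper = (0.25 * p - ks * p) / (s * math.sqrt(2.0))
    lower = (-0.25 * p - ks * p) / (s * math.sqrt(2.0))
    m = 0.5 * float(np.sum(special.erf(upper) - special.erf(lower)))
    return 2.0 * m - 1.0


def _ladder_column(spec: DofLadderSpec) -> np.ndarray:
    """The ideal ladder rendered as a single 1-D column (float gray levels).

    Uses the same supersample/box-downsample and 8-bit quantization as the
    full renderer, so it is sample-for-sample identical to any interior
    column of the rendered chart.
    """
    rows = _ss_coords(spec.height_px)
    r_start = float(spec.margin_px)
    r_end = r_start + spec.length_mm * spec.px_per_mm
    mm = (rows - r_start) / spec.px_per_mm
    inside = (rows >= r_start) & (rows < r_end)
    phase = np.mod(mm * spec.lp_per_mm, 1.0)
    white, black = _dof_levels_at(spec, mm)
    col = np.where(inside, np.where(phase < 0.5, black, white), 255.0)
    col = col.reshape(spec.height_px, _SS).mean(axis=1)
    return np.clip(np.rint(col), 0, 255)


def dof_pair_contrasts(
    spec: DofLadderSpec, sigma_of_row=None
) -> tuple[np.ndarray, np.ndarray]:
    """(midpoint mm, peak-trough contrast) for every (peak_k, trough_{k+1})
    pair of the ideal ladder column under the given per-row blur schedule.

    Pair ``k`` takes the brightest sample inside light bar ``k`` and the
    darkest sample inside the next dark bar, exactly mirroring how the
    measurement algorithm pairs each detected peak with its adjacent trough.
    This is a discrete model: it shares the simulator's blur kernel and
    sampling so the resulting ground truth describes the rendered image,
    not an idealized continuous chart.
    """
    col = _ladder_column(spec)
    h = spec.height_px
    if sigma_of_row is not None:
        sigmas = np.array([float(sigma_of_row(r)) for r in range(h)])
        col = _varying_row_blur(col[:, None], sigmas)[:, 0]
    r_start = float(spec.margin_px)
    p = spec.period_px
    mids, contrasts = [], []
    for k in range(spec.n_pairs - 1):
        light = np.arange(
            math.ceil(r_start + (k + 0.5) * p), math.floor(r_start + (k + 1.0) * p) + 1
        )
        dark = np.arange(
            math.ceil(r_start + (k + 1.0) * p), math.floor(r_start + (k + 1.5) * p) + 1
        )
        light = light[(light >= 0) & (light < h)]
        dark = dark[(dark >= 0) & (dark < h)]
        if light.size == 0 or dark.size == 0:
            break
        mids.append((k + 1) / spec.lp_per_mm)
        contrasts.append(float(col[light].max() - col[dark].min()))
    return np.asarray(mids), np.asarray(contrasts)


def dof_failure_position_mm(spec: DofLadderSpec, sigma_of_row=None) -> float | None:
    """Position (mm from ladder start) where pairwise contrast first falls
    below half the initial pairwise contrast, or None if it never does.

    The "initial" contrast is the first (full peak, adjacent trough) pair,
    one line pair into the ladder -- the same pair the measurement
    algorithm uses.  The crossing is linearly interpolated between pair
    midpoints, so the truth is continuous in the degradation parameters.
    """
    mids, contrasts = dof_pair_contrasts(spec, sigma_of_row)
    if contrasts.size == 0 or contrasts[0] <= 0:
        return None
    threshold = contrasts[0] / 2.0
    below = np.nonzero(contrasts < threshold)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(mids[0])
    x0, x1 = mids[i - 1], mids[i]
    c0, c1 = contrasts[i - 1], contrasts[i]
    return float(x0 + (c0 - threshold) / (c0 - c1) * (x1 - x0))


def solve_blur_gradient_for_failure(
    spec: DofLadderSpec, target_mm: float, sigma_start: float = 0.0
) -> DegradationSpec:
    """Find a linear blur gradient whose analytic contrast-failure position
    equals ``target_mm``, for constructing ladders with known ground truth.
    """
    if not 0.5 / spec.lp_per_mm < target_mm < spec.length_mm:
        raise ValueError("target failure must lie inside the ladder")
    h = spec.height_px

    def failure_for(s_end: float) -> float | None:
        sig = lambda row: sigma_start + (s_end - sigma_start) * row / (h - 1)
        return dof_failure_position_mm(spec, sig)

    def objective(s_end: float) -> float:
        f = failure_for(s_end)
        return (f if f is not None else spec.length_mm * 2) - target_mm

    # bracket: increase s_end until the failure point moves before target_mm
    lo, hi = sigma_start + 1e-3, max(1.0, sigma_start + 1.0)
    while objective(hi) > 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("could not bracket blur gradient")
    s_end = optimize.brentq(objective, lo, hi, xtol=1e-6)
    return DegradationSpec(blur_gradient=(sigma_start, float(s_end)))


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------


def radial_forward_map(
    points: np.ndarray, shape: tuple[int, ...], k1: float
) -> np.ndarray:
    """Forward one-term Brown-Conrady mapping of (row, col) points.

    Coordinates are normalized by half the image diagonal about the image
    center; an undistorted point at normalized radius r moves to
    ``r * (1 + k1 * r**2)``.
    """
    h, w = shape[0], shape[1]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rnorm = math.hypot((h - 1) / 2.0, (w - 1) / 2.0)
    pts = np.asarray(points, dtype=float)
    d = (pts - center) / rnorm
    r2 = np.sum(d * d, axis=-1, keepdims=True)
    return center + d * (1.0 + k1 * r2) * rnorm


def _radial_warp_image(img: np.ndarray, k1: float) -> np.ndarray:
    """Resample the image under the forward radial map (inverse warping)."""
    h, w = img.shape[:2]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rnorm = math.hypot((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dr = (rr - center[0]) / rnorm
    dc = (cc - center[1]) / rnorm
    r_d = np.hypot(dr, dc)
    # invert r_d = r_u (1 + k1 r_u^2) by Newton iteration from r_u = r_d
    r_u = r_d.copy()
    for _ in range(25):
        f = k1 * r_u**3 + r_u - r_d
        fp = 3.0 * k1 * r_u**2 + 1.0
        r_u = r_u - f / fp
    scale = np.where(r_d > 0, r_u / np.maximum(r_d, 1e-12), 1.0)
    src_r = center[0] + dr * scale * rnorm
    src_c = center[1] + dc * scale * rnorm

    def warp_plane(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(plane, [src_r, src_c], order=1, mode="nearest")

    if img.ndim == 2:
        return warp_plane(img)
    return np.stack([warp_plane(img[..., ch]) for ch in range(img.shape[-1])], axis=-1)


def _varying_row_blur(img: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """1-D Gaussian blur along the row axis with a per-output-row sigma
    (gather form, nearest-edge handling)."""
    h = img.shape[0]
    flat = img.reshape(h, -1).astype(float)
    out = np.empty_like(flat)
    for i in range(h):
        s = sigmas[i]
        if s < 1e-6:
            out[i] = flat[i]
            continue
        k = int(math.ceil(4 * s))
        idx = np.clip(np.arange(i - k, i + k + 1), 0, h - 1)
        w = np.exp(-0.5 * ((np.arange(-k, k + 1)) / s) ** 2)
        w /= w.sum()
        out[i] = w @ flat[idx]
    return out.reshape(img.shape)


def _gradient_blur(img: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """Gaussian blur whose sigma varies linearly along the row axis.

    Applied as two 1-D passes with the output row's sigma: a vertical
    gather pass and a matched horizontal pass, so the blur seen along a
    vertical profile follows exactly the per-row sigma schedule.
    """
    h = img.shape[0]
    sigmas = np.linspace(s0, s1, h)
    out = _varying_row_blur(img, sigmas)
    for i in range(h):
        s = sigmas[i]
        if s >= 1e-6:
            out[i] = ndimage.gaussian_filter1d(out[i], s, axis=0, mode="nearest")
    return out


def apply_degradation(
    image: np.ndarray, truth: GroundTruth, deg: DegradationSpec
) -> tuple[np.ndarray, GroundTruth]:
    """Apply optical degradations and update the ground truth to match.

    Order is fixed: blur -> radial distortion -> CIELAB offset -> noise.
    Grid landmark coordinates are recomputed through the analytic forward
    radial map; color-patch effective CIELAB values absorb the offset; a
    blurred dof ladder gets its analytic contrast-failure position.
    """
    truth = copy.deepcopy(truth)
    truth.degradation = dataclasses.asdict(deg)
    if deg.is_identity:
        return image.copy(), truth

    img = image.astype(float)

    if deg.blur_sigma_px > 0:
        sig = (
            (deg.blur_sigma_px, deg.blur_sigma_px, 0)
            if img.ndim == 3
            else deg.blur_sigma_px
        )
        img = ndimage.gaussian_filter(img, sig, mode="nearest")
    elif deg.blur_gradient is not None:
        img = _gradient_blur(img, *deg.blur_gradient)

    if deg.k1 != 0:
        img = _radial_warp_image(img, deg.k1)
        if truth.landmarks_pre is not None:
            post = {}
            h, w = image.shape[:2]
            for name, pt in truth.landmarks_pre.items():
                mapped = radial_forward_map(np.array(pt), image.shape, deg.k1)
                if not (0 <= mapped[0] <= h - 1 and 0 <= mapped[1] <= w - 1):
                    raise ValueError(
                        f"distortion maps landmark {name!r} outside the frame: "
                        f"{tuple(float(v) for v in mapped)}"
                    )
                post[name] = (float(mapped[0]), float(mapped[1]))
            truth.landmarks_post = post

    if deg.lab_offset != (0.0, 0.0, 0.0):
        if img.ndim != 3:
            raise ValueError("lab_offset requires an RGB image")
        lab = skcolor.rgb2lab(np.clip(img, 0, 255) / 255.0)
        lab += np.asarray(deg.lab_offset, dtype=float)
        img = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0) * 255.0
        if truth.patches is not None:
            for p in truth.patches:
                p.lab_effective = tuple(
                    float(a + b) for a, b in zip(p.lab_ref, deg.lab_offset)
                )

    if deg.noise_sigma > 0:
        rng = np.random.default_rng(deg.seed)
        img = img + rng.normal(0.0, deg.noise_sigma, img.shape)

    if truth.dof is not None:
        spec = _dof_spec_from_chart(truth.chart)
        if deg.blur_gradient is not None:
            s0, s1 = deg.blur_gradient
            h = image.shape[0]
            sigma_of_row = lambda row: s0 + (s1 - s0) * row / (h - 1)
        elif deg.blur_sigma_px > 0:
            sigma_of_row = lambda row: deg.blur_sigma_px
        else:
            sigma_of_row = None
        truth.dof.failure_mm = dof_failure_position_mm(spec, sigma_of_row)

    return _quantize(img), truth


def _dof_spec_from_chart(chart: dict) -> DofLadderSpec:
    fields = {f.name for f in dataclasses.fields(DofLadderSpec)}
    return DofLadderSpec(**{k: v for k, v in chart.items() if k in fields})


# ---------------------------------------------------------------------------
# convenience builders (auto-sized canvases)
# ---------------------------------------------------------------------------


def usaf_chart(
    group: int,
    elements: Sequence[int] = (1, 2, 3, 4, 5, 6),
    px_per_mm: float = 40.0,
    levels: tuple[int, int] = GLASS_TARGET_LEVELS,
    element_levels: dict[int, tuple[int, int]] | None = None,
    margin_px: int = 12,
    gap_mm: float = 0.75,
) -> UsafChartSpec:
    """Auto-sized chart spec for one USAF group.

    ``element_levels`` overrides (white, black) per element index, which is
    how charts with a constructed limit of resolution are built.
    """
    white, black = levels
    specs = []
    width = margin_px * 2.0
    for i, e in enumerate(elements):
        w_lvl, b_lvl = (element_levels or {}).get(e, (white, black))
        el = UsafElementSpec(group, e, white_level=w_lvl, black_level=b_lvl)
        specs.append(el)
        bar_w = px_per_mm * 0.5 / el.frequency_lp_mm
        width += 7 * bar_w + (gap_mm * px_per_mm if i < len(elements) - 1 else 0)
    coarsest = max(px_per_mm * 0.5 / usaf_frequency_lp_mm(group, e) for e in elements)
    height = int(math.ceil(2 * margin_px + max(10 * coarsest, 40)))
    return UsafChartSpec(
        width_px=int(math.ceil(width)) + 4,
        height_px=height,
        px_per_mm=px_per_mm,
        elements=tuple(specs),
        margin_px=margin_px,
        gap_mm=gap_mm,
    )


def grid_chart(
    n_lines: int = 5,
    spacing_px: float = 80.0,
    line_width_px: float = 3.0,
    px_per_mm: float = 10.0,
    margin_px: int = 30,
) -> GridChartSpec:
    side = int(math.ceil(2 * margin_px + (n_lines - 1) * spacing_px)) + 1
    return GridChartSpec(
        width_px=side,
        height_px=side,
        px_per_mm=px_per_mm,
        spacing_px=spacing_px,
        line_width_px=line_width_px,
        n_vertical=n_lines,
        n_horizontal=n_lines,
        margin_px=margin_px,
    )


def colorchecker_chart(
    patches: Sequence[ColorPatchSpec],
    rows: int = 4,
    cols: int = 6,
    patch_px: int = 40,
    gutter_px: int = 6,
    margin_px: int = 10,
    px_per_mm: float = 10.0,
) -> ColorCheckerSpec:
    pitch = patch_px + gutter_px
    return ColorCheckerSpec(
        width_px=2 * margin_px + cols * pitch - gutter_px,
        height_px=2 * margin_px + rows * pitch - gutter_px,
        px_per_mm=px_per_mm,
        rows=rows,
        cols=cols,
        patches=tuple(patches),
        patch_px=patch_px,
        gutter_px=gutter_px,
        margin_px=margin_px,
    )


def dof_ladder_chart(
    length_mm: float = 10.0,
    lp_per_mm: float = 5.0,
    px_per_mm: float = 40.0,
    width_px: int = 96,
    margin_px: int = 16,
    levels: tuple[int, int] = GLASS_TARGET_LEVELS,
    end_levels: tuple[int, int] | None = None,
) -> DofLadderSpec:
    height = int(math.ceil(length_mm * px_per_mm + 2 * margin_px)) + 1
    white, black = levels
    ew, eb = (None, None) if end_levels is None else end_levels
    return DofLadderSpec(
        width_px=width_px,
        height_px=height,
        px_per_mm=px_per_mm,
        length_mm=length_mm,
        lp_per_mm=lp_per_mm,
        margin_px=margin_px,
        white_level=white,
        black_level=black,
        end_white_level=ew,
        end_black_level=eb,
    )
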