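"""Color accuracy: per-patch and mean CIE76 color error against a reference
CIELAB table.

The color chart image is sampled patch by patch (mean RGB over the inner
region of each patch to avoid border bleed), converted to CIELAB (sRGB
decoding per IEC 61966-2-1, D65 white, 2 degree observer), and compared
with the reference table:

* ``dE*ab = sqrt(dL*^2 + da*^2 + db*^2)`` -- the Euclidean color error,
  including luminance (CIE76);
* ``dC*ab = sqrt(da*^2 + db*^2)`` -- the chroma-only error, which ignores
  luminance.

White-balance patches are summarized separately and excluded from the
color-error means.  No chromatic-adaptation transform is applied: measured
and reference values are compared in the same D65 CIELAB space, which users
comparing captures across illuminants should keep in mind.

Two reference tables ship with the package (editable CSV, columns
``patch_id, role, L, a, b``): the widely published CIELAB values of the
classic 24-patch chart, and a synthetic 18-color + 6-white-balance layout.
Users may supply their own table for other targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .chartgen import ColorPatchSpec

__all__ = [
    "LabColor",
    "PatchLayout",
    "PatchDiff",
    "ColorDiffResult",
    "srgb_to_lab",
    "lab_to_srgb",
    "extract_patches",
    "delta_e_ab",
    "delta_c_ab",
    "compare_to_reference",
    "swatch_image",
    "load_reference_csv",
    "load_reference_preset",
    "layout_from_truth",
    "REFERENCE_PRESETS",
]

REFERENCE_PRESETS = ("classic24", "paper18x6")


@dataclass(frozen=True)
class LabColor:
    """A CIELAB triple: L* luminance in [0, 100], a*/b* opponent axes."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class PatchLayout:
    """Rectangular patch ROIs in pixel coordinates.

    ``rois`` are ``(r0, c0, r1, c1)`` with exclusive ends, one per patch in
    reference-table order.  ``inner_fraction`` is the linear fraction of
    each ROI (centered) actually averaged, to keep patch-border bleed and
    gutter pixels out of the measurement.
    """

    rois: tuple[tuple[int, int, int, int], ...]
    inner_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_fraction <= 1.0:
            raise ValueError("inner_fraction must lie in (0, 1]")
        for roi in self.rois:
            r0, c0, r1, c1 = roi
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"empty ROI {roi}")

    def inner_roi(self, i: int) -> tuple[int, int, int, int]:
        r0, c0, r1, c1 = self.rois[i]
        mh = (r1 - r0) * (1.0 - self.inner_fraction) / 2.0
        mw = (c1 - c0) * (1.0 - self.inner_fraction) / 2.0
        ir0, ir1 = int(round(r0 + mh)), int(round(r1 - mh))
        ic0, ic1 = int(round(c0 + mw)), int(round(c1 - mw))
        return ir0, ic0, max(ir1, ir0 + 1), max(ic1, ic0 + 1)


@dataclass
class PatchDiff:
    patch_id: str
    role: str
    measured_rgb: tuple[float, float, float]
    measured_lab: LabColor
    reference_lab: LabColor
    delta_e: float
    delta_c: float


@dataclass
class ColorDiffResult:
    """Per-patch color differences plus means.

    Means are taken over the ``color`` patches; white-balance patches are
    reported separately (``mean_*_wb`` are None when the table has none).
    """

    patches: list[PatchDiff]
    mean_delta_e: float
    mean_delta_c: float
    mean_delta_e_wb: float | None
    mean_delta_c_wb: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patches:
            rows.append(
                {
                    "patch_id": p.patch_id,
                    "role": p.role,
                    "measured_L": p.measured_lab.L,
                    "measured_a": p.measured_lab.a,
                    "measured_b": p.measured_lab.b,
                    "reference_L": p.reference_lab.L,
                    "reference_a": p.reference_lab.a,
                    "reference_b": p.reference_lab.b,
                    "delta_e_ab": p.delta_e,
                    "delta_c_ab": p.delta_c,
                }
            )
        return pd.DataFrame(rows)


def srgb_to_lab(rgb) -> LabColor:
    """8-bit sRGB triple -> CIELAB (D65, 2 degree observer)."""
    arr = np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0
    L, a, b = skcolor.rgb2lab(arr)[0, 0]
    return LabColor(float(np.clip(L, 0.0, 100.0)), float(a), float(b))


def lab_to_srgb(lab: LabColor) -> tuple[int, int, int]:
    """CIELAB -> 8-bit sRGB with gamut clipping."""
    rgb = skcolor.lab2rgb(lab.as_array().reshape(1, 1, 3))
    return tuple(int(v) for v in np.rint(np.clip(rgb[0, 0], 0, 1) * 255))


def delta_e_ab(m: LabColor, r: LabColor) -> float:
    """CIE76 color difference: Euclidean distance in CIELAB."""
    return float(np.linalg.norm(m.as_array() - r.as_array()))


def delta_c_ab(m: LabColor, r: LabColor) -> float:
    """Chroma-only color difference: Euclidean distance in the (a*, b*) plane."""
    return float(np.hypot(m.a - r.a, m.b - r.b))


def extract_patches(image: np.ndarray, layout: PatchLayout) -> list[tuple[float, float, float]]:
    """Mean RGB of each patch over the inner sampling region of its ROI."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ValueError("color chart image must be RGB")
    h, w = img.shape[:2]
    means = []
    for i, roi in enumerate(layout.rois):
        r0, c0, r1, c1 = roi
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"ROI of patch {i} {roi} lies outside the {h}x{w} image")
        ir0, ic0, ir1, ic1 = layout.inner_roi(i)
        region = img[ir0:ir1, ic0:ic1, :3].reshape(-1, 3).astype(float)
        means.append(tuple(region.mean(axis=0)))
    return means


def compare_to_reference(
    image: np.ndarray,
    layout: PatchLayout,
    reference: pd.DataFrame,
) -> ColorDiffResult:
    """Measure per-patch and mean dE*ab / dC*ab against a reference table.

    ``reference`` needs columns ``patch_id, role, L, a, b`` in layout
    order; ``role`` is ``color`` or ``white_balance``.
    """
    _validate_reference(reference)
    if len(reference) != len(layout.rois):
        raise ValueError(
            f"reference table has {len(reference)} patches but layout has "
            f"{len(layout.rois)} ROIs"
        )
    measured = extract_patches(image, layout)
    patches: list[PatchDiff] = []
    for (_, row), rgb in zip(reference.iterrows(), measured):
        m = srgb_to_lab(rgb)
        r = LabColor(float(row["L"]), float(row["a"]), float(row["b"]))
        patches.append(
            PatchDiff(
                patch_id=str(row["patch_id"]),
                role=str(row["role"]),
                measured_rgb=rgb,
                measured_lab=m,
                reference_lab=r,
                delta_e=delta_e_ab(m, r),
                delta_c=delta_c_ab(m, r),
            )
        )
    color = [p for p in patches if p.role == "color"]
    wb = [p for p in patches if p.role == "white_balance"]
    if not color:
        raise ValueError("reference table contains no color patches")
    return ColorDiffResult(
        patches=patches,
        mean_delta_e=float(np.mean([p.delta_e for p in color])),
        mean_delta_c=float(np.mean([p.delta_c for p in color])),
        mean_delta_e_wb=float(np.mean([p.delta_e for p in wb])) if wb else None,
        mean_delta_c_wb=float(np.mean([p.delta_c for p in wb])) if wb else None,
    )


def swatch_image(
    result: ColorDiffResult, tile_px: int = 48, cols: int = 6
) -> np.ndarray:
    """Side-by-side reference/measured swatches for visual audit.

    Each patch becomes a tile whose left half shows the reference color and
    right half the measured color, laid out in reading order.
    """
    n = len(result.patches)
    rows = (n + cols - 1) // cols
    img = np.zeros((rows * tile_px, cols * tile_px, 3), dtype=np.uint8)
    half = tile_px // 2
    for i, p in enumerate(result.patches):
        r, c = divmod(i, cols)
        r0, c0 = r * tile_px, c * tile_px
        img[r0 : r0 + tile_px, c0 : c0 + half] = lab_to_srgb(p.reference_lab)
        img[r0 : r0 + tile_px, c0 + half : c0 + tile_px] = lab_to_srgb(p.measured_lab)
    return img


def _validate_reference(df: pd.DataFrame) -> None:
    missing = {"patch_id", "role", "L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    bad = set(df["role"]) - {"color", "white_balance"}
    if bad:
        raise ValueError(f"unknown patch roles: {sorted(bad)}")


def load_reference_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _validate_reference(df)
    return df


def load_reference_preset(name: str) -> pd.DataFrame:
    """Load a bundled reference table: ``classic24`` (the published CIELAB
    values of the classic 24-patch chart, neutral row as white-balance) or
    ``paper18x6`` (synthetic 18-color + 6-white-balance layout)."""
    files = {
        "classic24": "colorchecker_classic_24.csv",
        "paper18x6": "color_target_18_6_synthetic.csv",
    }
    if name not in files:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(files)}")
    with resources.files("lapqc.data").joinpath(files[name]).open("r") as fh:
        return load_reference_csv(fh)


def as_rendered_reference(reference: pd.DataFrame) -> pd.DataFrame:
    """Snap a reference table to what an 8-bit sRGB display can show.

    Some published chart colors (cyan, notably) fall outside the sRGB
    gamut, so a synthetic chart rendered from the table cannot reproduce
    them exactly; each Lab value is passed through 8-bit sRGB (with gamut
    clipping) and back, yielding the reference actually achievable in the
    rendered image.  Use this as the comparison table in closed-loop
    synthetic experiments; for physical captures keep the published table.
    """
    out = reference.copy()
    for i, row in reference.iterrows():
        lab = srgb_to_lab(lab_to_srgb(LabColor(row["L"], row["a"], row["b"])))
        out.loc[i, ["L", "a", "b"]] = (lab.L, lab.a, lab.b)
    return out


def reference_to_patch_specs(reference: pd.DataFrame) -> list[ColorPatchSpec]:
    """Turn a reference table into renderable chart patch specs."""
    return [
        ColorPatchSpec(
            patch_id=str(r["patch_id"]),
            role=str(r["role"]),
            lab=(float(r["L"]), float(r["a"]), float(r["b"])),
        )
        for _, r in reference.iterrows()
    ]


def layout_from_truth(truth, inner_fraction: float = 0.5) -> PatchLayout:
    """Patch layout taken from a synthetic chart's ground truth."""
    if truth.patches is None:
        raise ValueError("ground truth carries no patch information")
    return PatchLayout(
        rois=tuple(p.roi for p in truth.patches), inner_fraction=inner_fraction
    )
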