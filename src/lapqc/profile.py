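"""Intensity profiles along user-drawn lines, and their peak/trough sequences.

Both the resolution and depth-of-field engines consume the same substrate: a
"plot profile" of pixel intensity sampled along a line the user draws across
the chart, reduced to an alternating sequence of local maxima (white bars /
gaps) and minima (dark bars).  Sampling uses 1 px arc-length steps with
bilinear interpolation, optionally averaged over a perpendicular band, which
mirrors the ImageJ plot-profile behaviour the manual method relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "LineSegment",
    "IntensityProfile",
    "Extremum",
    "ExtremaSequence",
    "DEFAULT_MIN_PROMINENCE",
    "sample_profile",
    "detect_extrema",
    "to_luminance",
]

#: Default prominence (gray levels) below which local extrema are treated as
#: noise ripples rather than chart structure.
DEFAULT_MIN_PROMINENCE = 5.0

#: Rec. 601 luma weights used to collapse RGB input to a single intensity
#: channel before profiling (ImageJ's weighted RGB-to-gray conversion).
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LineSegment:
    """A measurement line in pixel coordinates.

    ``p0``/``p1`` are real-valued ``(row, col)`` endpoints; ``width_px`` is
    the perpendicular averaging band (1 = single-pixel line).
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    width_px: int = 1

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")
        if self.length == 0.0:
            raise ValueError("line endpoints coincide (zero-length line)")

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def reversed(self) -> "LineSegment":
        return LineSegment(self.p1, self.p0, self.width_px)


@dataclass
class IntensityProfile:
    """Ordered intensity samples along a line.

    ``distances`` are strictly increasing arc-length positions in px and
    ``values`` the interpolated intensities in [0, 255].
    """

    distances: np.ndarray
    values: np.ndarray
    line: LineSegment

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.distances.shape != self.values.shape:
            raise ValueError("distances and values must have equal length")
        if self.distances.size and np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.distances, self.values]),
            delimiter=",",
            header="distance_px,intensity",
            comments="",
            fmt="%.6f",
        )


@dataclass(frozen=True)
class Extremum:
    index: int  # index into the profile arrays
    value: float
    kind: str  # "peak" | "trough"


@dataclass
class ExtremaSequence:
    """Alternating peaks and troughs extracted from a profile."""

    extrema: list[Extremum] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [e.index for e in self.extrema]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("extrema indices must be strictly increasing")
        kinds = [e.kind for e in self.extrema]
        if any(b == a for a, b in zip(kinds, kinds[1:])):
            raise ValueError("extrema must strictly alternate peak/trough")

    def __len__(self) -> int:
        return len(self.extrema)

    def __iter__(self):
        return iter(self.extrema)

    def __getitem__(self, i):
        return self.extrema[i]

    @property
    def peaks(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "peak"]

    @property
    def troughs(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "trough"]


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Collapse an image to a float 2-D intensity plane (Rec. 601 luma)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        return img[..., :3] @ _LUMA
    raise ValueError(f"unsupported image shape {image.shape}")


def sample_profile(image: np.ndarray, line: LineSegment) -> IntensityProfile:
    """Sample pixel intensity along ``line`` at 1 px arc-length steps.

    Bilinear interpolation; RGB input is converted to luminance first; the
    result is averaged over ``line.width_px`` perpendicular 1 px offsets
    centered on the line.  The ``round(length) + 1`` samples are spread
    evenly over the full line, so the step is exactly 1 px on
    integer-length lines (where axis-parallel width-1 samples equal the raw
    pixel values exactly) and within half a pixel of 1 px otherwise; both
    endpoints are always sampled, which makes profiling symmetric under
    line reversal.
    """
    plane = to_luminance(image)
    h, w = plane.shape
    for name, (r, c) in (("p0", line.p0), ("p1", line.p1)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(
                f"line endpoint {name}=({r}, {c}) lies outside the "
                f"{h}x{w} image (rows 0..{h - 1}, cols 0..{w - 1})"
            )

    p0 = np.asarray(line.p0, dtype=float)
    p1 = np.asarray(line.p1, dtype=float)
    length = line.length
    n = max(1, int(round(length)))
    distances = np.arange(n + 1, dtype=float) * (length / n)
    u = (p1 - p0) / length  # unit tangent
    pts = p0[None, :] + distances[:, None] * u[None, :]

    perp = np.array([-u[1], u[0]])
    offsets = np.arange(line.width_px, dtype=float) - (line.width_px - 1) / 2.0
    rows = pts[:, 0][None, :] + offsets[:, None] * perp[0]
    cols = pts[:, 1][None, :] + offsets[:, None] * perp[1]
    sampled = ndimage.map_coordinates(
        plane, [rows.ravel(), cols.ravel()], order=1, mode="nearest"
    ).reshape(line.width_px, n + 1)
    return IntensityProfile(distances=distances, values=sampled.mean(axis=0), line=line)


def detect_extrema(
    profile: IntensityProfile, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> ExtremaSequence:
    """Local maxima/minima with prominence >= ``min_prominence``, forced into
    strict peak/trough alternation.

    Where two or more extrema of the same kind occur in a row (possible when
    the intervening counter-extremum fell below the prominence threshold),
    only the most extreme one of the run is kept.  An empty sequence is a
    valid result, not an error.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    v = profile.values
    peak_idx, _ = signal.find_peaks(v, prominence=min_prominence)
    trough_idx, _ = signal.find_peaks(-v, prominence=min_prominence)
    merged = sorted(
        [Extremum(int(i), float(v[i]), "peak") for i in peak_idx]
        + [Extremum(int(i), float(v[i]), "trough") for i in trough_idx],
        key=lambda e: e.index,
    )

    out: list[Extremum] = []
    for e in merged:
        if out and out[-1].kind == e.kind:
            keep_new = e.value > out[-1].value if e.kind == "peak" else e.value < out[-1].value
            if keep_new:
                out[-1] = e
        else:
            out.append(e)
    return ExtremaSequence(out)
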