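"""Signed SMIA TV distortion from six landmark points on a grid target.

The user selects the left-most, middle, and right-most points of the top
and bottom grid lines.  The vertical extents ``A1`` (left), ``B``
(center), and ``A2`` (right) are the Euclidean pixel distances between the
paired top/bottom points; with ``A = (A1 + A2) / 2`` the SMIA TV distortion
is

    percent = 100 * (A - B) / B

Under barrel distortion the outer corners are pulled toward the image
center, so ``A < B`` and the percentage is negative; pincushion distortion
gives a positive value.  Reports carry both the signed value and its
magnitude so results can be compared against tools that drop the sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .profile import to_luminance

__all__ = [
    "SixPoints",
    "DistortionResult",
    "side_lengths",
    "smia_tv",
    "analyze_distortion",
    "snap_points_to_lines",
]

_POINT_NAMES = (
    "top_left",
    "top_mid",
    "top_right",
    "bottom_left",
    "bottom_mid",
    "bottom_right",
)


@dataclass(frozen=True)
class SixPoints:
    """The six grid landmarks, as real ``(row, col)`` pixel coordinates."""

    top_left: tuple[float, float]
    top_mid: tuple[float, float]
    top_right: tuple[float, float]
    bottom_left: tuple[float, float]
    bottom_mid: tuple[float, float]
    bottom_right: tuple[float, float]

    def __post_init__(self) -> None:
        for t, b in (
            (self.top_left, self.bottom_left),
            (self.top_mid, self.bottom_mid),
            (self.top_right, self.bottom_right),
        ):
            if t[0] >= b[0]:
                raise ValueError("top points must lie above bottom points")
        for row in (
            (self.top_left, self.top_mid, self.top_right),
            (self.bottom_left, self.bottom_mid, self.bottom_right),
        ):
            if not row[0][1] < row[1][1] < row[2][1]:
                raise ValueError("points must be ordered left < mid < right")

    @classmethod
    def from_dict(cls, d: dict) -> "SixPoints":
        missing = set(_POINT_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing landmark(s): {sorted(missing)}")
        return cls(**{k: (float(d[k][0]), float(d[k][1])) for k in _POINT_NAMES})

    @classmethod
    def from_json(cls, path) -> "SixPoints":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def as_dict(self) -> dict:
        return {k: list(getattr(self, k)) for k in _POINT_NAMES}


@dataclass
class DistortionResult:
    A1: float  # outer-left vertical extent, px
    A2: float  # outer-right vertical extent, px
    B: float  # central vertical extent, px
    A: float  # (A1 + A2) / 2
    percent: float  # signed SMIA TV distortion
    points: SixPoints | None = None

    @property
    def magnitude(self) -> float:
        return abs(self.percent)


def _dist(p: tuple[float, float], q: tuple[float, float]) -> float:
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def side_lengths(points: SixPoints) -> tuple[float, float, float]:
    """(A1, B, A2): pixel distances between the paired top/bottom landmarks."""
    a1 = _dist(points.top_left, points.bottom_left)
    b = _dist(points.top_mid, points.bottom_mid)
    a2 = _dist(points.top_right, points.bottom_right)
    for name, v in (("A1", a1), ("B", b), ("A2", a2)):
        if v == 0.0:
            raise ValueError(f"{name} has zero length (coincident points)")
    return a1, b, a2


def smia_tv(a1: float, a2: float, b: float) -> DistortionResult:
    """Signed SMIA TV distortion percent from the three vertical extents."""
    if b <= 0:
        raise ValueError("central extent B must be positive")
    a = (a1 + a2) / 2.0
    return DistortionResult(A1=a1, A2=a2, B=b, A=a, percent=100.0 * (a - b) / b)


def analyze_distortion(
    points: SixPoints, image: np.ndarray | None = None, snap: bool = False
) -> DistortionResult:
    """SMIA TV distortion from six landmarks, optionally snapped to the
    nearest dark-line minimum of ``image`` first (reduces click error)."""
    if snap:
        if image is None:
            raise ValueError("snapping requires the image")
        points = snap_points_to_lines(image, points)
    a1, b, a2 = side_lengths(points)
    result = smia_tv(a1, a2, b)
    result.points = points
    return result


def snap_points_to_lines(
    image: np.ndarray, points: SixPoints, window_px: int = 5
) -> SixPoints:
    """Move each landmark to the darkest pixel within a square window.

    Grid lines are dark on white, so the intensity minimum inside a small
    window around a rough click recovers the line intersection to pixel
    precision.  Ties keep the candidate closest to the original point.
    """
    plane = to_luminance(image)
    h, w = plane.shape
    snapped = {}
    for name in _POINT_NAMES:
        r, c = getattr(points, name)
        r0, r1 = max(0, int(round(r)) - window_px), min(h, int(round(r)) + window_px + 1)
        c0, c1 = max(0, int(round(c)) - window_px), min(w, int(round(c)) + window_px + 1)
        patch = plane[r0:r1, c0:c1]
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        score = patch + 1e-6 * ((rr - r) ** 2 + (cc - c) ** 2)
        i = int(np.argmin(score))
        snapped[name] = (float(rr.ravel()[i]), float(cc.ravel()[i]))
    return SixPoints.from_dict(snapped)
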