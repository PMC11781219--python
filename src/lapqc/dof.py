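"""Depth of field from a line-pair ladder profile.

The user draws a line along the 5 lp/mm ladder of a tilted depth-of-field
target.  The measurement takes the intensity difference between the first
full peak and its adjacent trough as the initial contrast; the failure
point is the first (peak, adjacent trough) pair whose difference falls
below half that initial value, validated by requiring the following twenty
pairs to stay below the threshold so an isolated anomaly cannot trigger a
false failure.  The number of peaks before the failure point divided by the
ladder frequency (pairs per mm) gives the depth of field in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import (
    DEFAULT_MIN_PROMINENCE,
    ExtremaSequence,
    Extremum,
    LineSegment,
    detect_extrema,
    sample_profile,
)

__all__ = [
    "DofResult",
    "DEFAULT_VALIDATION_WINDOW",
    "initial_range",
    "find_failure",
    "dof_mm",
    "analyze_dof",
]

#: Number of subsequent pairs that must also sit below the range check for a
#: candidate failure to be confirmed (anomaly rejection).
DEFAULT_VALIDATION_WINDOW = 20


@dataclass
class DofResult:
    initial_range: float  # first full peak minus first adjacent trough
    range_check: float  # = initial_range / 2
    failure_pair_index: int | None  # index into the pair sequence, or None
    peaks_before_failure: int
    dof_mm: float
    status: str  # "failed_at" | "no_failure_found"
    n_pairs: int = 0

    @property
    def is_lower_bound(self) -> bool:
        """True when no failure was found and dof_mm only bounds the DOF."""
        return self.status == "no_failure_found"


def _first_full_peak(extrema: ExtremaSequence) -> int:
    """Index (into the extrema list) of the first full peak.

    A full peak is one preceded by a trough in the sequence: the rise out
    of that trough shows the peak was fully crossed by the line, excluding
    a clipped partial peak at the line start (a profile that begins mid-bar
    near a maximum).  Only the first three extrema are searched; failing
    that, the user should redraw the line to start ahead of the ladder.
    """
    for i, e in enumerate(extrema):
        if i > 2:
            break
        if e.kind == "peak" and i >= 1:
            return i
    raise ValueError(
        "no full peak (a peak preceded by a trough) within the first three "
        "extrema; redraw the line so it enters the ladder from outside"
    )


def _pairs(extrema: ExtremaSequence) -> tuple[int, list[tuple[Extremum, Extremum]]]:
    """(start index, list of (peak, adjacent trough) pairs from the first
    full peak on).  A trailing unpaired peak is ignored."""
    start = _first_full_peak(extrema)
    ex = extrema.extrema
    pairs = [
        (ex[i], ex[i + 1])
        for i in range(start, len(ex) - 1, 2)
        if ex[i].kind == "peak" and ex[i + 1].kind == "trough"
    ]
    return start, pairs


def initial_range(extrema: ExtremaSequence) -> tuple[float, float]:
    """Initial contrast of the ladder and the derived range check.

    Returns ``(initial_range, range_check)`` where ``initial_range`` is the
    first full peak minus its adjacent trough and ``range_check`` is half
    of it -- the threshold below which a pair counts as a contrast failure.
    """
    _, pairs = _pairs(extrema)
    if not pairs:
        raise ValueError("no (peak, trough) pair after the first full peak")
    peak, trough = pairs[0]
    rng = peak.value - trough.value
    if rng <= 0:
        raise ValueError(
            f"degenerate initial range {rng}; the profile start has no contrast"
        )
    return float(rng), float(rng) / 2.0


def find_failure(
    extrema: ExtremaSequence,
    range_check: float,
    validation_window: int = DEFAULT_VALIDATION_WINDOW,
) -> int | None:
    """Index of the first validated sub-threshold pair, or None.

    Scans consecutive (peak, adjacent trough) pairs; a candidate failure is
    the first pair whose difference drops below ``range_check``, confirmed
    only if the next ``validation_window`` pairs (or all remaining pairs,
    when fewer are left) also sit below the threshold.  An isolated low
    pair followed by recovery is an anomaly: scanning continues past it.
    """
    if range_check <= 0:
        raise ValueError("range_check must be positive")
    _, pairs = _pairs(extrema)
    diffs = np.array([p.value - t.value for p, t in pairs])
    for i, d in enumerate(diffs):
        if d < range_check:
            window = diffs[i + 1 : i + 1 + validation_window]
            if np.all(window < range_check):
                return i
    return None


def dof_mm(
    extrema: ExtremaSequence,
    failure_pair_index: int | None,
    lp_per_mm: float = 5.0,
) -> DofResult:
    """Depth of field from the failure index.

    Counts the peaks strictly before the failure pair (the failing peak
    itself is excluded) and divides by the ladder frequency.  Without a
    failure every paired peak is counted and the result is a lower bound.
    """
    init, check = initial_range(extrema)
    _, pairs = _pairs(extrema)
    if failure_pair_index is None:
        n_peaks = len(pairs)
        status = "no_failure_found"
    else:
        if not 0 <= failure_pair_index < len(pairs):
            raise ValueError(
                f"failure index {failure_pair_index} out of range "
                f"(0..{len(pairs) - 1})"
            )
        n_peaks = failure_pair_index
        status = "failed_at"
    return DofResult(
        initial_range=init,
        range_check=check,
        failure_pair_index=failure_pair_index,
        peaks_before_failure=n_peaks,
        dof_mm=n_peaks / lp_per_mm,
        status=status,
        n_pairs=len(pairs),
    )


def analyze_dof(
    image: np.ndarray,
    line: LineSegment,
    lp_per_mm: float = 5.0,
    validation_window: int = DEFAULT_VALIDATION_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> DofResult:
    """Full pipeline: profile -> extrema -> failure search -> DOF in mm."""
    prof = sample_profile(image, line)
    extrema = detect_extrema(prof, min_prominence=min_prominence)
    _, check = initial_range(extrema)
    failure = find_failure(extrema, check, validation_window=validation_window)
    return dof_mm(extrema, failure, lp_per_mm=lp_per_mm)
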