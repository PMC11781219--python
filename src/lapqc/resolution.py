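"""Limit of resolution from a USAF-1951 group profile.

A user draws one line through an entire group of the chart; each element
contributes three dark bars (troughs in the intensity profile) separated by
two light gaps (peaks).  An element resolves if the ratio of its peak
(white) level to its trough (black) level is at least 2:1; the limit of
resolution is the finest element that still passes, reported both as
(group, element) and as a line width in micrometers (500/f for frequency f
in line pairs per mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chartgen import usaf_frequency_lp_mm, usaf_line_width_um
from .profile import (
    DEFAULT_MIN_PROMINENCE,
    ExtremaSequence,
    Extremum,
    LineSegment,
    detect_extrema,
    sample_profile,
)

__all__ = [
    "UsafElement",
    "ElementRun",
    "ElementVerdict",
    "ResolutionResult",
    "usaf_elements",
    "segment_elements",
    "assess_element",
    "resolution_limit",
    "analyze_resolution",
    "PASS_RATIO",
    "TROUGH_FLOOR",
]

#: An element resolves when peak_level / trough_level >= this ratio.
PASS_RATIO = 2.0
#: Floor applied to the trough level so the ratio stays finite (gray levels).
TROUGH_FLOOR = 1.0
_BARS_PER_ELEMENT = 3


@dataclass(frozen=True)
class UsafElement:
    """A (group, element) index pair on the USAF-1951 chart."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError(f"element must be in 1..6, got {self.element}")

    @property
    def frequency_lp_mm(self) -> float:
        return usaf_frequency_lp_mm(self.group, self.element)

    @property
    def line_width_um(self) -> float:
        return usaf_line_width_um(self.group, self.element)

    def __str__(self) -> str:  # e.g. "G2E3"
        return f"G{self.group}E{self.element}"


def usaf_elements(group: int, n_elements: int = 6, first: int = 1) -> list[UsafElement]:
    """Elements ``first..first+n-1`` of a group, coarse to fine."""
    return [UsafElement(group, e) for e in range(first, first + n_elements)]


@dataclass
class ElementRun:
    """The extrema assigned to one element: its 3 dark-bar troughs and the
    interior peaks between them."""

    element: UsafElement | None
    peaks: list[Extremum]
    troughs: list[Extremum]


@dataclass
class ElementVerdict:
    element: UsafElement | None
    peak_level: float
    trough_level: float
    ratio: float
    passed: bool
    saturated: bool = False  # no measurable trough; ratio reported as +inf


@dataclass
class ResolutionResult:
    """Ordered per-element verdicts and the limit of resolution."""

    verdicts: list[ElementVerdict]
    limit: UsafElement | None
    limit_lp_mm: float | None
    limit_um: float | None
    status: str  # "resolved" | "unresolved"
    anomalous_passes: int = 0  # elements passing after the first failure
    leftover_extrema: int = 0


def segment_elements(
    extrema: ExtremaSequence,
    elements: int | Sequence[UsafElement],
) -> tuple[list[ElementRun], list[Extremum]]:
    """Assign consecutive runs of 3 troughs (dark bars) to elements in order
    along the line.

    Each run also receives the interior peaks between its first and last
    trough (exactly 2 when alternation held).  Extrema outside any run
    (leading/trailing peaks, surplus bars) are returned, not silently
    dropped.  Raises if fewer than ``3 * n_elements`` troughs were found,
    which happens when blur merges neighbouring elements.
    """
    if isinstance(elements, int):
        els: list[UsafElement | None] = [None] * elements
    else:
        els = list(elements)
    n = len(els)
    troughs = extrema.troughs
    need = _BARS_PER_ELEMENT * n
    if len(troughs) < need:
        raise ValueError(
            f"profile yields {len(troughs)} troughs but {n} elements require "
            f"{need} ({_BARS_PER_ELEMENT} dark bars each); the line may miss "
            "bars or blur may have merged neighbouring elements"
        )
    runs: list[ElementRun] = []
    used: set[int] = set()
    for i, el in enumerate(els):
        run_troughs = troughs[_BARS_PER_ELEMENT * i : _BARS_PER_ELEMENT * (i + 1)]
        lo, hi = run_troughs[0].index, run_troughs[-1].index
        run_peaks = [p for p in extrema.peaks if lo < p.index < hi]
        used.update(e.index for e in run_troughs + run_peaks)
        runs.append(ElementRun(element=el, peaks=run_peaks, troughs=run_troughs))
    leftover = [e for e in extrema if e.index not in used]
    return runs, leftover


def assess_element(run: ElementRun, strategy: str = "mean") -> ElementVerdict:
    """Pass/fail verdict for one element's extrema run.

    ``strategy="mean"`` compares the mean of the run's peak values against
    the mean of its trough values; ``"worst-pair"`` compares the dimmest
    peak against the brightest trough.  The trough level is floored at
    ``TROUGH_FLOOR`` gray levels so fully black bars give a finite ratio.
    A run with no measurable trough (saturated contrast) passes with a
    ``ratio`` of +inf and is flagged.
    """
    if not run.peaks:
        raise ValueError("element run has no peak; cannot assess")
    peak_vals = np.array([p.value for p in run.peaks])
    if not run.troughs:
        peak_level = float(peak_vals.mean())
        return ElementVerdict(
            element=run.element,
            peak_level=peak_level,
            trough_level=0.0,
            ratio=float("inf"),
            passed=True,
            saturated=True,
        )
    trough_vals = np.array([t.value for t in run.troughs])
    if strategy == "mean":
        peak_level = float(peak_vals.mean())
        trough_level = float(trough_vals.mean())
    elif strategy == "worst-pair":
        peak_level = float(peak_vals.min())
        trough_level = float(trough_vals.max())
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    ratio = peak_level / max(trough_level, TROUGH_FLOOR)
    return ElementVerdict(
        element=run.element,
        peak_level=peak_level,
        trough_level=trough_level,
        ratio=float(ratio),
        passed=bool(ratio >= PASS_RATIO),
    )


def resolution_limit(
    verdicts: Sequence[ElementVerdict], leftover_extrema: int = 0
) -> ResolutionResult:
    """Limit of resolution from verdicts ordered coarse to fine.

    The limit is the finest element that passed with every coarser element
    also passing; once an element fails, finer elements cannot define the
    limit even if they nominally pass (spurious passes occur at aliasing
    frequencies) -- such passes are counted as anomalies.
    """
    verdicts = list(verdicts)
    limit: ElementVerdict | None = None
    first_failure = None
    anomalies = 0
    for i, v in enumerate(verdicts):
        if first_failure is None:
            if v.passed:
                limit = v
            else:
                first_failure = i
        elif v.passed:
            anomalies += 1
    el = limit.element if limit is not None else None
    return ResolutionResult(
        verdicts=verdicts,
        limit=el,
        limit_lp_mm=el.frequency_lp_mm if el is not None else None,
        limit_um=el.line_width_um if el is not None else None,
        status="resolved" if limit is not None else "unresolved",
        anomalous_passes=anomalies,
        leftover_extrema=leftover_extrema,
    )


def analyze_resolution(
    image: np.ndarray,
    line: LineSegment,
    elements: Sequence[UsafElement],
    strategy: str = "mean",
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> ResolutionResult:
    """Full pipeline: profile -> extrema -> per-element verdicts -> limit."""
    prof = sample_profile(image, line)
    extrema = detect_extrema(prof, min_prominence=min_prominence)
    runs, leftover = segment_elements(extrema, elements)
    verdicts = [assess_element(r, strategy=strategy) for r in runs]
    return resolution_limit(verdicts, leftover_extrema=len(leftover))
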