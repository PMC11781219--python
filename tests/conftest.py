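"""Shared synthetic-chart fixtures.

Everything is generated at test time from the chart generator; there are no
stored image fixtures.  Module-scoped fixtures keep rendering cost down.
"""

from __future__ import annotations

import numpy as np
import pytest

from lapqc import chartgen as cg
from lapqc import colorimetry as cm
from lapqc.profile import Extremum, ExtremaSequence, LineSegment


@pytest.fixture(scope="session")
def usaf_group1():
    """Unblurred full-contrast USAF group 1 chart at 36 px/mm."""
    spec = cg.usaf_chart(group=1, px_per_mm=36.0)
    img, truth = cg.render_chart(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def usaf_midline(usaf_group1):
    _, img, _ = usaf_group1
    row = (img.shape[0] - 1) / 2.0
    return LineSegment((row, 0.0), (row, img.shape[1] - 1.0))


@pytest.fixture(scope="session")
def grid5():
    """5x5-line grid chart, landmarks on integer pixel coordinates."""
    spec = cg.grid_chart(n_lines=5, spacing_px=200.0, line_width_px=3.0, margin_px=40)
    img, truth = cg.render_chart(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def classic24_reference():
    return cm.load_reference_preset("classic24")


@pytest.fixture(scope="session")
def colorchecker24(classic24_reference):
    spec = cg.colorchecker_chart(cm.reference_to_patch_specs(classic24_reference))
    img, truth = cg.render_chart(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def dof_ladder10():
    """10 mm ladder at 5 lp/mm, 40 px/mm, full contrast, undegraded."""
    spec = cg.dof_ladder_chart(length_mm=10.0, px_per_mm=40.0)
    img, truth = cg.render_chart(spec)
    return spec, img, truth


def ladder_line(img: np.ndarray, truth) -> LineSegment:
    col = truth.dof.profile_col
    return LineSegment((0.0, col), (img.shape[0] - 1.0, col))


def make_extrema(values, start_kind="peak") -> ExtremaSequence:
    """Alternating extrema sequence from a flat list of values."""
    kinds = ["peak", "trough"] if start_kind == "peak" else ["trough", "peak"]
    return ExtremaSequence(
        [Extremum(i, float(v), kinds[i % 2]) for i, v in enumerate(values)]
    )
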