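"""Batch configuration, suite runner, and QA report writing.

Ties the four metric engines and the chart generator into a single
manufacturing-QA workflow: a config file names the images and the
geometric inputs (measurement lines, patch layout, landmark points --
always explicit user data, never inferred, so results stay auditable), the
runner executes every configured test independently, and the report embeds
the exact configuration, input checksums, and full per-test results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .colorimetry import (
    PatchLayout,
    compare_to_reference,
    layout_from_truth,
    load_reference_csv,
    load_reference_preset,
    swatch_image,
)
from .distortion import SixPoints, analyze_distortion
from .dof import DEFAULT_VALIDATION_WINDOW, analyze_dof
from .profile import DEFAULT_MIN_PROMINENCE, LineSegment
from .resolution import analyze_resolution, usaf_elements

__all__ = [
    "AnalysisConfig",
    "ResolutionConfig",
    "DofConfig",
    "ColorConfig",
    "DistortionConfig",
    "QaReport",
    "TestOutcome",
    "run_suite",
    "write_report",
    "load_config",
]

log = logging.getLogger("lapqc")

TESTS = ("resolution", "dof", "color", "distortion")


class _LineModel(BaseModel):
    r0: float
    c0: float
    r1: float
    c1: float
    width_px: int = 1

    def to_line(self) -> LineSegment:
        return LineSegment((self.r0, self.c0), (self.r1, self.c1), self.width_px)


class ResolutionConfig(BaseModel):
    image: str
    line: _LineModel
    group: int
    n_elements: int = Field(6, ge=1, le=6)
    first_element: int = Field(1, ge=1, le=6)
    strategy: Literal["mean", "worst-pair"] = "mean"


class DofConfig(BaseModel):
    image: str
    line: _LineModel
    lp_per_mm: float = Field(5.0, gt=0)
    validation_window: int = Field(DEFAULT_VALIDATION_WINDOW, ge=0)


class ColorConfig(BaseModel):
    image: str
    reference_csv: str | None = None  # path; falls back to reference_preset
    reference_preset: str = "classic24"
    layout_json: str | None = None  # {"rois": [[r0,c0,r1,c1], ...]}
    inner_fraction: float = Field(0.5, gt=0.0, le=1.0)


class DistortionConfig(BaseModel):
    image: str
    points_json: str  # six named landmarks as [row, col]
    snap: bool = False


class AnalysisConfig(BaseModel):
    """Per-test blocks plus global knobs; omitted blocks are not run."""

    resolution: ResolutionConfig | None = None
    dof: DofConfig | None = None
    color: ColorConfig | None = None
    distortion: DistortionConfig | None = None
    min_prominence: float = Field(DEFAULT_MIN_PROMINENCE, ge=0)
    output_dir: str = "."
    seed: int = 0

    def configured_tests(self) -> list[str]:
        return [t for t in TESTS if getattr(self, t) is not None]


@dataclass
class TestOutcome:
    status: str  # "ok" | "error" | "not_run"
    result: dict | None = None
    error: str | None = None


@dataclass
class QaReport:
    tool_version: str
    config: dict
    timestamp: str
    image_checksums: dict[str, str] = field(default_factory=dict)
    results: dict[str, TestOutcome] = field(default_factory=dict)

    @property
    def all_configured_ok(self) -> bool:
        return all(o.status != "error" for o in self.results.values())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QaReport":
        raw = json.loads(text)
        rep = cls(
            tool_version=raw["tool_version"],
            config=raw["config"],
            timestamp=raw["timestamp"],
            image_checksums=raw.get("image_checksums", {}),
        )
        rep.results = {k: TestOutcome(**v) for k, v in raw.get("results", {}).items()}
        return rep

    def summary_rows(self) -> list[dict]:
        """One row per scalar metric, for the CSV summary."""
        rows = []
        for test, outcome in self.results.items():
            if outcome.status != "ok" or outcome.result is None:
                rows.append({"test": test, "metric": "status", "value": outcome.status})
                continue
            for key, value in outcome.result.items():
                if isinstance(value, (int, float)) or value is None:
                    rows.append({"test": test, "metric": key, "value": value})
        return rows


def load_config(path) -> AnalysisConfig:
    """Read a YAML or JSON config file into a validated AnalysisConfig."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return AnalysisConfig.model_validate(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_image(path: str, base: Path) -> np.ndarray:
    p = Path(path)
    if not p.is_absolute():
        p = base / p
    return np.asarray(iio.imread(p))


def _resolution_outcome(cfg: ResolutionConfig, img: np.ndarray, prominence: float) -> dict:
    elements = usaf_elements(cfg.group, cfg.n_elements, cfg.first_element)
    res = analyze_resolution(
        img, cfg.line.to_line(), elements, strategy=cfg.strategy, min_prominence=prominence
    )
    return {
        "status": res.status,
        "limit_group": res.limit.group if res.limit else None,
        "limit_element": res.limit.element if res.limit else None,
        "limit_lp_mm": res.limit_lp_mm,
        "limit_um": res.limit_um,
        "anomalous_passes": res.anomalous_passes,
        "leftover_extrema": res.leftover_extrema,
        "verdicts": [
            {
                "group": v.element.group if v.element else None,
                "element": v.element.element if v.element else None,
                "peak_level": v.peak_level,
                "trough_level": v.trough_level,
                "ratio": None if v.ratio == float("inf") else v.ratio,
                "passed": v.passed,
                "saturated": v.saturated,
            }
            for v in res.verdicts
        ],
    }


def _dof_outcome(cfg: DofConfig, img: np.ndarray, prominence: float) -> dict:
    res = analyze_dof(
        img,
        cfg.line.to_line(),
        lp_per_mm=cfg.lp_per_mm,
        validation_window=cfg.validation_window,
        min_prominence=prominence,
    )
    return {
        "status": res.status,
        "dof_mm": res.dof_mm,
        "is_lower_bound": res.is_lower_bound,
        "initial_range": res.initial_range,
        "range_check": res.range_check,
        "failure_pair_index": res.failure_pair_index,
        "peaks_before_failure": res.peaks_before_failure,
        "n_pairs": res.n_pairs,
    }


def _color_outcome(cfg: ColorConfig, img: np.ndarray, base: Path, out_dir: Path) -> dict:
    if cfg.reference_csv is not None:
        ref = load_reference_csv(base / cfg.reference_csv)
    else:
        ref = load_reference_preset(cfg.reference_preset)
    if cfg.layout_json is None:
        raise ValueError("color config requires layout_json with patch ROIs")
    layout_raw = json.loads(Path(base / cfg.layout_json).read_text())
    layout = PatchLayout(
        rois=tuple(tuple(r) for r in layout_raw["rois"]),
        inner_fraction=cfg.inner_fraction,
    )
    res = compare_to_reference(img, layout, ref)
    sw_path = out_dir / "color_swatches.png"
    iio.imwrite(sw_path, swatch_image(res))
    return {
        "mean_delta_e_ab": res.mean_delta_e,
        "mean_delta_c_ab": res.mean_delta_c,
        "mean_delta_e_ab_wb": res.mean_delta_e_wb,
        "mean_delta_c_ab_wb": res.mean_delta_c_wb,
        "swatch_image": sw_path.name,
        "patches": json.loads(res.to_frame().to_json(orient="records")),
    }


def _distortion_outcome(cfg: DistortionConfig, img: np.ndarray, base: Path) -> dict:
    points = SixPoints.from_json(base / cfg.points_json)
    res = analyze_distortion(points, image=img, snap=cfg.snap)
    return {
        "A1": res.A1,
        "A2": res.A2,
        "B": res.B,
        "A": res.A,
        "percent": res.percent,
        "magnitude": res.magnitude,
        "points_used": res.points.as_dict() if res.points else None,
    }


def run_suite(config: AnalysisConfig, base_dir: str | Path = ".") -> QaReport:
    """Execute every configured test; one test's failure never aborts the rest.

    ``base_dir`` anchors relative paths in the config.  Unconfigured tests
    are reported explicitly as ``not_run``.
    """
    base = Path(base_dir)
    out_dir = Path(config.output_dir)
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    report = QaReport(
        tool_version=__version__,
        config=config.model_dump(mode="json"),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    for test in TESTS:
        cfg = getattr(config, test)
        if cfg is None:
            report.results[test] = TestOutcome(status="not_run")
            continue
        log.info("running %s analysis on %s", test, cfg.image)
        try:
            img_path = Path(cfg.image)
            if not img_path.is_absolute():
                img_path = base / img_path
            report.image_checksums[cfg.image] = _sha256(img_path)
            img = np.asarray(iio.imread(img_path))
            if test == "resolution":
                result = _resolution_outcome(cfg, img, config.min_prominence)
            elif test == "dof":
                result = _dof_outcome(cfg, img, config.min_prominence)
            elif test == "color":
                result = _color_outcome(cfg, img, base, out_dir)
            else:
                result = _distortion_outcome(cfg, img, base)
            report.results[test] = TestOutcome(status="ok", result=result)
        except Exception as exc:  # deliberate: capture per-test, keep going
            log.error("%s analysis failed: %s", test, exc)
            report.results[test] = TestOutcome(status="error", error=str(exc))
    return report


def write_report(report: QaReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the canonical JSON report and a one-row-per-metric CSV summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "qa_report.json"
    json_path.write_text(report.to_json())
    csv_path = out / "qa_summary.csv"
    pd.DataFrame(report.summary_rows(), columns=["test", "metric", "value"]).to_csv(
        csv_path, index=False
    )
    return {"json": json_path, "csv": csv_path}
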