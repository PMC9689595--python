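"""End-to-end orchestration: preprocess -> segment -> gate -> count -> aggregate.

This module ties the stages together for whole cohorts and defines the
single configuration object the CLI serializes to/from YAML. Excluded or
unanalyzable eyes are always carried through to the output, flagged,
never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .chamber_segmentation import ChamberConfig, segment_chamber
from .errors import ACCellScanError, GateError, SegmentationError
from .imaging_io import CohortManifest, EyeRecord, OCTImage, SCAN_ANGLES, load_image
from .preprocess import PreprocessConfig, preprocess_scan
from .spot_detection import (
    EyeSpotCount,
    GateConfig,
    SpotCount,
    aggregate_eye,
    count_cellular_spots,
    fibrin_gate,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations plus run-level options."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    chamber: ChamberConfig = field(default_factory=ChamberConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    tile_size: int = 5
    clip_predictions: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            preprocess=PreprocessConfig(**raw.get("preprocess", {})),
            chamber=ChamberConfig(**raw.get("chamber", {})),
            gate=GateConfig(**raw.get("gate", {})),
            tile_size=raw.get("tile_size", 5),
            clip_predictions=raw.get("clip_predictions", False),
            seed=raw.get("seed", 0),
        )

    def to_dict(self) -> dict:
        return {
            "preprocess": vars(self.preprocess).copy(),
            "chamber": vars(self.chamber).copy(),
            "gate": vars(self.gate).copy(),
            "tile_size": self.tile_size,
            "clip_predictions": self.clip_predictions,
            "seed": self.seed,
        }


@dataclass
class ScanResult:
    """Outcome of analyzing one B-scan."""

    eye_id: str
    scan_angle: int
    status: str  # counted | removed_fibrin | segmentation_failed | unreadable
    count: int | None = None
    white_fraction: float | None = None


def analyze_image(image: OCTImage, config: PipelineConfig | None = None) -> ScanResult:
    """Run the full single-scan chain and classify the outcome."""
    config = config or PipelineConfig()
    mask = preprocess_scan(image, config.preprocess)
    try:
        chamber = segment_chamber(mask, config.chamber)
    except SegmentationError as exc:
        logger.warning("eye=%s angle=%s: segmentation failed (%s)", image.eye_id, image.scan_angle, exc)
        return ScanResult(image.eye_id, image.scan_angle, "segmentation_failed")
    try:
        decision = fibrin_gate(mask, chamber, config.gate)
    except GateError as exc:
        logger.warning("eye=%s angle=%s: gate error (%s)", image.eye_id, image.scan_angle, exc)
        return ScanResult(image.eye_id, image.scan_angle, "segmentation_failed")
    if not decision.kept:
        logger.warning(
            "eye=%s angle=%s: removed by fibrin gate (white fraction %.3f)",
            image.eye_id, image.scan_angle, decision.white_fraction,
        )
        return ScanResult(
            image.eye_id, image.scan_angle, "removed_fibrin", white_fraction=decision.white_fraction
        )
    spots = count_cellular_spots(mask, chamber, tile_size=config.tile_size, image_ref=image.eye_id)
    return ScanResult(
        image.eye_id,
        image.scan_angle,
        "counted",
        count=spots.count,
        white_fraction=decision.white_fraction,
    )


def analyze_eye(record: EyeRecord, config: PipelineConfig | None = None) -> tuple[EyeSpotCount, list[ScanResult]]:
    """Analyze all four scans of one eye and aggregate."""
    config = config or PipelineConfig()
    results: list[ScanResult] = []
    per_scan = []
    for angle, path in zip(SCAN_ANGLES, record.scans):
        try:
            image = load_image(path, eye_id=record.eye_id, scan_angle=angle)
        except ACCellScanError as exc:
            logger.error("eye=%s angle=%s: unreadable image (%s)", record.eye_id, angle, exc)
            results.append(ScanResult(record.eye_id, angle, "unreadable"))
            per_scan.append(exc)
            continue
        result = analyze_image(image, config)
        results.append(result)
        if result.status == "counted":
            per_scan.append(SpotCount(count=result.count, image_ref=str(path)))
        else:
            per_scan.append(result)
    return aggregate_eye(record, per_scan), results


def analyze_manifest(
    manifest: CohortManifest, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a whole cohort.

    Returns an (per-eye frame, per-scan frame) pair. The per-eye frame has
    columns eye_id, sun_grade, excluded, total; the per-scan frame one row
    per B-scan with its gate status, white fraction, and count.
    """
    config = config or PipelineConfig()
    eye_rows = []
    scan_rows = []
    for record in manifest:
        logger.info("analyzing eye %s (grade %g)", record.eye_id, record.sun_grade)
        eye_result, scan_results = analyze_eye(record, config)
        eye_rows.append(
            {
                "eye_id": record.eye_id,
                "sun_grade": record.sun_grade,
                "excluded": eye_result.excluded,
                "total": eye_result.total if not eye_result.excluded else pd.NA,
            }
        )
        for r in scan_results:
            scan_rows.append(
                {
                    "eye_id": r.eye_id,
                    "scan_angle": r.scan_angle,
                    "status": r.status,
                    "kept": r.status == "counted",
                    "white_fraction": r.white_fraction,
                    "count": r.count,
                }
            )
    eye_frame = pd.DataFrame(
        eye_rows, columns=["eye_id", "sun_grade", "excluded", "total"]
    )
    scan_frame = pd.DataFrame(
        scan_rows, columns=["eye_id", "scan_angle", "status", "kept", "white_fraction", "count"]
    )
    return eye_frame, scan_frame
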