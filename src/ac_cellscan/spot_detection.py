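"""Fibrin exclusion gate, 5x5-tile cellular-spot counting, per-eye totals.

Severe fibrin formation floods the aqueous with contiguous white signal
and defeats spot counting, so scans are gated first: two probe rectangles
of 1/8 image width x 1/8 image height are placed inside the chamber,
symmetric about its centroid, and the scan is removed when white pixels
exceed 20% of the probed chamber area (strictly greater).

Counting then partitions the image into independent 5x5-pixel tiles; a
tile counts as one cellular spot iff at least one of its pixels is white
*and* inside the AC mask. Counting occupied tiles rather than connected
components deliberately absorbs cell clumping and cells of varying size.
Per-eye totals sum the four radial scans; an eye with any removed or
unanalyzable scan is excluded as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chamber_segmentation import ChamberSegmentation
from .errors import GateError
from .imaging_io import EyeRecord
from .preprocess import BinaryMask

TILE_SIZE = 5


@dataclass
class GateConfig:
    """Fibrin-gate geometry and threshold.

    ``region_width`` / ``region_height`` default to W/8 and H/8 of the
    gated image (floor). ``threshold_fraction`` is the white-pixel
    proportion above which (strictly) a scan is removed.
    """

    region_width: int | None = None
    region_height: int | None = None
    threshold_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        for v in (self.region_width, self.region_height):
            if v is not None and v < 1:
                raise ValueError("probe region dimensions must be >= 1")


@dataclass
class GateDecision:
    """Outcome of the fibrin gate for one scan."""

    kept: bool
    white_fraction: float
    region_origins: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class SpotCount:
    """Cellular-spot tally of one scan (count of occupied 5x5 tiles)."""

    count: int
    tile_size: int = TILE_SIZE
    image_ref: str = ""


@dataclass
class EyeSpotCount:
    """Per-eye aggregate over the four radial scans."""

    eye_id: str
    excluded: bool
    total: int | None
    per_scan: list = field(default_factory=list)


def _probe_regions(
    chamber: ChamberSegmentation, shape: tuple[int, int], config: GateConfig
) -> tuple[np.ndarray, tuple[tuple[int, int], tuple[int, int]]]:
    H, W = shape
    rw = config.region_width if config.region_width is not None else max(1, W // 8)
    rh = config.region_height if config.region_height is not None else max(1, H // 8)
    rows, cols = np.nonzero(chamber.mask)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    cr, cc = chamber.centroid
    region = np.zeros(shape, dtype=bool)
    origins = []
    for center_col in (cc - rw, cc + rw):
        top = int(round(cr)) - rh // 2
        left = int(round(center_col)) - rw // 2
        top = min(max(top, r0), max(r0, r1 - rh + 1))
        left = min(max(left, c0), max(c0, c1 - rw + 1))
        region[top : top + rh, left : left + rw] = True
        origins.append((top, left))
    return region, (origins[0], origins[1])


def fibrin_gate(
    binarized: BinaryMask, chamber: ChamberSegmentation, config: GateConfig | None = None
) -> GateDecision:
    """Decide whether a scan is analyzable or flooded by fibrin/flare.

    The white fraction is pooled over both probe rectangles intersected
    with the AC mask; the scan is removed iff it strictly exceeds
    ``threshold_fraction``. Raises :class:`GateError` when the probes do
    not intersect the chamber at all.
    """
    config = config or GateConfig()
    m = np.asarray(binarized, dtype=bool)
    if not chamber.mask.any():
        raise GateError("chamber mask is empty")
    region, origins = _probe_regions(chamber, m.shape, config)
    probed = region & chamber.mask
    denom = int(probed.sum())
    if denom == 0:
        raise GateError("probe regions do not intersect the chamber mask")
    white = int((m & probed).sum())
    fraction = white / denom
    return GateDecision(kept=fraction <= config.threshold_fraction, white_fraction=fraction, region_origins=origins)


def count_cellular_spots(
    binarized: BinaryMask,
    chamber: ChamberSegmentation,
    tile_size: int = TILE_SIZE,
    image_ref: str = "",
) -> SpotCount:
    """Count occupied tiles: spots of any size or clump count once per tile.

    The image is partitioned into non-overlapping ``tile_size`` x
    ``tile_size`` tiles anchored at (0, 0); partial tiles at the right and
    bottom edges participate. A tile contributes 1 iff it contains at
    least one pixel that is white in ``binarized`` and inside the AC mask.
    """
    active = np.asarray(binarized, dtype=bool) & chamber.mask
    H, W = active.shape
    th, tw = -(-H // tile_size), -(-W // tile_size)
    padded = np.zeros((th * tile_size, tw * tile_size), dtype=bool)
    padded[:H, :W] = active
    tiles = padded.reshape(th, tile_size, tw, tile_size).any(axis=(1, 3))
    return SpotCount(count=int(tiles.sum()), tile_size=tile_size, image_ref=image_ref)


def aggregate_eye(record: EyeRecord, per_scan: list) -> EyeSpotCount:
    """Combine four per-scan results into a per-eye tally.

    ``per_scan`` entries are :class:`SpotCount` for analyzed scans, or
    anything else (a :class:`GateDecision` with ``kept=False``, an
    exception instance, ...) for scans that could not be counted. If any
    scan was not counted the whole eye is excluded — mirroring the rule
    that eyes with fibrin-flooded scans drop out of the quantitative
    analysis — otherwise the total is the sum of the four counts.
    """
    if len(per_scan) != 4:
        raise ValueError(f"eye {record.eye_id!r}: expected 4 per-scan results, got {len(per_scan)}")
    counted = [r for r in per_scan if isinstance(r, SpotCount)]
    if len(counted) < 4:
        return EyeSpotCount(eye_id=record.eye_id, excluded=True, total=None, per_scan=list(per_scan))
    return EyeSpotCount(
        eye_id=record.eye_id,
        excluded=False,
        total=sum(r.count for r in counted),
        per_scan=list(per_scan),
    )
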