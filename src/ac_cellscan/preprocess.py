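"""Binarization and morphological noise suppression.

A B-scan becomes a ``{0,1}`` mask of hyperreflective ("white") pixels in
three steps: a global threshold (Otsu by default, fixed override), removal
of the vertical fixation artifact, and a small morphological opening that
erases speckle specks below the structuring-element scale. All steps
preserve image dimensions and never invent white pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import opening

from .imaging_io import OCTImage

logger = logging.getLogger(__name__)

BinaryMask = np.ndarray  # 2-D bool array; True = white pixel


@dataclass
class PreprocessConfig:
    """Thresholding and denoising knobs.

    threshold_mode
        ``"otsu"`` computes a global Otsu threshold per image;
        ``"fixed"`` uses ``fixed_threshold`` directly. A pixel is white
        iff its intensity is **strictly greater** than the threshold.
    fixed_threshold
        Intensity used in fixed mode, and the fallback when Otsu is
        undefined (constant image).
    opening_radius
        Radius of the square opening element (the (2r+1) x (2r+1)
        neighborhood); 0 disables denoising.
    artifact_removal / artifact_max_width
        Enable zeroing of the central vertical fixation-artifact line and
        the maximum width (in columns) a candidate line may have.
    """

    threshold_mode: str = "otsu"
    fixed_threshold: int = 100
    opening_radius: int = 1
    artifact_removal: bool = True
    artifact_max_width: int = 3

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"threshold_mode must be 'otsu' or 'fixed', got {self.threshold_mode!r}")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")


def binarize(image: OCTImage, config: PreprocessConfig | None = None) -> BinaryMask:
    """Threshold a B-scan to a boolean mask (white iff intensity > T)."""
    config = config or PreprocessConfig()
    pixels = image.pixels
    if config.threshold_mode == "fixed":
        threshold = config.fixed_threshold
    else:
        if pixels.min() == pixels.max():
            logger.warning(
                "Otsu undefined on constant image (eye=%s angle=%s); falling back to fixed threshold %d",
                image.eye_id, image.scan_angle, config.fixed_threshold,
            )
            threshold = config.fixed_threshold
        else:
            threshold = threshold_otsu(pixels)
    return pixels > threshold


def denoise(mask: BinaryMask, config: PreprocessConfig | None = None) -> BinaryMask:
    """Morphological opening with the square ``opening_radius`` neighborhood.

    Opening is anti-extensive (never adds white pixels) and idempotent;
    radius 0 is the identity. The default 3x3 element erases single-pixel
    speckle while leaving multi-pixel cell spots intact.
    """
    config = config or PreprocessConfig()
    mask = np.asarray(mask, dtype=bool)
    r = config.opening_radius
    if r == 0:
        return mask.copy()
    return opening(mask, np.ones((2 * r + 1, 2 * r + 1), dtype=bool))


def _max_white_run(column: np.ndarray) -> int:
    """Longest run of consecutive True values in a 1-D boolean array."""
    padded = np.concatenate(([False], column, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if edges.size == 0:
        return 0
    return int((edges[1::2] - edges[0::2]).max())


def remove_fixation_artifact(mask: BinaryMask, config: PreprocessConfig | None = None) -> BinaryMask:
    """Zero the central vertical fixation-artifact line, if present.

    A column qualifies when it lies in the central third of the image and
    its longest vertical white run exceeds H/2. Qualifying columns are
    grouped into contiguous bands; a band wider than
    ``artifact_max_width`` is left alone (it is anatomy or fibrin, for the
    exclusion gate to judge), otherwise its columns are zeroed entirely.
    """
    config = config or PreprocessConfig()
    mask = np.asarray(mask, dtype=bool)
    if not config.artifact_removal:
        return mask.copy()
    H, W = mask.shape
    lo, hi = W // 3, 2 * W // 3  # central third, [lo, hi)
    qualifies = np.zeros(W, dtype=bool)
    for col in range(lo, hi):
        if _max_white_run(mask[:, col]) > H / 2:
            qualifies[col] = True
    out = mask.copy()
    if not qualifies.any():
        return out
    padded = np.concatenate(([False], qualifies, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[0::2], edges[1::2]):
        if stop - start <= config.artifact_max_width:
            logger.info("fixation artifact removed: columns %d..%d", start, stop - 1)
            out[:, start:stop] = False
    return out


def preprocess_scan(image: OCTImage, config: PreprocessConfig | None = None) -> BinaryMask:
    """Full chain: binarize, artifact removal, opening."""
    config = config or PreprocessConfig()
    mask = binarize(image, config)
    mask = remove_fixation_artifact(mask, config)
    return denoise(mask, config)
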