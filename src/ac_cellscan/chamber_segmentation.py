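"""Anterior-chamber segmentation via border following.

The anterior chamber (AC) is the dark aqueous region bounded above by the
bright corneal arc and below by the bright iris/lens complex. Candidate
dark regions are found on a structure-scale morphological opening of the
binarized scan (which erases cell-sized white spots while preserving the
thick anatomical bands), and the largest dark component bounded by bright
structure above and below is selected as the AC. Its outline is traced
with a Suzuki–Abe style border-following algorithm, which also serves the
generic contour-extraction operation with an outer/hole hierarchy.

Connectivity pairing is the standard one for border following:
8-connectivity for white structures, 4-connectivity for dark regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import closing, disk, erosion, opening

from .errors import SegmentationError
from .preprocess import BinaryMask

# 8-neighborhood offsets in counterclockwise order starting east.
_DI = (0, -1, -1, -1, 0, 1, 1, 1)
_DJ = (1, 1, 0, -1, -1, -1, 0, 1)
_DIR_OF = {(_DI[d], _DJ[d]): d for d in range(8)}

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Contour:
    """An ordered, 8-connected border of a white region or of a hole.

    ``points`` are (row, col) pixel coordinates in traversal order;
    ``hierarchy_level`` is 0 for outermost white borders, increasing by
    one per nesting level (a hole directly inside a level-0 region has
    level 1, a component inside that hole level 2, ...).
    """

    points: list[tuple[int, int]]
    closed: bool
    hierarchy_level: int
    is_hole: bool


def trace_contours(mask: BinaryMask) -> list[Contour]:
    """Trace all outer and hole borders of a binary mask.

    Border-following in the style of Suzuki & Abe: a raster scan assigns a
    sequential number to each new border met and follows it around its
    connected component, labelling pixels so each border is traced exactly
    once. Every white 8-connected component yields exactly one outer
    contour; every 4-connected hole yields one hole contour. An empty mask
    yields ``[]``.
    """
    m = np.asarray(mask, dtype=bool)
    H, W = m.shape
    f = np.zeros((H + 2, W + 2), dtype=np.int32)
    f[1:-1, 1:-1] = m
    border_is_hole = {1: True}  # NBD 1 is the frame, treated as a hole border
    parent = {1: 0}
    traced: list[tuple[int, list[tuple[int, int]], bool]] = []
    nbd = 1

    for i in range(1, H + 1):
        lnbd = 1
        row_nonzero = np.flatnonzero(f[i] != 0)  # marking never zeroes a pixel
        for j in row_nonzero:
            j = int(j)
            fij = f[i, j]
            is_outer = fij == 1 and f[i, j - 1] == 0
            is_hole = fij >= 1 and f[i, j + 1] == 0
            if is_outer or is_hole:
                nbd += 1
                if is_outer:
                    i2, j2 = i, j - 1
                else:
                    i2, j2 = i, j + 1
                    if fij > 1:
                        lnbd = fij
                border_is_hole[nbd] = not is_outer
                if border_is_hole[lnbd] == border_is_hole[nbd]:
                    parent[nbd] = parent[lnbd]
                else:
                    parent[nbd] = lnbd
                points = _follow_border(f, i, j, i2, j2, nbd)
                traced.append((nbd, points, border_is_hole[nbd]))
            if f[i, j] != 1:
                lnbd = abs(int(f[i, j]))

    levels = {1: -1}
    for b in sorted(parent):
        if b == 1:
            continue
        levels[b] = levels[parent[b]] + 1

    contours = []
    for b, points, is_hole in traced:
        pts = [(r - 1, c - 1) for r, c in points]
        contours.append(
            Contour(points=pts, closed=len(pts) >= 3, hierarchy_level=levels[b], is_hole=is_hole)
        )
    return contours


def _follow_border(f: np.ndarray, i: int, j: int, i2: int, j2: int, nbd: int) -> list[tuple[int, int]]:
    """Follow one border starting at (i, j); marks pixels in-place."""
    d0 = _DIR_OF[(i2 - i, j2 - j)]
    i1 = j1 = None
    for k in range(8):  # clockwise search for a nonzero neighbor
        d = (d0 - k) % 8
        ii, jj = i + _DI[d], j + _DJ[d]
        if f[ii, jj] != 0:
            i1, j1 = ii, jj
            break
    if i1 is None:
        f[i, j] = -nbd  # isolated pixel
        return [(i, j)]

    points = []
    i2, j2 = i1, j1
    i3, j3 = i, j
    while True:
        d0 = _DIR_OF[(i2 - i3, j2 - j3)]
        examined_right_zero = False
        i4 = j4 = 0
        for k in range(1, 9):  # counterclockwise search
            d = (d0 + k) % 8
            ii, jj = i3 + _DI[d], j3 + _DJ[d]
            if f[ii, jj] != 0:
                i4, j4 = ii, jj
                break
            if (ii, jj) == (i3, j3 + 1):
                examined_right_zero = True
        if examined_right_zero:
            f[i3, j3] = -nbd
        elif f[i3, j3] == 1:
            f[i3, j3] = nbd
        points.append((i3, j3))
        if (i4, j4) == (i, j) and (i3, j3) == (i1, j1):
            return points
        i2, j2 = i3, j3
        i3, j3 = i4, j4


@dataclass
class ChamberConfig:
    """Knobs for chamber detection.

    structure_radius
        Disk radius of the opening that isolates anatomical structures;
        white features thinner than ~2x this radius (cell spots, thin
        artifacts) are erased before dark-region analysis.
    boundary_margin
        Erosion applied to the selected cavity so the AC mask does not
        annex corneal/iris boundary pixels.
    seal_radius
        Closing applied before the structure opening so narrow slits
        (e.g. the zeroed fixation-artifact column cutting through the
        cornea) do not leak the cavity into the background.
    min_area
        Minimum candidate area in pixels.
    central_fraction
        Horizontal band (centered) within which the above/below enclosure
        test is evaluated.
    enclosure_min_fraction
        Minimum fraction of tested columns that must have bright
        structure both above and below the candidate.
    """

    structure_radius: int = 8
    boundary_margin: int = 2
    seal_radius: int = 2
    min_area: int = 100
    central_fraction: float = 0.8
    enclosure_min_fraction: float = 0.95


@dataclass
class ChamberSegmentation:
    """The AC interior mask, its bounding contour, and pixel area."""

    mask: BinaryMask
    contour: Contour
    area: int
    centroid: tuple[float, float] = field(default=(0.0, 0.0))


def _enclosure_fraction(region: np.ndarray, structures: np.ndarray, central_fraction: float) -> float:
    """Fraction of the region's central-band columns with structure above and below."""
    H, W = region.shape
    half_band = central_fraction / 2.0
    lo = int(np.floor(W * (0.5 - half_band)))
    hi = int(np.ceil(W * (0.5 + half_band)))
    cols = np.flatnonzero(region[:, lo:hi].any(axis=0)) + lo
    if cols.size == 0:
        return 1.0 if not _touches_border(region) else 0.0
    cum = np.cumsum(structures, axis=0)
    rows = np.arange(H)[:, None]
    sub = region[:, cols]
    top = np.where(sub.any(axis=0), np.argmax(sub, axis=0), 0)
    bottom = H - 1 - np.argmax(sub[::-1], axis=0)
    above = np.zeros(cols.size, dtype=bool)
    nz = top > 0
    above[nz] = cum[top[nz] - 1, cols[nz]] > 0
    below = (cum[-1, cols] - cum[bottom, cols]) > 0
    return float(np.mean(above & below))


def _vertical_closure(region: np.ndarray) -> np.ndarray:
    """Per column, fill all rows between the region's first and last pixel."""
    H, W = region.shape
    has = region.any(axis=0)
    top = np.where(has, np.argmax(region, axis=0), H)
    bottom = np.where(has, H - 1 - np.argmax(region[::-1], axis=0), -1)
    rows = np.arange(H)[:, None]
    return (rows >= top[None, :]) & (rows <= bottom[None, :])


def _touches_border(region: np.ndarray) -> bool:
    return bool(region[0].any() or region[-1].any() or region[:, 0].any() or region[:, -1].any())


def segment_chamber(binarized: BinaryMask, config: ChamberConfig | None = None) -> ChamberSegmentation:
    """Locate the anterior-chamber cavity in a binarized B-scan.

    Candidates are dark 4-connected components of the structure-opened
    mask that touch neither the top nor the bottom image row and are
    bounded by bright structure above and below across the central
    columns (or are fully enclosed). The largest candidate wins; ties go
    to the higher (smaller-row) centroid. The final AC mask is the
    column-wise vertical closure of the winning component — the full
    cavity between its upper and lower envelopes — so intra-chamber
    content (cell spots, fibrin) lies inside the mask by construction;
    it is then shrunk by ``boundary_margin`` to stay clear of anatomy.

    Raises :class:`SegmentationError` when no candidate exists, which
    marks the image unanalyzable (distinct from fibrin-gate removal).
    """
    config = config or ChamberConfig()
    m = np.asarray(binarized, dtype=bool)
    H, W = m.shape
    # seal narrow slits (zeroed fixation-artifact columns) before the
    # structure opening so they neither leak the cavity nor notch its rim
    sealed = closing(m, disk(config.seal_radius)) if config.seal_radius > 0 else m
    structures = opening(sealed, disk(config.structure_radius)) if config.structure_radius > 0 else sealed
    dark = ~structures
    labels, n_labels = ndi.label(dark, structure=_CROSS)
    if n_labels == 0:
        raise SegmentationError("no dark region in scan")

    edge_labels = set(np.unique(labels[0])) | set(np.unique(labels[-1]))
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    candidates: list[tuple[int, int, float]] = []  # (area, label, centroid_row)
    for lab in range(1, n_labels + 1):
        if lab in edge_labels or areas[lab] < config.min_area:
            continue
        region = labels == lab
        if _enclosure_fraction(region, structures, config.central_fraction) < config.enclosure_min_fraction:
            continue
        centroid_row = float(np.mean(np.nonzero(region)[0]))
        candidates.append((int(areas[lab]), lab, centroid_row))
    if not candidates:
        raise SegmentationError("no enclosed dark region qualifies as anterior chamber")

    # largest area; ties broken by the higher centroid (AC sits under the cornea)
    candidates.sort(key=lambda t: (-t[0], t[2]))
    _, lab, _ = candidates[0]
    # The cavity interior is the full vertical span of the selected dark
    # component, so intra-chamber content (cell spots, fibrin) that the
    # structure opening classified as "bright" still lies inside the mask.
    mask = _vertical_closure(labels == lab)
    if config.boundary_margin > 0:
        mask = erosion(mask, disk(config.boundary_margin))
        labels2, n2 = ndi.label(mask, structure=_CROSS)
        if n2 == 0:
            raise SegmentationError("chamber candidate vanished under boundary margin")
        if n2 > 1:
            sizes = np.bincount(labels2.ravel())[1:]
            mask = labels2 == (int(np.argmax(sizes)) + 1)

    outer = [c for c in trace_contours(mask) if not c.is_hole]
    contour = max(outer, key=lambda c: len(c.points))
    rows, cols = np.nonzero(mask)
    return ChamberSegmentation(
        mask=mask,
        contour=contour,
        area=int(mask.sum()),
        centroid=(float(rows.mean()), float(cols.mean())),
    )
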