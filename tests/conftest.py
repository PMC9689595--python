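import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage as ndi

from ac_cellscan.chamber_segmentation import ChamberSegmentation, Contour

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")


@pytest.fixture
def brute_force_tile_count():
    """Independent oracle: double loop over every 5x5 tile."""

    def _count(binarized, chamber_mask, tile=5):
        active = np.asarray(binarized, bool) & np.asarray(chamber_mask, bool)
        H, W = active.shape
        n = 0
        for r0 in range(0, H, tile):
            for c0 in range(0, W, tile):
                if active[r0 : r0 + tile, c0 : c0 + tile].any():
                    n += 1
        return n

    return _count


@pytest.fixture
def reconstruct_from_contours():
    """Oracle: rebuild a mask by filling outer contours and carving hole interiors."""

    def _reconstruct(contours, shape):
        out = np.zeros(shape, dtype=bool)
        for c in sorted(contours, key=lambda c: c.hierarchy_level):
            pts = np.zeros(shape, dtype=bool)
            for r, col in c.points:
                pts[r, col] = True
            filled = ndi.binary_fill_holes(pts)
            if c.is_hole:
                out &= ~(filled & ~pts)
            else:
                out |= filled
        return out

    return _reconstruct


@pytest.fixture
def assert_contours_characterize_mask(reconstruct_from_contours):
    """Independent contour oracle via connected-component labeling.

    Checks, for an arbitrary mask: exactly one outer contour per
    8-connected white component and one hole contour per 4-connected
    hole; every component's traced border points sandwiched between its
    pixels 4-adjacent and 8-adjacent to background; and fill-based
    reconstruction exact away from the border band (borders that weave
    diagonally around an interior pixel are inherently ambiguous to a
    point-set fill, so deviations may only occur on band pixels).
    """
    S8 = np.ones((3, 3), dtype=int)
    S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    def _check(mask, contours):
        mask = np.asarray(mask, dtype=bool)
        lab_w, n_comp = ndi.label(mask, structure=S8)
        lab_b, n_bg = ndi.label(np.pad(~mask, 1, constant_values=True), structure=S4)
        assert sum(not c.is_hole for c in contours) == n_comp
        assert sum(c.is_hole for c in contours) == n_bg - 1  # minus the exterior

        bg = np.pad(~mask, 1, constant_values=True)
        band4 = mask & ndi.binary_dilation(bg, structure=S4)[1:-1, 1:-1]
        band8 = mask & ndi.binary_dilation(bg, structure=S8)[1:-1, 1:-1]
        traced: dict[int, set] = {}
        for c in contours:
            r0, c0 = c.points[0]
            traced.setdefault(lab_w[r0, c0], set()).update(c.points)
        for comp in range(1, n_comp + 1):
            cm = lab_w == comp
            inner = {tuple(p) for p in np.argwhere(band4 & cm)}
            outer = {tuple(p) for p in np.argwhere(band8 & cm)}
            assert inner <= traced[comp] <= outer

        rec = reconstruct_from_contours(contours, mask.shape)
        assert not (rec & ~mask).any()
        assert not ((mask & ~rec) & ~band8).any()

    return _check


@pytest.fixture
def make_chamber():
    """Wrap a plain boolean mask as a ChamberSegmentation for gate/count tests."""

    def _make(mask):
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        return ChamberSegmentation(
            mask=mask,
            contour=Contour(points=[], closed=False, hierarchy_level=0, is_hole=False),
            area=int(mask.sum()),
            centroid=(float(rows.mean()), float(cols.mean())),
        )

    return _make
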