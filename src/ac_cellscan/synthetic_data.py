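"""Synthetic AS-OCT B-scans and cohorts with exact ground truth.

A rendered scan emulates the geometry the pipeline relies on: a bright
parabolic corneal band across the top, a bright iris/lens band below, a
dark aqueous chamber between them, small bright disk-shaped cell spots
inside the chamber, optional diffuse fibrin blobs, an optional 1-px
vertical fixation-artifact line at the image center, and additive
Gaussian noise standing in for speckle. Everything is seeded and
deterministic.

By default spot centers snap to the centers of distinct 5x5 tiles, so the
ground-truth tile count equals the number of spots placed and end-to-end
fidelity is exactly testable; clumping scenarios are produced by turning
that alignment off.

Cohorts invert the count-to-grade calibration: each eye draws a SUN grade
from a specified census, receives a target total count of about
exp((g - b)/a) perturbed by lognormal dispersion, and spreads it over
four radial scans. Fibrin-heavy grade-4 eyes exercise the exclusion gate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.morphology import disk, erosion

from .errors import GenerationError
from .grading import CalibrationModel, published_model
from .imaging_io import CohortManifest, EyeRecord, OCTImage, SCAN_ANGLES, save_image, write_manifest

# scene intensities (8-bit)
BACKGROUND = 15
CORNEA = 230
IRIS = 220
FIBRIN = 210
ARTIFACT = 200

# anatomy as fractions of image height
_CORNEA_APEX = 0.10
_CORNEA_SAG = 0.23
_BAND_THICKNESS = 0.0667
_IRIS_TOP = 0.7333


@dataclass
class ScanRecipe:
    """Parameters of one rendered B-scan."""

    W: int = 800
    H: int = 600
    n_spots: int = 0
    spot_radius: int = 1
    spot_intensity: int = 180
    noise_sigma: float = 0.0
    fibrin_fraction: float = 0.0
    fixation_artifact: bool = False
    seed: int = 0
    align_spots_to_tiles: bool = True
    enforce_separation: bool = True

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise GenerationError("n_spots must be >= 0")
        if not 0.0 <= self.fibrin_fraction <= 1.0:
            raise GenerationError("fibrin_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact scene knowledge for one rendered scan."""

    chamber_mask: np.ndarray
    spot_centers: list[tuple[int, int]]
    true_count: int
    fibrin_present: bool


def _anatomy(W: int, H: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cornea band, iris band, and the dark chamber between them."""
    cols = np.arange(W)
    half = max((W - 1) / 2.0, 1.0)
    top = _CORNEA_APEX * H + _CORNEA_SAG * H * ((cols - (W - 1) / 2.0) / half) ** 2
    thick = max(3, int(round(_BAND_THICKNESS * H)))
    rows = np.arange(H)[:, None]
    cornea = (rows >= top[None, :]) & (rows < top[None, :] + thick)
    iris_top = int(round(_IRIS_TOP * H))
    iris_band = (rows >= iris_top) & (rows < iris_top + thick)
    iris = np.broadcast_to(iris_band, (H, W)).copy()
    chamber = (rows >= top[None, :] + thick) & (rows < iris_top)
    return cornea, iris, chamber


def _spot_sites(recipe: ScanRecipe, chamber: np.ndarray, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Choose seeded spot centers inside the chamber."""
    H, W = chamber.shape
    pad = recipe.spot_radius + 2
    allowed = erosion(chamber, disk(pad)) if pad > 0 else chamber
    if recipe.fixation_artifact:
        lo = max(0, W // 2 - (recipe.spot_radius + 3))
        hi = min(W, W // 2 + (recipe.spot_radius + 3) + 1)
        allowed = allowed.copy()
        allowed[:, lo:hi] = False

    if recipe.align_spots_to_tiles:
        rr, cc = np.meshgrid(np.arange(2, H, 5), np.arange(2, W, 5), indexing="ij")
        sites = np.stack([rr.ravel(), cc.ravel()], axis=1)
        sites = sites[allowed[sites[:, 0], sites[:, 1]]]
    else:
        rows, cols = np.nonzero(allowed)
        sites = np.stack([rows, cols], axis=1)
    if sites.shape[0] < recipe.n_spots:
        raise GenerationError(
            f"cannot place {recipe.n_spots} spots: only {sites.shape[0]} candidate sites"
        )
    order = rng.permutation(sites.shape[0])
    if not recipe.enforce_separation:
        return [tuple(map(int, sites[k])) for k in order[: recipe.n_spots]]

    min_sep = 2 * (recipe.spot_radius + 3)
    chosen: list[tuple[int, int]] = []
    chosen_arr = np.empty((0, 2), dtype=int)
    for k in order:
        cand = sites[k]
        if chosen_arr.shape[0]:
            d2 = ((chosen_arr - cand[None, :]) ** 2).sum(axis=1)
            if d2.min() < min_sep**2:
                continue
        chosen.append((int(cand[0]), int(cand[1])))
        chosen_arr = np.vstack([chosen_arr, cand[None, :]])
        if len(chosen) == recipe.n_spots:
            return chosen
    raise GenerationError(
        f"could not place {recipe.n_spots} spots with separation >= {min_sep}px "
        f"(placed {len(chosen)})"
    )


def _paint_disks(scene: np.ndarray, centers: list[tuple[int, int]], radius: int, value: int) -> None:
    H, W = scene.shape
    # digital disk with +0.5 inclusion: radius 1 renders a full 3x3 block,
    # which survives the pipeline's small square opening exactly
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= (radius + 0.5) ** 2
    ]
    for r, c in centers:
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W:
                scene[rr, cc] = value


def _paint_fibrin(
    scene: np.ndarray, chamber: np.ndarray, fraction: float, rng: np.random.Generator
) -> None:
    """Flood the chamber with dense bright fibrin flecks.

    Severe fibrin shows up in the binarized chamber as extensive
    contiguous white spots; it is rendered as overlapping medium-sized
    flecks (a few pixels across — well below the anatomy scale, well
    above the cell scale) placed until they cover ``fraction`` of the
    chamber area.
    """
    H, W = scene.shape
    rows, cols = np.nonzero(chamber)
    area = rows.size
    covered = np.zeros_like(chamber)
    n_covered = 0
    for _ in range(20000):
        if n_covered / area >= fraction:
            break
        k = rng.integers(rows.size)
        cr, cc = int(rows[k]), int(cols[k])
        radius = rng.uniform(3.0, 6.0)
        r = int(math.ceil(radius))
        r0, r1 = max(0, cr - r), min(H, cr + r + 1)
        c0, c1 = max(0, cc - r), min(W, cc + r + 1)
        yy, xx = np.ogrid[r0:r1, c0:c1]
        blob = ((yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2) & chamber[r0:r1, c0:c1]
        n_covered += int((blob & ~covered[r0:r1, c0:c1]).sum())
        covered[r0:r1, c0:c1] |= blob
        scene[r0:r1, c0:c1][blob] = FIBRIN


def generate_scan(recipe: ScanRecipe) -> tuple[OCTImage, GroundTruth]:
    """Render one synthetic B-scan and its exact ground truth."""
    rng = np.random.default_rng(recipe.seed)
    W, H = recipe.W, recipe.H
    cornea, iris, chamber = _anatomy(W, H)

    scene = np.full((H, W), BACKGROUND, dtype=np.float64)
    scene[cornea] = CORNEA
    scene[iris] = IRIS

    if recipe.fibrin_fraction > 0:
        _paint_fibrin(scene, chamber, recipe.fibrin_fraction, rng)

    centers = _spot_sites(recipe, chamber, rng) if recipe.n_spots > 0 else []
    _paint_disks(scene, centers, recipe.spot_radius, recipe.spot_intensity)

    if recipe.fixation_artifact:
        scene[:, W // 2] = ARTIFACT

    if recipe.noise_sigma > 0:
        scene = scene + rng.normal(0.0, recipe.noise_sigma, size=scene.shape)
    pixels = np.clip(np.rint(scene), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        chamber_mask=chamber,
        spot_centers=centers,
        true_count=len(centers),
        fibrin_present=recipe.fibrin_fraction > 0,
    )
    return OCTImage(pixels=pixels), truth


#: Grade census of the original analyzable cohort (48 eyes): grade -> eyes.
DEFAULT_GRADE_CENSUS = {0.0: 13, 0.5: 6, 1.0: 12, 2.0: 10, 3.0: 7}


@dataclass
class CohortGroundTruth:
    """Per-eye scene knowledge for a generated cohort."""

    grade: float
    total_count: int
    per_scan_counts: list[int]
    fibrin: bool
    scans: list[GroundTruth] = field(default_factory=list)


def _census_from_distribution(n_eyes: int, distribution: dict[float, float]) -> dict[float, int]:
    total = sum(distribution.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise GenerationError(f"grade proportions must sum to 1, got {total}")
    quotas = {g: n_eyes * p for g, p in distribution.items()}
    counts = {g: int(math.floor(q)) for g, q in quotas.items()}
    rest = n_eyes - sum(counts.values())
    for g in sorted(quotas, key=lambda g: (-(quotas[g] - counts[g]), g))[:rest]:
        counts[g] += 1
    return counts


def generate_cohort(
    out_dir: str | Path,
    n_eyes: int = 48,
    grade_distribution: dict[float, float] | None = None,
    model: CalibrationModel | None = None,
    count_noise: float = 0.4,
    seed: int = 0,
    n_fibrin_eyes: int = 0,
    recipe_defaults: ScanRecipe | None = None,
) -> tuple[CohortManifest, dict[str, CohortGroundTruth]]:
    """Write a synthetic cohort (PNGs + manifest CSV + truth JSON) to disk.

    Each analyzable eye's total spot count targets the inverse of the
    calibration curve at its grade, multiplied by lognormal noise of
    dispersion ``count_noise`` (at least 1 spot — even clinically quiet
    eyes show occasional hyperreflective specks). ``n_fibrin_eyes``
    additional grade-4 eyes are rendered with dense fibrin in every scan
    so the exclusion gate removes them end to end.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    model = model or published_model()
    base_recipe = recipe_defaults or ScanRecipe()
    if grade_distribution is None:
        grade_distribution = {g: n / 48 for g, n in DEFAULT_GRADE_CENSUS.items()}
    census = _census_from_distribution(n_eyes, grade_distribution)

    rng = np.random.default_rng(seed)
    eyes: list[EyeRecord] = []
    truths: dict[str, CohortGroundTruth] = {}
    plan: list[tuple[float, bool]] = [(g, False) for g in sorted(census) for _ in range(census[g])]
    plan += [(4.0, True)] * n_fibrin_eyes

    for idx, (grade, fibrin) in enumerate(plan):
        eye_id = f"eye_{idx:03d}"
        if fibrin:
            per_scan = [150] * 4
            total = sum(per_scan)
        else:
            target = math.exp((grade - model.intercept) / model.slope)
            total = max(1, int(round(target * math.exp(rng.normal(0.0, count_noise)))))
            per_scan = rng.multinomial(total, [0.25] * 4).tolist()
        scan_paths = []
        scan_truths = []
        for angle, n_spots in zip(SCAN_ANGLES, per_scan):
            recipe = ScanRecipe(
                W=base_recipe.W,
                H=base_recipe.H,
                n_spots=int(n_spots),
                spot_radius=base_recipe.spot_radius,
                spot_intensity=base_recipe.spot_intensity,
                noise_sigma=base_recipe.noise_sigma,
                fibrin_fraction=0.5 if fibrin else 0.0,
                fixation_artifact=base_recipe.fixation_artifact,
                seed=int(rng.integers(0, 2**31 - 1)),
                align_spots_to_tiles=True,
                enforce_separation=False,
            )
            image, truth = generate_scan(recipe)
            path = out_dir / "images" / f"{eye_id}_{angle:03d}.png"
            save_image(image, path)
            scan_paths.append(path)
            scan_truths.append(truth)
        eyes.append(EyeRecord(eye_id=eye_id, sun_grade=grade, scans=tuple(scan_paths)))
        truths[eye_id] = CohortGroundTruth(
            grade=grade,
            total_count=int(sum(per_scan)),
            per_scan_counts=[int(c) for c in per_scan],
            fibrin=fibrin,
            scans=scan_truths,
        )

    manifest = CohortManifest(eyes=eyes, source=out_dir / "manifest.csv")
    write_manifest(manifest, out_dir / "manifest.csv")
    truth_json = {
        eid: {
            "grade": t.grade,
            "total_count": t.total_count,
            "per_scan_counts": t.per_scan_counts,
            "fibrin": t.fibrin,
        }
        for eid, t in truths.items()
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))
    return manifest, truths
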