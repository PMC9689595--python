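"""Reading and writing of AS-OCT B-scans and cohort manifests.

Conventions inherited by every downstream stage:

* pixels are stored row-major with the origin at the **top-left**, indexed
  0-based as ``(row, col)``;
* images are grayscale, 8- or 16-bit unsigned integers;
* RGB inputs are tolerated and converted by the arithmetic mean of the
  first three channels (screenshots and viewer exports are common);
* clinician anterior-chamber cell grades follow the SUN ordinal scale and
  are stored as floats ``{0.0, 0.5, 1.0, 2.0, 3.0, 4.0}``.

A cohort manifest is a UTF-8 CSV with header
``eye_id,sun_grade,scan_0,scan_45,scan_90,scan_135`` — one row per eye,
four radial B-scans (every 45 degrees) per eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError

#: SUN grading scale for anterior-chamber cells (0, 0.5+, 1+, 2+, 3+, 4+).
SUN_GRADES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)

#: Radial scan positions acquired per eye, in degrees.
SCAN_ANGLES = (0, 45, 90, 135)

_MANIFEST_COLUMNS = ("eye_id", "sun_grade", "scan_0", "scan_45", "scan_90", "scan_135")
_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class OCTImage:
    """One grayscale B-scan plus eye / scan-angle metadata."""

    pixels: np.ndarray
    eye_id: str = ""
    scan_angle: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"expected a 2-D grayscale array, got ndim={self.pixels.ndim}")
        if self.pixels.dtype not in (np.uint8, np.uint16):
            raise ValidationError(f"expected uint8 or uint16 pixels, got {self.pixels.dtype}")
        if self.pixels.size == 0:
            raise ValidationError("image must have positive width and height")
        if self.scan_angle not in SCAN_ANGLES:
            raise ValidationError(f"scan_angle must be one of {SCAN_ANGLES}, got {self.scan_angle}")

    @property
    def H(self) -> int:
        return self.pixels.shape[0]

    @property
    def W(self) -> int:
        return self.pixels.shape[1]

    @property
    def bit_depth(self) -> int:
        return 8 if self.pixels.dtype == np.uint8 else 16


@dataclass
class EyeRecord:
    """One eye: clinician SUN grade plus the paths of its 4 radial scans."""

    eye_id: str
    sun_grade: float
    scans: tuple[Path, Path, Path, Path]

    def __post_init__(self) -> None:
        if self.sun_grade not in SUN_GRADES:
            raise ValidationError(
                f"eye {self.eye_id!r}: grade {self.sun_grade} outside the SUN set {SUN_GRADES}"
            )
        if len(self.scans) != 4:
            raise ValidationError(f"eye {self.eye_id!r}: exactly 4 scans required, got {len(self.scans)}")
        self.scans = tuple(Path(p) for p in self.scans)  # type: ignore[assignment]


@dataclass
class CohortManifest:
    """An ordered collection of eyes read from a manifest CSV."""

    eyes: list[EyeRecord]
    source: Path = field(default_factory=lambda: Path("."))

    def __len__(self) -> int:
        return len(self.eyes)

    def __iter__(self):
        return iter(self.eyes)


def load_image(path: str | Path, eye_id: str = "", scan_angle: int = 0) -> OCTImage:
    """Read a grayscale PNG/TIFF B-scan.

    RGB(A) inputs are converted to grayscale by the arithmetic mean of the
    first three channels, rounded to the nearest integer of the source
    dtype. Raises :class:`InputError` for a missing file and
    :class:`FormatError` for unsupported formats.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r} (need PNG or TIFF)")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise FormatError(f"could not decode {path}: {exc}") from exc
    if arr.ndim == 3:
        dtype = arr.dtype
        arr = np.rint(arr[..., :3].astype(np.float64).mean(axis=2)).astype(dtype)
    if arr.dtype not in (np.uint8, np.uint16):
        # e.g. int32 PNGs decoded by some writers; normalise conservatively
        if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 65535:
            arr = arr.astype(np.uint16 if arr.max() > 255 else np.uint8)
        else:
            raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path}")
    return OCTImage(pixels=arr, eye_id=eye_id, scan_angle=scan_angle)


def save_image(image: OCTImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as PNG or TIFF (dtype preserved)."""
    path = Path(path)
    pixels = image.pixels if isinstance(image, OCTImage) else np.asarray(image)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported output format {path.suffix!r}")
    iio.imwrite(path, pixels)


def _parse_grade(raw: object) -> float:
    text = str(raw).strip().rstrip("+")
    try:
        grade = float(text)
    except ValueError:
        raise ValidationError(f"unparseable SUN grade {raw!r}") from None
    if grade not in SUN_GRADES:
        raise ValidationError(f"SUN grade {raw!r} outside the set {SUN_GRADES}")
    return grade


def load_manifest(path: str | Path, check_files: bool = True) -> CohortManifest:
    """Load a cohort manifest CSV, preserving row order.

    Scan paths are resolved relative to the CSV's directory. With
    ``check_files=True`` every referenced image must exist.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"manifest not found: {path}")
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns: {missing}")

    base = path.parent
    eyes: list[EyeRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        eye_id = str(row["eye_id"]).strip()
        if eye_id in seen:
            raise ValidationError(f"duplicate eye_id {eye_id!r} in {path}")
        seen.add(eye_id)
        grade = _parse_grade(row["sun_grade"])
        scans = []
        for col in _MANIFEST_COLUMNS[2:]:
            raw = row[col]
            if pd.isna(raw) or not str(raw).strip():
                raise ValidationError(f"eye {eye_id!r}: missing scan path in column {col!r}")
            scan_path = Path(str(raw).strip())
            if not scan_path.is_absolute():
                scan_path = base / scan_path
            if check_files and not scan_path.is_file():
                raise ValidationError(f"eye {eye_id!r}: scan file not found: {scan_path}")
            scans.append(scan_path)
        eyes.append(EyeRecord(eye_id=eye_id, sun_grade=grade, scans=tuple(scans)))
    return CohortManifest(eyes=eyes, source=path)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest CSV with paths relative to the output directory."""
    path = Path(path)
    base = path.parent
    rows = []
    for eye in manifest.eyes:
        scans = []
        for p in eye.scans:
            try:
                scans.append(str(p.relative_to(base)))
            except ValueError:
                scans.append(str(p))
        grade = eye.sun_grade
        rows.append(
            {
                "eye_id": eye.eye_id,
                "sun_grade": f"{grade:g}",
                **dict(zip(_MANIFEST_COLUMNS[2:], scans)),
            }
        )
    pd.DataFrame(rows, columns=list(_MANIFEST_COLUMNS)).to_csv(path, index=False)
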