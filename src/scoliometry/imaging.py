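"""Radiograph loading, spine-region selection, cropping and equalization.

Images are plain 2-D float64 arrays with intensities in [0, 1], row 0 at the
top of the image and (row, col) indexing throughout.  The 4-point region
annotation uses (x, y) click coordinates, i.e. (col, row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

GrayImage = np.ndarray  # 2-D float array, values in [0, 1]


class DegenerateRegionError(ValueError):
    """The 4 annotation points collapse to a line or point on some axis."""


class UnsupportedFormatError(ValueError):
    """The file is readable but not a supported single-frame grayscale image."""


@dataclass(frozen=True)
class RegionBox:
    """Axis-aligned spine selection box.

    ``left``/``right`` are column bounds, ``low``/``up`` row bounds
    (``low`` = topmost row index, ``up`` = bottommost), all inclusive.
    """

    left: int
    right: int
    low: int
    up: int

    def __post_init__(self) -> None:
        if not (self.left < self.right and self.low < self.up):
            raise DegenerateRegionError(
                f"degenerate region box: left={self.left} right={self.right} "
                f"low={self.low} up={self.up}"
            )


def as_gray_image(pixels: np.ndarray) -> GrayImage:
    """Validate and coerce an array to the GrayImage contract."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"GrayImage must be 2-D with shape >= (2, 2); got {arr.shape}")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("GrayImage intensities must lie in [0, 1]")
    return arr


def _rescale_minmax(arr: np.ndarray) -> GrayImage:
    # Constant images map to all-zero rather than dividing by zero.
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    if arr.ndim == 3:
        raise UnsupportedFormatError(f"multi-frame DICOM not supported: {path}")
    arr = arr.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    # MONOCHROME1 stores an inverted scale (air bright); flip so bone is bright.
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = arr.max() - arr
    return arr


def load_image(path: str | Path) -> GrayImage:
    """Read a DICOM/PNG/TIFF radiograph as a [0, 1] grayscale array.

    Intensities are min-max rescaled; a constant image maps to all zeros.
    DICOM rescale slope/intercept and photometric interpretation are honored
    so that bone is always bright.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        arr = _load_dicom(path)
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"could not read image {path}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 3:
            if arr.shape[2] in (3, 4):
                # Luma reduction; alpha ignored.
                arr = arr[..., :3].astype(np.float64) @ np.array([0.2126, 0.7152, 0.0722])
            else:
                raise UnsupportedFormatError(f"unsupported channel layout {arr.shape}: {path}")
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"expected a single 2-D frame, got shape {arr.shape}: {path}")
    return as_gray_image(_rescale_minmax(arr))


def select_region(points: Sequence[Sequence[float]]) -> RegionBox:
    """Build the spine selection box from 4 annotation clicks.

    Boundaries are the coordinate extrema: left = min x, right = max x,
    low = min y, up = max y.  Invariant under any permutation of the points.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape != (4, 2):
        raise ValueError(f"expected exactly 4 (x, y) points, got shape {pts.shape}")
    x, y = pts[:, 0], pts[:, 1]
    return RegionBox(
        left=int(x.min()), right=int(x.max()), low=int(y.min()), up=int(y.max())
    )


def load_roi(path: str | Path) -> RegionBox:
    """Read a JSON ROI annotation (``{"points": [[x, y], ...]}``)."""
    with open(path) as fh:
        payload = json.load(fh)
    return select_region(payload["points"])


def crop(image: GrayImage, box: RegionBox) -> GrayImage:
    """Extract the region box (inclusive bounds) from the image."""
    image = as_gray_image(image)
    n_rows, n_cols = image.shape
    if box.left < 0 or box.low < 0 or box.right >= n_cols or box.up >= n_rows:
        raise IndexError(
            f"region box {box} exceeds image of shape {image.shape}"
        )
    return image[box.low : box.up + 1, box.left : box.right + 1].copy()


def equalize_histogram(image: GrayImage, n_bins: int = 256) -> GrayImage:
    """Histogram equalization over a fixed 256-bin quantization of [0, 1].

    Each pixel maps to the empirical CDF of its intensity bin, which spreads
    the dynamic range and highlights the bright spinal column.  The mapping
    is monotone (rank order of pixels is preserved or tied) and idempotent up
    to one bin width.  Constant images are returned unchanged.
    """
    image = as_gray_image(image)
    if image.max() == image.min():
        return image.copy()
    levels = np.minimum((image * n_bins).astype(np.intp), n_bins - 1)
    counts = np.bincount(levels.ravel(), minlength=n_bins)
    cdf = np.cumsum(counts) / image.size
    return cdf[levels]
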