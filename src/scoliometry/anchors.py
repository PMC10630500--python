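"""Anchor-point extraction: row-wise maxima, local extrema, cleanup and sieve.

A candidate anchor is a pixel that is both its row's global intensity maximum
and a strict local maximum within a 3-5 pixel horizontal neighborhood.  The
sieve keeps only anchors whose connecting line to the previously kept anchor
makes at most 45 degrees with the vertical axis (|slope| > 1 in row/col
units), discarding lateral noise jumps that no real spine can make between
adjacent rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import morphology

from .imaging import GrayImage
from .symmetry import BinaryMask

logger = logging.getLogger(__name__)

_KINDS = ("global-max", "local-extremum", "candidate", "fine")


class EmptyAnchorsError(ValueError):
    """No candidate anchors to sieve."""


@dataclass(frozen=True)
class AnchorSet:
    """Ordered (row, col) point collection of a given kind."""

    points: tuple[tuple[int, int], ...]
    kind: str = "candidate"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown anchor kind {self.kind!r}")
        if self.kind in ("candidate", "fine"):
            rows = [r for r, _ in self.points]
            if len(set(rows)) != len(rows):
                raise ValueError(f"{self.kind} anchors must have at most one point per row")
            if self.kind == "fine" and any(b <= a for a, b in zip(rows, rows[1:])):
                raise ValueError("fine anchor rows must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        # float64: anchors from images are integer pixels, but subpixel
        # coordinates are legal downstream (curve fitting).
        if not self.points:
            return np.empty(0), np.empty(0)
        arr = np.asarray(self.points, dtype=np.float64)
        return arr[:, 0], arr[:, 1]

    def to_mask(self, shape: tuple[int, int]) -> BinaryMask:
        mask = np.zeros(shape, dtype=np.uint8)
        rows, cols = self.as_arrays()
        mask[rows.astype(np.intp), cols.astype(np.intp)] = 1
        return mask

    @classmethod
    def from_mask(cls, mask: BinaryMask, kind: str) -> "AnchorSet":
        rows, cols = np.nonzero(mask)
        order = np.lexsort((cols, rows))
        return cls(tuple((int(r), int(c)) for r, c in zip(rows[order], cols[order])), kind)


@dataclass(frozen=True)
class SieveConfig:
    """Tunables of the anchor extraction and sieve stage.

    max_angle_deg: largest angle the line between consecutive fine anchors may
        make with the vertical axis (45 degrees == |slope| > 1).
    local_radius: half-width of the local-extremum neighborhood, 3-5 px.
    min_object_area: opening removes point-map components smaller than this.
    erosion_size: side of the square erosion element (with empty-result guard).
    connectivity: 4 or 8, for component labeling.
    """

    max_angle_deg: float = 45.0
    local_radius: int = 3
    min_object_area: int = 3
    erosion_size: int = 2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.local_radius not in (3, 4, 5):
            raise ValueError(f"local_radius must be in {{3, 4, 5}}; got {self.local_radius}")
        if not (0.0 < self.max_angle_deg < 90.0):
            raise ValueError(f"max_angle_deg must lie in (0, 90); got {self.max_angle_deg}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8; got {self.connectivity}")


def row_global_maxima(image: GrayImage, mask: BinaryMask | None = None) -> AnchorSet:
    """One point per row at the brightest pixel; ties break leftmost.

    If ``mask`` is given, pixels outside it are treated as 0.  Rows whose
    (gated) intensities are constant emit no point: there is nothing to
    distinguish, and fully masked-out rows fall in this case.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
        image = image * (mask != 0)
    has_range = image.max(axis=1) > image.min(axis=1)
    cols = image.argmax(axis=1)  # argmax is leftmost on ties
    points = tuple(
        (int(r), int(cols[r])) for r in np.nonzero(has_range)[0]
    )
    return AnchorSet(points, "global-max")


def row_local_extrema(image: GrayImage, radius: int = 3) -> AnchorSet:
    """Pixels strictly brighter than every neighbor within ``radius`` columns.

    Boundary columns compare only against in-range neighbors; plateaus are
    excluded by the strict inequality.
    """
    if radius not in (3, 4, 5):
        raise ValueError(f"radius must be in {{3, 4, 5}}; got {radius}")
    image = np.asarray(image, dtype=np.float64)
    is_peak = np.ones(image.shape, dtype=bool)
    for d in range(1, radius + 1):
        # Out-of-range neighbors are vacuously smaller (-inf fill).
        right = np.full_like(image, -np.inf)
        right[:, :-d] = image[:, d:]
        left = np.full_like(image, -np.inf)
        left[:, d:] = image[:, :-d]
        is_peak &= (image > right) & (image > left)
    return AnchorSet.from_mask(is_peak, "local-extremum")


def remove_small_objects(mask: BinaryMask, min_area: int = 3, connectivity: int = 8) -> BinaryMask:
    """Opening step: delete connected components with fewer than ``min_area`` pixels."""
    mask = np.asarray(mask) != 0
    conn = 1 if connectivity == 4 else 2
    cleaned = morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=conn)
    return cleaned.astype(np.uint8)


def erode_square(mask: BinaryMask, size: int = 2) -> BinaryMask:
    """Binary erosion with a size x size square structuring element.

    Size 1 is the identity.  If erosion would empty a non-empty mask (as any
    size >= 3 does to 1-pixel-wide point chains) the input is returned
    unchanged and a warning is logged, so the anchor chain is never destroyed
    by an over-aggressive element.
    """
    if size < 1:
        raise ValueError(f"size must be >= 1; got {size}")
    mask = (np.asarray(mask) != 0).astype(np.uint8)
    if size == 1:
        return mask.copy()
    eroded = morphology.erosion(mask, footprint=np.ones((size, size), dtype=np.uint8))
    if not eroded.any() and mask.any():
        logger.warning("erosion with %dx%d square would empty the mask; input kept", size, size)
        return mask.copy()
    return eroded.astype(np.uint8)


def candidate_anchors(global_set: AnchorSet, local_set: AnchorSet) -> AnchorSet:
    """Intersect the global-max and local-extremum point sets.

    Exact (row, col) matches only; if a row retains several intersection
    points, the leftmost is kept.
    """
    common = sorted(set(global_set.points) & set(local_set.points))
    per_row: dict[int, int] = {}
    for r, c in common:
        if r not in per_row or c < per_row[r]:
            per_row[r] = c
    return AnchorSet(tuple((r, per_row[r]) for r in sorted(per_row)), "candidate")


def sieve_fine_anchors(candidates: AnchorSet, cfg: SieveConfig | None = None) -> AnchorSet:
    """Slope-sieve candidates into fine anchors.

    Starting from the topmost candidate (always kept), a candidate is accepted
    when the line to the current fine anchor is vertical or steeper than the
    configured angle with the y-axis (|d_row/d_col| > tan(90 deg - max_angle);
    for 45 degrees, ratio > 1).  Rejected candidates are skipped and the scan
    continues downward from the same fine anchor.
    """
    if cfg is None:
        cfg = SieveConfig()
    if len(candidates) == 0:
        raise EmptyAnchorsError("cannot sieve an empty candidate set")
    # Compare angles, not slopes: atan2(|dc|, |dr|) is exact at the 45-degree
    # boundary (dr == dc), where tan(radians(45)) suffers roundoff.
    max_angle = math.radians(cfg.max_angle_deg)
    pts = sorted(candidates.points)
    kept = [pts[0]]
    for r2, c2 in pts[1:]:
        r1, c1 = kept[-1]
        if c2 == c1 or math.atan2(abs(c2 - c1), abs(r2 - r1)) < max_angle:
            kept.append((r2, c2))
    return AnchorSet(tuple(kept), "fine")
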