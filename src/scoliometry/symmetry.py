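"""Flip-overlay suppression of centrally symmetric structure.

Anatomy that is symmetric under a point reflection through the image center
(ribs, pelvis, soft-tissue gradients) reproduces its own intensity in the
half-plus-reflected-half overlay, while a laterally deviated (scoliotic)
spine contributes only half its intensity at each of two mirror locations.
Thresholding the overlay at 0.5 therefore keeps the brightest asymmetric
structure and discards symmetric background below the cutoff.
"""

from __future__ import annotations

import numpy as np

from .imaging import GrayImage, as_gray_image

OverlayImage = np.ndarray
BinaryMask = np.ndarray  # uint8 {0, 1}


def _point_reflect(arr: np.ndarray) -> np.ndarray:
    """Reflect through index (floor(M/2), floor(N/2)); out-of-range -> 0.

    The mirror of index i is 2*floor(M/2) - i.  For odd M this is the exact
    reversal M-1-i; for even M index 0 maps past the last row and the
    contribution is zero-filled.
    """
    m, n = arr.shape
    rows = 2 * (m // 2) - np.arange(m)
    cols = 2 * (n // 2) - np.arange(n)
    row_ok = (rows >= 0) & (rows < m)
    col_ok = (cols >= 0) & (cols < n)
    out = np.zeros_like(arr)
    out[np.ix_(row_ok, col_ok)] = arr[np.ix_(rows[row_ok], cols[col_ok])]
    return out


def flip_overlay(image: GrayImage) -> OverlayImage:
    """Superimpose the half-intensity image with its point reflection.

    G(i, j) = X(i, j) + X(2*floor(M/2) - i, 2*floor(N/2) - j) with X = image/2
    and zero contribution from mirrored coordinates outside the grid.  Values
    provably stay in [0, 1]; a centrally symmetric input (odd dimensions)
    reproduces itself.
    """
    image = as_gray_image(image)
    half = image / 2.0
    overlay = half + _point_reflect(half)
    assert overlay.min() >= 0.0 and overlay.max() <= 1.0 + 1e-12
    return np.clip(overlay, 0.0, 1.0)


def binarize(overlay: OverlayImage, cutoff: float = 0.5, strict: bool = False) -> BinaryMask:
    """Threshold the overlay into a {0, 1} mask.

    Default comparison is non-strict (pixel >= cutoff -> 1): a maximal
    asymmetric pixel over a zero background lands exactly at 0.5 after
    halving and must survive.  ``strict=True`` uses > instead.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError(f"cutoff must lie in (0, 1); got {cutoff}")
    overlay = np.asarray(overlay, dtype=np.float64)
    if strict:
        return (overlay > cutoff).astype(np.uint8)
    return (overlay >= cutoff).astype(np.uint8)
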