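"""Spine-curve fitting and the standardized integral area.

Fine anchors (row, col) are interpolated by a natural cubic spline
col = f(row).  The chord joining the first and last curve points is the
reference line; the standardized area is the summed horizontal distance
between curve and chord over equally spaced sampling rows, normalized by the
curve's horizontal extent max f - min f.  The score is dimensionless and
invariant to image scale and to the amplitude of the deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .anchors import AnchorSet

#: extents below this (in px) are treated as a straight spine -> area 0
_STRAIGHT_EPS = 1e-6


class InsufficientAnchorsError(ValueError):
    """Fewer than 2 fine anchors: no curve can be fitted."""


@dataclass(frozen=True)
class SpineCurve:
    """Interpolating curve col = f(row) through the fine anchors."""

    anchors: AnchorSet
    evaluator: Callable[[np.ndarray], np.ndarray]
    kind: str  # cubic | quadratic | linear
    row_first: float
    row_last: float

    def __call__(self, rows: np.ndarray | float) -> np.ndarray | float:
        return self.evaluator(rows)


@dataclass(frozen=True)
class AreaResult:
    """Raw deviation-length sum and its normalized form."""

    raw_sum: float
    n_segments: int
    norm_factor: float
    standardized_area: float
    variant: str  # mean | literal


def fit_spline(anchors: AnchorSet) -> SpineCurve:
    """Interpolate fine anchors: natural cubic spline for >= 4 points,
    quadratic for 3, straight line for 2."""
    rows, cols = anchors.as_arrays()
    if len(rows) < 2:
        raise InsufficientAnchorsError(f"need >= 2 anchors, got {len(rows)}")
    if np.any(np.diff(rows) <= 0):
        raise ValueError("anchor rows must be strictly increasing")
    r = rows.astype(np.float64)
    c = cols.astype(np.float64)
    if len(r) >= 4:
        spline = CubicSpline(r, c, bc_type="natural")
        evaluator, kind = spline, "cubic"
    elif len(r) == 3:
        poly = np.polynomial.Polynomial.fit(r, c, deg=2)
        evaluator, kind = poly, "quadratic"
    else:
        poly = np.polynomial.Polynomial.fit(r, c, deg=1)
        evaluator, kind = poly, "linear"
    return SpineCurve(
        anchors=anchors,
        evaluator=evaluator,
        kind=kind,
        row_first=float(r[0]),
        row_last=float(r[-1]),
    )


def reference_line(curve: SpineCurve) -> tuple[tuple[float, float], tuple[float, float]]:
    """Chord from the first to the last point of the fitted curve."""
    r0, r1 = curve.row_first, curve.row_last
    return (r0, float(curve(r0))), (r1, float(curve(r1)))


def _chord_evaluator(curve: SpineCurve) -> Callable[[np.ndarray], np.ndarray]:
    (r0, c0), (r1, c1) = reference_line(curve)
    slope = (c1 - c0) / (r1 - r0)
    return lambda rows: c0 + slope * (np.asarray(rows, dtype=np.float64) - r0)


def curve_extent(curve: SpineCurve) -> float:
    """Horizontal extent max f - min f over a dense per-row sampling."""
    rows = np.arange(np.ceil(curve.row_first), np.floor(curve.row_last) + 1.0)
    rows = np.concatenate(([curve.row_first], rows, [curve.row_last]))
    vals = np.asarray(curve(rows), dtype=np.float64)
    return float(vals.max() - vals.min())


def standardized_area(
    curve: SpineCurve, n_segments: int = 100, variant: str = "mean"
) -> AreaResult:
    """Standardized integral area between the curve and its reference chord.

    ``n_segments`` horizontal sampling rows are placed at
    r_k = row_first + k * H / n (k = 0..n-1, H the row span), so the length
    sum divided by n is the Riemann-sum estimate of the mean absolute
    horizontal deviation.  Variant ``mean`` (default) reports
    (raw_sum / n) / extent, variant ``literal`` reports raw_sum / extent
    (exactly n times the mean variant).  A straight spine (extent below
    1e-6 px) scores 0.
    """
    if n_segments < 2:
        raise ValueError(f"n_segments must be >= 2; got {n_segments}")
    if variant not in ("mean", "literal"):
        raise ValueError(f"variant must be 'mean' or 'literal'; got {variant!r}")
    span = curve.row_last - curve.row_first
    rows = curve.row_first + np.arange(n_segments) * (span / n_segments)
    chord = _chord_evaluator(curve)
    lengths = np.abs(np.asarray(curve(rows), dtype=np.float64) - chord(rows))
    raw_sum = float(lengths.sum())
    norm = curve_extent(curve)
    if norm < _STRAIGHT_EPS:
        area = 0.0
    elif variant == "mean":
        area = (raw_sum / n_segments) / norm
    else:
        area = raw_sum / norm
    return AreaResult(
        raw_sum=raw_sum,
        n_segments=n_segments,
        norm_factor=norm,
        standardized_area=area,
        variant=variant,
    )
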