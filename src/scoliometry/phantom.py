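"""Synthetic full-spine radiograph phantoms with known ground truth.

A phantom is a bright, vertically running vertebral band with a Gaussian
cross-section laid over a centrally symmetric background (radial gradient
plus point-symmetric decoy blobs) and optional additive Gaussian noise.  The
band's centerline col = g(row) is parametric and analytically known, so the
standardized area of every phantom has an independent dense-quadrature value
and every pipeline stage can be validated without patient data.

The phantoms emulate the geometry and contrast ordering of a radiograph
(spine brightest, symmetric anatomy dimmer), not its anatomy: there are no
vertebra outlines, ribs or projection physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .grading import GradingConfig, classify_severity
from .imaging import GrayImage

_FAMILIES = ("straight", "half-sine", "double-sine", "polynomial")

#: default S-shaped polynomial deviation (zero endpoint slope, so the
#: centerline respects the sieve's 45-degree assumption at all amplitudes)
_CUBIC_SHAPE = lambda t: t**2 * (1.0 - t) ** 2 * (t - 0.4)


class PhantomSpecError(ValueError):
    """The requested centerline does not fit the image with a safe margin."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic radiograph.

    ``amplitude`` is the deviation amplitude in px, ``tilt`` the total
    horizontal drift of the chord across the image (px); the centerline is
    re-centered so its horizontal midrange sits at the image center.  Odd
    default dimensions make the point reflection of the flip overlay exact.
    """

    height: int = 401
    width: int = 201
    family: str = "half-sine"
    amplitude: float = 30.0
    tilt: float = 0.0
    phase: float = 0.0
    coefficients: tuple[float, ...] | None = None
    band_sigma: float = 3.0
    band_peak: float = 0.7
    background_peak: float = 0.3
    decoy_peak: float = 0.2
    n_decoy_pairs: int = 3
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown centerline family {self.family!r}")
        if self.band_sigma < 1.0:
            raise ValueError("band_sigma must be >= 1 px")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one phantom."""

    centerline: Callable[[np.ndarray], np.ndarray]  # col = g(row)
    true_area: float  # mean-variant standardized area (dense quadrature)
    true_grade: str
    corridor: float  # candidate anchors should fall within +/- this of g


def _deviation(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    """Horizontal deviation (px) as a function of normalized row t in [0, 1]."""
    a = spec.amplitude
    if spec.family == "straight":
        return np.zeros_like(t)
    if spec.family == "half-sine":
        return a * np.sin(math.pi * t + spec.phase)
    if spec.family == "double-sine":
        return a * np.sin(2.0 * math.pi * t + spec.phase)
    if spec.coefficients is not None:
        return np.polynomial.polynomial.polyval(t, np.asarray(spec.coefficients))
    shape = _CUBIC_SHAPE(t)
    peak = np.max(np.abs(_CUBIC_SHAPE(np.linspace(0.0, 1.0, 10001))))
    return a * shape / peak


def centerline_function(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form centerline col = g(row), midrange-centered in the image."""
    span = spec.height - 1

    def raw(rows: np.ndarray) -> np.ndarray:
        t = np.asarray(rows, dtype=np.float64) / span
        return spec.tilt * t + _deviation(spec, t)

    dense = raw(np.linspace(0.0, span, 4096))
    offset = (spec.width - 1) / 2.0 - (dense.max() + dense.min()) / 2.0
    return lambda rows: raw(rows) + offset


def oracle_area(
    centerline: Callable[[np.ndarray], np.ndarray],
    row_first: float,
    row_last: float,
    n_dense: int = 100_000,
) -> float:
    """Brute-force mean-variant standardized area of an exact centerline.

    Mean absolute horizontal deviation from the endpoint chord over
    ``n_dense`` uniform row samples, divided by the centerline's horizontal
    extent.  Independent of the spline pipeline; serves as its oracle.
    """
    if n_dense < 10_000:
        raise ValueError("n_dense must be >= 10000 for a trustworthy quadrature")
    rows = np.linspace(row_first, row_last, n_dense)
    vals = np.asarray(centerline(rows), dtype=np.float64)
    chord = vals[0] + (vals[-1] - vals[0]) * (rows - row_first) / (row_last - row_first)
    extent = float(vals.max() - vals.min())
    if extent < 1e-9:
        return 0.0
    return float(np.mean(np.abs(vals - chord)) / extent)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, GroundTruth]:
    """Render a phantom radiograph and its analytic ground truth.

    image = clip(background + band + noise, 0, 1) with
    band(r, c) = band_peak * exp(-(c - g(r))^2 / (2 band_sigma^2)).
    Identical specs (same seed) give bit-identical images.
    """
    g = centerline_function(spec)
    rows = np.arange(spec.height, dtype=np.float64)
    cols = np.arange(spec.width, dtype=np.float64)
    center = g(rows)
    margin = 4.0 * spec.band_sigma + 2.0
    if center.min() < margin or center.max() > spec.width - 1 - margin:
        raise PhantomSpecError(
            f"centerline extent {center.min():.1f}..{center.max():.1f} leaves "
            f"less than the {margin:.0f} px margin in a width-{spec.width} image"
        )

    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0

    # Radial gradient: bright at center, exactly point-symmetric.
    dist = np.hypot(rr - cy, cc - cx)
    image = spec.background_peak * (1.0 - dist / dist.max())

    # Decoy blobs in point-symmetric pairs: they survive the flip overlay at
    # full intensity and exercise its suppression contract, but stay dimmer
    # than the band so the row maxima have a well-defined truth.
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.n_decoy_pairs):
        br = rng.uniform(0.1, 0.9) * (spec.height - 1)
        bc = rng.uniform(0.1, 0.9) * (spec.width - 1)
        sigma = rng.uniform(4.0, 9.0)
        for pr, pc in ((br, bc), (2 * cy - br, 2 * cx - bc)):
            image += spec.decoy_peak * np.exp(
                -((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * sigma**2)
            )

    image += spec.band_peak * np.exp(
        -((cc - center[:, None]) ** 2) / (2.0 * spec.band_sigma**2)
    )

    if spec.noise_sigma > 0.0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)

    image = np.clip(image, 0.0, 1.0)
    true_area = oracle_area(g, 0.0, spec.height - 1.0)
    truth = GroundTruth(
        centerline=g,
        true_area=true_area,
        true_grade=classify_severity(true_area),
        corridor=spec.band_sigma,
    )
    return image, truth


def solve_tilt_for_area(
    target_area: float,
    amplitude: float = 30.0,
    height: int = 401,
    width: int = 301,
    tol: float = 1e-4,
) -> float:
    """Chord tilt (px) giving a tilted half-sine the requested standardized area.

    A pure half-sine scores 2/pi regardless of amplitude (deviation and
    extent both scale with A); tilting the chord grows the extent without
    changing the deviation, so the area decreases monotonically with tilt
    and can be solved by bisection against the quadrature oracle.
    """
    if not (0.0 < target_area < 2.0 / math.pi):
        raise ValueError(f"target area must lie in (0, 2/pi); got {target_area}")

    def area_of(tilt: float) -> float:
        spec = PhantomSpec(
            height=height, width=width, family="half-sine", amplitude=amplitude, tilt=tilt
        )
        return oracle_area(centerline_function(spec), 0.0, height - 1.0, n_dense=20_000)

    lo, hi = 0.0, 4.0 * amplitude / (math.pi * target_area)
    while area_of(hi) > target_area:  # pragma: no cover - generous initial bracket
        hi *= 2.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if area_of(mid) > target_area:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


_AREA_BANDS = {"mild": (0.06, 0.19), "moderate": (0.21, 0.39), "severe": (0.40, 0.56)}


@dataclass(frozen=True)
class CohortCase:
    case_id: str
    spec: PhantomSpec
    truth: GroundTruth
    nominal_cobb: float  # degrees


def generate_cohort(
    n: int,
    grade_mix: Sequence[float] = (0.4, 0.5, 0.1),
    seed: int = 0,
    jitter_sd: float = 3.0,
    noise_sigma: float = 0.0,
    height: int = 401,
    width: int = 301,
    grading: GradingConfig | None = None,
) -> list[CohortCase]:
    """Reproducible synthetic cohort with known per-case truth.

    Each case draws a severity grade from ``grade_mix`` (mild, moderate,
    severe proportions), a target area uniform within that grade's band, a
    tilted half-sine phantom realizing it, and a nominal manual Cobb angle
    from the published affine relation plus Gaussian jitter (``jitter_sd``
    degrees, the assumed inter-observer noise of manual measurement).
    """
    if n < 3:
        raise ValueError("cohort needs n >= 3")
    if grading is None:
        grading = GradingConfig()
    mix = np.asarray(grade_mix, dtype=np.float64)
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    for k in range(n):
        grade = ("mild", "moderate", "severe")[rng.choice(3, p=mix)]
        lo, hi = _AREA_BANDS[grade]
        target = float(rng.uniform(lo, hi))
        # Extent scales as (2A/pi)/area, so small target areas need a smaller
        # amplitude for the tilted centerline to fit the image width.
        usable = width - 1 - 2 * (4.0 * 3.0 + 2.0)
        amplitude = float(min(30.0, target * 0.9 * usable * math.pi / 2.0))
        tilt = solve_tilt_for_area(target, amplitude=amplitude, height=height, width=width)
        spec = PhantomSpec(
            height=height,
            width=width,
            family="half-sine",
            amplitude=amplitude,
            tilt=tilt,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        g = centerline_function(spec)
        true_area = oracle_area(g, 0.0, height - 1.0)
        cobb = (
            grading.cobb_intercept
            + grading.cobb_slope * true_area
            + (float(rng.normal(0.0, jitter_sd)) if jitter_sd > 0 else 0.0)
        )
        truth = GroundTruth(
            centerline=g,
            true_area=true_area,
            true_grade=classify_severity(true_area, grading),
            corridor=spec.band_sigma,
        )
        cases.append(CohortCase(case_id=f"case{k:03d}", spec=spec, truth=truth, nominal_cobb=cobb))
    return cases


def write_phantom_png(image: GrayImage, path) -> None:
    """Write a phantom as 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(str(path), np.round(np.asarray(image) * 255.0).astype(np.uint8))
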