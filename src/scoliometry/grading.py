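"""Severity grading and Cobb-angle estimation from the standardized area.

The published bands put mild scoliosis at area <= 0.2, severe at >= 0.4 and
moderate in between; the published linear relation to the manually measured
Cobb angle is Cobb = 13.36 + 70.54 x area (degrees).
"""

from __future__ import annotations

from dataclasses import dataclass

MILD = "mild"
MODERATE = "moderate"
SEVERE = "severe"


@dataclass(frozen=True)
class GradingConfig:
    mild_max: float = 0.2
    severe_min: float = 0.4
    cobb_intercept: float = 13.36  # degrees
    cobb_slope: float = 70.54  # degrees per unit area

    def __post_init__(self) -> None:
        if not (0.0 < self.mild_max < self.severe_min):
            raise ValueError(
                f"require 0 < mild_max < severe_min; got {self.mild_max}, {self.severe_min}"
            )


def classify_severity(area: float, cfg: GradingConfig | None = None) -> str:
    """Map a standardized area to mild/moderate/severe.

    Boundary values follow the printed inequalities: <= mild_max is mild,
    >= severe_min is severe, moderate is the open interval between.
    """
    if cfg is None:
        cfg = GradingConfig()
    if area < 0:
        raise ValueError(f"standardized area must be >= 0; got {area}")
    if area <= cfg.mild_max:
        return MILD
    if area >= cfg.severe_min:
        return SEVERE
    return MODERATE


def estimate_cobb(area: float, cfg: GradingConfig | None = None) -> float:
    """Estimated Cobb angle (degrees) from the published affine relation."""
    if cfg is None:
        cfg = GradingConfig()
    if area < 0:
        raise ValueError(f"standardized area must be >= 0; got {area}")
    return cfg.cobb_intercept + cfg.cobb_slope * area
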