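"""End-to-end measurement pipeline and batch/evaluation orchestration.

run_pipeline executes the full chain on one image:

    crop -> equalize -> flip overlay -> binarize -> row maxima / local
    extrema (mask-gated) -> morphological cleanup -> candidate intersection
    -> slope sieve -> spline fit -> standardized area -> grade + Cobb

Everything is deterministic for a fixed (image, ROI, config) triple; failures
in batch mode are recorded per image, never fatal to the batch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchors as anchors_mod
from . import curve as curve_mod
from . import evaluation, grading, imaging, symmetry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the measurement chain in one place."""

    sieve: anchors_mod.SieveConfig = field(default_factory=anchors_mod.SieveConfig)
    grading: grading.GradingConfig = field(default_factory=grading.GradingConfig)
    binarize_cutoff: float = 0.5
    binarize_strict: bool = False
    gating: str = "gated"  # gated | ungated: maxima restricted to the overlay mask?
    # Erosion applied to the overlay mask by default: eroding 1-px-wide
    # per-row point chains deletes them wholesale under noise.
    erode_target: str = "mask"  # points | mask | both
    n_segments: int = 100
    area_variant: str = "mean"

    def __post_init__(self) -> None:
        if self.gating not in ("gated", "ungated"):
            raise ValueError(f"gating must be 'gated' or 'ungated'; got {self.gating!r}")
        if self.erode_target not in ("points", "mask", "both"):
            raise ValueError(f"bad erode_target {self.erode_target!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sieve" in d:
            d["sieve"] = anchors_mod.SieveConfig(**d["sieve"])
        if "grading" in d:
            d["grading"] = grading.GradingConfig(**d["grading"])
        return cls(**d)


@dataclass(frozen=True)
class MeasurementReport:
    image_id: str
    status: str  # ok | measurement-failed
    n_fine_anchors: int
    area: curve_mod.AreaResult | None
    grade: str | None
    estimated_cobb: float | None
    warnings: tuple[str, ...]
    config_fingerprint: str

    @property
    def standardized_area(self) -> float | None:
        return None if self.area is None else self.area.standardized_area

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["warnings"] = list(self.warnings)
        return d


def run_pipeline(
    image: imaging.GrayImage,
    roi: imaging.RegionBox,
    cfg: PipelineConfig | None = None,
    image_id: str = "image",
) -> MeasurementReport:
    """Measure the standardized area of one radiograph."""
    if cfg is None:
        cfg = PipelineConfig()
    warnings: list[str] = []

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    roi_img = _stage("crop", imaging.crop, image, roi)
    equalized = _stage("equalize", imaging.equalize_histogram, roi_img)
    overlay = _stage("flip_overlay", symmetry.flip_overlay, equalized)
    mask = _stage(
        "binarize", symmetry.binarize, overlay, cfg.binarize_cutoff, cfg.binarize_strict
    )
    if cfg.erode_target in ("mask", "both"):
        mask = _stage("erode_mask", anchors_mod.erode_square, mask, cfg.sieve.erosion_size)

    gate = mask if cfg.gating == "gated" else None
    gated = equalized * (np.asarray(mask) != 0) if gate is not None else equalized
    global_set = _stage("row_global_maxima", anchors_mod.row_global_maxima, equalized, gate)
    local_set = _stage("row_local_extrema", anchors_mod.row_local_extrema, gated, cfg.sieve.local_radius)

    def _cleanup(point_set: anchors_mod.AnchorSet) -> anchors_mod.AnchorSet:
        pm = point_set.to_mask(roi_img.shape)
        pm = anchors_mod.remove_small_objects(pm, cfg.sieve.min_object_area, cfg.sieve.connectivity)
        if cfg.erode_target in ("points", "both"):
            before = pm.copy()
            pm = anchors_mod.erode_square(pm, cfg.sieve.erosion_size)
            if np.array_equal(pm, before) and cfg.sieve.erosion_size > 1:
                warnings.append("erosion guard fired on point map")
        return anchors_mod.AnchorSet.from_mask(pm, point_set.kind)

    global_set = _cleanup(global_set)
    local_set = _cleanup(local_set)
    candidates = _stage("candidate_anchors", anchors_mod.candidate_anchors, global_set, local_set)

    fingerprint = cfg.fingerprint()
    try:
        fine = anchors_mod.sieve_fine_anchors(candidates, cfg.sieve)
        spine = curve_mod.fit_spline(fine)
    except (anchors_mod.EmptyAnchorsError, curve_mod.InsufficientAnchorsError) as exc:
        warnings.append(f"measurement failed: {exc}")
        return MeasurementReport(
            image_id=image_id,
            status="measurement-failed",
            n_fine_anchors=0,
            area=None,
            grade=None,
            estimated_cobb=None,
            warnings=tuple(warnings),
            config_fingerprint=fingerprint,
        )
    area = curve_mod.standardized_area(spine, cfg.n_segments, cfg.area_variant)
    grade = grading.classify_severity(area.standardized_area, cfg.grading)
    cobb = grading.estimate_cobb(area.standardized_area, cfg.grading)
    return MeasurementReport(
        image_id=image_id,
        status="ok",
        n_fine_anchors=len(spine.anchors),
        area=area,
        grade=grade,
        estimated_cobb=cobb,
        warnings=tuple(warnings),
        config_fingerprint=fingerprint,
    )


def run_batch(manifest: str | Path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Measure every image listed in a manifest CSV (columns: id, image, roi).

    Per-row failures are recorded in the ``status``/``error`` columns and
    never abort the batch.
    """
    if cfg is None:
        cfg = PipelineConfig()
    manifest = Path(manifest)
    try:
        table = pd.read_csv(manifest)
    except Exception as exc:
        raise IOError(f"could not read manifest {manifest}: {exc}") from exc
    rows = []
    for rec in table.itertuples(index=False):
        row = {"id": rec.id, "image": rec.image}
        try:
            img = imaging.load_image(_resolve(manifest, rec.image))
            box = imaging.load_roi(_resolve(manifest, rec.roi))
            report = run_pipeline(img, box, cfg, image_id=str(rec.id))
            row.update(
                status=report.status,
                standardized_area=report.standardized_area,
                grade=report.grade,
                estimated_cobb=report.estimated_cobb,
                n_fine_anchors=report.n_fine_anchors,
                n_warnings=len(report.warnings),
                error="",
            )
        except Exception as exc:
            logger.warning("batch row %s failed: %s", rec.id, exc)
            row.update(
                status="error",
                standardized_area=None,
                grade=None,
                estimated_cobb=None,
                n_fine_anchors=0,
                n_warnings=1,
                error=str(exc),
            )
        rows.append(row)
    columns = [
        "id", "image", "status", "standardized_area", "grade",
        "estimated_cobb", "n_fine_anchors", "n_warnings", "error",
    ]
    return pd.DataFrame(rows, columns=columns)


def _resolve(manifest: Path, entry: str) -> Path:
    p = Path(entry)
    return p if p.is_absolute() else manifest.parent / p


def run_evaluation(
    batch: pd.DataFrame,
    manual: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Compare measured areas with manual Cobb angles.

    ``manual`` needs columns ``id`` and ``manual_cobb``.  Emits Spearman
    rho/p, ROC for the moderate-or-worse task (max-sensitivity policy) and
    the severe task (max-specificity policy), and the OLS fit of Cobb on
    area.  ROC labels come from the manual-Cobb severity bands: moderate
    means Cobb > 25 degrees, severe Cobb > 45.
    """
    if cfg is None:
        cfg = PipelineConfig()
    ok = batch[batch["status"] == "ok"][["id", "standardized_area"]]
    joined = ok.merge(manual[["id", "manual_cobb"]], on="id")
    if len(joined) < 3:
        raise ValueError(f"need >= 3 joined records, got {len(joined)}")
    areas = joined["standardized_area"].to_numpy(dtype=float)
    cobb = joined["manual_cobb"].to_numpy(dtype=float)
    rho, p = evaluation.spearman(list(zip(cobb, areas)))
    intercept, slope = evaluation.linear_fit(areas, cobb)
    out = {
        "n": int(len(joined)),
        "spearman_rho": rho,
        "spearman_p": p,
        "regression": {"intercept": intercept, "slope": slope},
    }
    for task, threshold, policy in (
        ("moderate", 25.0, evaluation.MAX_SENSITIVITY),
        ("severe", 45.0, evaluation.MAX_SPECIFICITY),
    ):
        labels = (cobb > threshold).astype(int)
        if labels.min() == labels.max():
            out[f"roc_{task}"] = None
            continue
        roc = evaluation.roc_with_youden(areas, labels, policy)
        out[f"roc_{task}"] = dataclasses.asdict(roc)
    return out
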