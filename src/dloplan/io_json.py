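"""Landmark and result serialization.

The interchange format is a small JSON document (``LandmarkFileV1``)
holding named 2D points in pixel coordinates plus the calibration scale
measured from a 100 x 100 mm reference square.  It stands in for the
measurements a planner would take in any DICOM viewer; no pixel data are
ever read.  Unknown fields are rejected so that typos fail loudly.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import CalibrationError, LandmarkValidationError
from .geometry import Calibration, Point2
from .landmarks import LimbLandmarks

SCHEMA_VERSION = 1
_PRECISION = 4  # decimal places for mm / degrees in files


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PointModel(_Strict):
    x: float
    y: float

    @field_validator("x", "y")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("coordinate must be finite")
        return v


class CalibrationModel(_Strict):
    mm_per_pixel: float = Field(gt=0)
    is_calibrated: bool = True


class PointsModel(_Strict):
    hip_center: PointModel
    plateau_medial: PointModel
    plateau_lateral: PointModel
    condyle_medial: PointModel
    condyle_lateral: PointModel
    ankle_center: PointModel


class SegmentsModel(_Strict):
    femoral_medial_cortex: list[PointModel] = Field(min_length=2, max_length=2)
    femoral_lateral_cortex: list[PointModel] = Field(min_length=2, max_length=2)
    tibial_medial_cortex: list[PointModel] = Field(min_length=2, max_length=2)
    tibial_lateral_cortex: list[PointModel] = Field(min_length=2, max_length=2)


class HingesModel(_Strict):
    femoral: Optional[PointModel] = None
    tibial: Optional[PointModel] = None


class PlanOverridesModel(_Strict):
    target_percent: Optional[float] = None
    nmjl_angle: Optional[float] = None
    tibial_hinge_offset: Optional[float] = None
    femoral_hinge_offset: Optional[float] = None
    tibial_osteotomy_entry_offset: Optional[float] = None
    osteotomy_obliquity: Optional[float] = None
    uncalibrated_gap_increment: Optional[float] = None
    apply_jlca_adjustment: Optional[bool] = None


class LandmarkFileV1(_Strict):
    schema_version: int
    patient_id: str
    side: str
    calibration: CalibrationModel
    points: PointsModel
    segments: SegmentsModel
    hinges: Optional[HingesModel] = None
    plan_overrides: Optional[PlanOverridesModel] = None

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}")
        return v

    @field_validator("side")
    @classmethod
    def _side(cls, v: str) -> str:
        if v not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        return v


# ---------------------------------------------------------------------------

def _to_mm(p: PointModel, s: float) -> Point2:
    return Point2(p.x * s, p.y * s)


def read_landmarks(path) -> LimbLandmarks:
    """Load, schema-validate and calibrate a landmark file.

    Coordinates are multiplied by ``mm_per_pixel``; the ``side`` flag is
    preserved and every downstream operation canonicalizes (mirrors a left
    limb) internally.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        doc = LandmarkFileV1.model_validate(raw)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise LandmarkValidationError(
            f"landmark file {path} failed validation at: {fields}") from exc

    s = doc.calibration.mm_per_pixel
    if s <= 0:
        raise CalibrationError("mm_per_pixel must be positive")
    pts = doc.points
    segs = doc.segments

    def seg(pair):
        return (_to_mm(pair[0], s), _to_mm(pair[1], s))

    hinges = doc.hinges or HingesModel()
    return LimbLandmarks(
        side=doc.side,
        hip_center=_to_mm(pts.hip_center, s),
        plateau_medial=_to_mm(pts.plateau_medial, s),
        plateau_lateral=_to_mm(pts.plateau_lateral, s),
        condyle_medial=_to_mm(pts.condyle_medial, s),
        condyle_lateral=_to_mm(pts.condyle_lateral, s),
        ankle_center=_to_mm(pts.ankle_center, s),
        femoral_medial_cortex=seg(segs.femoral_medial_cortex),
        femoral_lateral_cortex=seg(segs.femoral_lateral_cortex),
        tibial_medial_cortex=seg(segs.tibial_medial_cortex),
        tibial_lateral_cortex=seg(segs.tibial_lateral_cortex),
        calibration=Calibration(mm_per_pixel=s,
                                is_calibrated=doc.calibration.is_calibrated),
        femoral_hinge=_to_mm(hinges.femoral, s) if hinges.femoral else None,
        tibial_hinge=_to_mm(hinges.tibial, s) if hinges.tibial else None,
    )


def landmarks_to_document(lm: LimbLandmarks, patient_id: str = "anon") -> dict:
    """Serialize a landmark set back to the file schema (pixel coordinates,
    4-decimal rounding)."""
    s = lm.calibration.mm_per_pixel

    def pt(p: Point2) -> dict:
        return {"x": round(p.x / s, _PRECISION), "y": round(p.y / s, _PRECISION)}

    doc = {
        "schema_version": SCHEMA_VERSION,
        "patient_id": patient_id,
        "side": lm.side,
        "calibration": {"mm_per_pixel": s,
                        "is_calibrated": lm.calibration.is_calibrated},
        "points": {
            "hip_center": pt(lm.hip_center),
            "plateau_medial": pt(lm.plateau_medial),
            "plateau_lateral": pt(lm.plateau_lateral),
            "condyle_medial": pt(lm.condyle_medial),
            "condyle_lateral": pt(lm.condyle_lateral),
            "ankle_center": pt(lm.ankle_center),
        },
        "segments": {
            "femoral_medial_cortex": [pt(q) for q in lm.femoral_medial_cortex],
            "femoral_lateral_cortex": [pt(q) for q in lm.femoral_lateral_cortex],
            "tibial_medial_cortex": [pt(q) for q in lm.tibial_medial_cortex],
            "tibial_lateral_cortex": [pt(q) for q in lm.tibial_lateral_cortex],
        },
    }
    if lm.femoral_hinge or lm.tibial_hinge:
        doc["hinges"] = {
            "femoral": pt(lm.femoral_hinge) if lm.femoral_hinge else None,
            "tibial": pt(lm.tibial_hinge) if lm.tibial_hinge else None,
        }
    return doc


def write_landmarks(lm: LimbLandmarks, path, patient_id: str = "anon") -> None:
    write_json(landmarks_to_document(lm, patient_id), path)


# ---------------------------------------------------------------------------
# generic result serialization
# ---------------------------------------------------------------------------

def round_floats(obj, ndigits: int = _PRECISION):
    """Recursively round floats for stable, byte-identical JSON output."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round_floats(v, ndigits) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    """Atomic JSON write: serialize fully, then move into place, so an error
    never leaves a partial result file behind."""
    text = json.dumps(round_floats(payload), indent=2, sort_keys=True)
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def plan_to_document(plan) -> dict:
    c = plan.construction
    return {
        "femoral_correction_deg": plan.femoral_correction,
        "tibial_correction_deg": plan.tibial_correction,
        "femoral_gap_mm": plan.femoral_gap,
        "tibial_gap_mm": plan.tibial_gap,
        "jlca_adjustment_deg": plan.jlca_adjustment,
        "calibrated": plan.calibrated,
        "construction": {
            "correction_point": {"x": c.correction_point.x, "y": c.correction_point.y},
            "femoral_hinge": {"x": c.femoral_hinge.x, "y": c.femoral_hinge.y},
            "tibial_hinge": {"x": c.tibial_hinge.x, "y": c.tibial_hinge.y},
        },
    }


def analysis_to_document(stats) -> dict:
    return {
        "hka_deviation_deg": stats.hka_deviation,
        "hka_full_angle_deg": stats.hka_full_angle,
        "mpta_deg": stats.mpta,
        "ldfa_deg": stats.ldfa,
        "jlca_deg": stats.jlca,
        "wbl_percent": stats.wbl_percent,
        "mjl_angle_deg": stats.mjl_angle,
        "jlo_plateau_angle_deg": stats.jlo_plateau_angle,
    }
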