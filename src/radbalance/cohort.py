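"""Domain types and file I/O for radiograph cohort metadata and annotations.

A cohort is a list of :class:`ImageRecord`, one per radiograph, carrying the
patient/case metadata used for matched test-set construction (age, projection,
fracture presence, radiologist-graded difficulty) together with ground-truth
fracture bounding boxes.  Metadata travels as a flat CSV; boxes travel as
YOLO-style per-image text files (normalized center/size, class 0 = fracture).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BoundingBox",
    "ImageRecord",
    "ClassScore",
    "Detection",
    "MetadataError",
    "GENDERS",
    "LATERALITIES",
    "PROJECTIONS",
    "STUDY_TYPES",
    "DIFFICULTIES",
    "METADATA_COLUMNS",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "read_scores",
    "write_scores",
    "read_detections",
    "write_detections",
]

GENDERS = ("female", "male")
LATERALITIES = ("left", "right")
PROJECTIONS = ("ap", "lateral", "oblique")
STUDY_TYPES = ("initial", "followup")
DIFFICULTIES = ("easy", "difficult", "not_applicable")

METADATA_COLUMNS = (
    "image_id",
    "patient_age",
    "gender",
    "laterality",
    "projection",
    "study_type",
    "fracture",
    "difficulty",
    "diagnosis_uncertain",
    "image_width",
    "image_height",
)


class MetadataError(ValueError):
    """Raised when a metadata file violates the schema or record invariants."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in continuous 0-based corner coordinates.

    Areas are ``(x_max - x_min) * (y_max - y_min)`` with no +1 pixel
    correction, so the arithmetic matches normalized YOLO coordinates exactly.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "fracture"

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("box coordinates must be >= 0")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min


@dataclass
class ImageRecord:
    """One radiograph's metadata plus its ground-truth fracture boxes.

    ``difficulty`` is a radiologist's subjective grading of fracture
    visibility and is only meaningful for fracture-positive images; it is
    ``"not_applicable"`` exactly when ``fracture`` is false.
    """

    image_id: str
    patient_age: float
    gender: str
    laterality: str
    projection: str
    study_type: str
    fracture: bool
    difficulty: str
    diagnosis_uncertain: bool
    image_width: int = 640
    image_height: int = 640
    boxes: list[BoundingBox] = field(default_factory=list)

    def problems(self) -> list[str]:
        """Return invariant violations as human-readable strings (empty if valid)."""
        out: list[str] = []
        if self.gender not in GENDERS:
            out.append(f"gender={self.gender!r} not in {GENDERS}")
        if self.laterality not in LATERALITIES:
            out.append(f"laterality={self.laterality!r} not in {LATERALITIES}")
        if self.projection not in PROJECTIONS:
            out.append(f"projection={self.projection!r} not in {PROJECTIONS}")
        if self.study_type not in STUDY_TYPES:
            out.append(f"study_type={self.study_type!r} not in {STUDY_TYPES}")
        if self.difficulty not in DIFFICULTIES:
            out.append(f"difficulty={self.difficulty!r} not in {DIFFICULTIES}")
        elif self.fracture == (self.difficulty == "not_applicable"):
            out.append(
                f"difficulty={self.difficulty!r} inconsistent with fracture={self.fracture}"
            )
        if not (0.0 <= self.patient_age <= 19.0):
            out.append(f"patient_age={self.patient_age} outside [0, 19]")
        if self.image_width <= 0 or self.image_height <= 0:
            out.append("non-positive image extent")
        for b in self.boxes:
            if b.x_max > self.image_width or b.y_max > self.image_height:
                out.append(f"box {b} exceeds image extent")
        return out

    @property
    def stratum(self) -> str:
        """Prediction-difficulty stratum: easy_fracture / difficult_fracture / no_fracture."""
        if not self.fracture:
            return "no_fracture"
        return "difficult_fracture" if self.difficulty == "difficult" else "easy_fracture"


@dataclass(frozen=True)
class ClassScore:
    """A model's fracture-presence score for one image, in [0, 1]."""

    image_id: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class Detection:
    """A model's localized fracture prediction with its confidence in [0, 1]."""

    image_id: str
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


# ---------------------------------------------------------------------------
# metadata CSV


def _parse_bool(token: str) -> bool:
    t = token.strip().lower()
    if t == "true":
        return True
    if t == "false":
        return False
    raise ValueError(f"expected 'true'/'false', got {token!r}")


def read_metadata(path: str | Path) -> list[ImageRecord]:
    """Read a cohort metadata CSV into a list of :class:`ImageRecord`.

    Enumerated fields are parsed case-insensitively.  Rows violating record
    invariants make the whole file invalid; the raised :class:`MetadataError`
    lists every offending row (1-based, counting the header as line 1) with
    the fields at fault.  Boxes are not stored in the CSV and come back empty;
    attach them from annotation files if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ImageRecord] = []
    errors: list[str] = []
    seen_ids: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in METADATA_COLUMNS if c not in header]
        if missing:
            raise MetadataError(f"{path}: missing required columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = ImageRecord(
                    image_id=row["image_id"].strip(),
                    patient_age=float(row["patient_age"]),
                    gender=row["gender"].strip().lower(),
                    laterality=row["laterality"].strip().lower(),
                    projection=row["projection"].strip().lower(),
                    study_type=row["study_type"].strip().lower(),
                    fracture=_parse_bool(row["fracture"]),
                    difficulty=row["difficulty"].strip().lower(),
                    diagnosis_uncertain=_parse_bool(row["diagnosis_uncertain"]),
                    image_width=int(row["image_width"]),
                    image_height=int(row["image_height"]),
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"row {lineno}: {exc}")
                continue
            bad = rec.problems()
            if bad:
                errors.append(f"row {lineno}: " + "; ".join(bad))
                continue
            if rec.image_id in seen_ids:
                errors.append(f"row {lineno}: duplicate image_id {rec.image_id!r}")
                continue
            seen_ids.add(rec.image_id)
            records.append(rec)
    if errors:
        raise MetadataError(f"{path}: invalid rows:\n" + "\n".join(errors))
    return records


def write_metadata(records: Sequence[ImageRecord], path: str | Path) -> None:
    """Write records as a CSV readable by :func:`read_metadata` (lossless round-trip)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.image_id,
                    format(r.patient_age, ".10g"),
                    r.gender,
                    r.laterality,
                    r.projection,
                    r.study_type,
                    "true" if r.fracture else "false",
                    r.difficulty,
                    "true" if r.diagnosis_uncertain else "false",
                    r.image_width,
                    r.image_height,
                ]
            )


# ---------------------------------------------------------------------------
# YOLO-style annotations: "class cx cy w h", all normalized to [0, 1]


def read_annotations(path: str | Path, image_width: int, image_height: int) -> list[BoundingBox]:
    """Parse one image's YOLO-format annotation file into absolute-corner boxes."""
    boxes: list[BoundingBox] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{path}:{lineno}: normalized {name}={v} outside [0, 1]")
            boxes.append(
                BoundingBox(
                    x_min=(cx - w / 2.0) * image_width,
                    y_min=(cy - h / 2.0) * image_height,
                    x_max=(cx + w / 2.0) * image_width,
                    y_max=(cy + h / 2.0) * image_height,
                )
            )
    return boxes


def write_annotations(
    boxes: Iterable[BoundingBox], path: str | Path, image_width: int, image_height: int
) -> None:
    """Write boxes in YOLO normalized-center format (class index 0 = fracture)."""
    with open(path, "w") as fh:
        for b in boxes:
            cx = (b.x_min + b.x_max) / 2.0 / image_width
            cy = (b.y_min + b.y_max) / 2.0 / image_height
            w = b.width / image_width
            h = b.height / image_height
            fh.write(f"0 {cx:.12g} {cy:.12g} {w:.12g} {h:.12g}\n")


# ---------------------------------------------------------------------------
# prediction files


def read_scores(path: str | Path) -> list[ClassScore]:
    """Read classification scores from a CSV with columns image_id, score."""
    out: list[ClassScore] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ClassScore(image_id=row["image_id"], score=float(row["score"])))
    return out


def write_scores(scores: Iterable[ClassScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "score"])
        for s in scores:
            writer.writerow([s.image_id, format(s.score, ".12g")])


def read_detections(path: str | Path) -> list[Detection]:
    """Read detections from a CSV with columns image_id, x_min..y_max, confidence."""
    out: list[Detection] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Detection(
                    image_id=row["image_id"],
                    box=BoundingBox(
                        float(row["x_min"]),
                        float(row["y_min"]),
                        float(row["x_max"]),
                        float(row["y_max"]),
                    ),
                    confidence=float(row["confidence"]),
                )
            )
    return out


def write_detections(dets: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x_min", "y_min", "x_max", "y_max", "confidence"])
        for d in dets:
            writer.writerow(
                [
                    d.image_id,
                    format(d.box.x_min, ".12g"),
                    format(d.box.y_min, ".12g"),
                    format(d.box.x_max, ".12g"),
                    format(d.box.y_max, ".12g"),
                    format(d.confidence, ".12g"),
                ]
            )
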