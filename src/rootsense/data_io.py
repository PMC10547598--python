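"""Readers and writers for every format the pipeline touches.

Raster images (PNG/JPEG/TIFF via Pillow), sensory ground-truth tables
(CSV), bounding-box annotations (normalized centre-format text), and
prediction exports (CSV).  All readers validate and raise typed errors
instead of silently coercing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import (
    AnnotationFormatError,
    EmptyInputError,
    InputError,
    SchemaError,
)
from .geometry import BoundingBox

__all__ = [
    "SensoryRecord",
    "PredictionRecord",
    "AnnotationRecord",
    "read_image",
    "write_image",
    "read_sensory_table",
    "read_annotations",
    "write_annotations",
    "write_predictions_csv",
    "read_predictions_csv",
]


@dataclass(frozen=True)
class SensoryRecord:
    """One variety's panel ground truth."""

    variety_name: str
    flesh_colour_mean: float
    mealiness_by_hand_mean: float
    positive_force_1r: float  # dimensionless instrument units

    def __post_init__(self) -> None:
        for name in ("flesh_colour_mean", "mealiness_by_hand_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise SchemaError(f"{name}={v} outside [0, 10] for {self.variety_name!r}")
        if self.positive_force_1r < 0:
            raise SchemaError(f"negative positive_force_1r for {self.variety_name!r}")


@dataclass(frozen=True)
class PredictionRecord:
    """One image's prediction as exported to CSV."""

    image_name: str
    mean_rgb: tuple[int, int, int]
    predicted_score: float
    image_size: tuple[int, int]  # (height, width)
    attribute: str  # flesh_colour | mealiness | positive_force

    def __post_init__(self) -> None:
        if self.attribute not in {"flesh_colour", "mealiness", "positive_force"}:
            raise SchemaError(f"unknown attribute {self.attribute!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One normalized centre-format annotation line."""

    class_id: int
    centre_x: float
    centre_y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("centre_x", "centre_y", "width", "height"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise AnnotationFormatError(f"{name}={v} outside [0, 1]")
        if self.centre_x - self.width / 2 < -1e-9 or self.centre_x + self.width / 2 > 1 + 1e-9:
            raise AnnotationFormatError("box exceeds [0,1] horizontally")
        if self.centre_y - self.height / 2 < -1e-9 or self.centre_y + self.height / 2 > 1 + 1e-9:
            raise AnnotationFormatError("box exceeds [0,1] vertically")


def read_image(path: str | Path) -> np.ndarray:
    """Load an image as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated to three channels; alpha is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise InputError(f"cannot decode image: {path}") from exc
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Save an (H, W, 3) uint8 RGB or (H, W) uint8 grayscale array."""
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise InputError(f"expected uint8 image, got {image.dtype}")
    mode = "RGB" if image.ndim == 3 else "L"
    Image.fromarray(image, mode=mode).save(Path(path))


# Accepted (normalized) spellings of the sensory-table columns.
_SENSORY_ALIASES = {
    "variety_name": {"variety_name", "variety", "genotype"},
    "flesh_colour_mean": {
        "flesh_colour_mean", "flesh_colour", "flesh_color",
        "flesh_colour_intensity", "flesh_color_intensity",
    },
    "mealiness_by_hand_mean": {
        "mealiness_by_hand_mean", "mealiness_by_hand", "mealiness",
    },
    "positive_force_1r": {"positive_force_1r", "positive_force", "positive_peak_force"},
}


def _normalize_header(name: str) -> str:
    return name.strip().lower().replace("-", "_").replace(" ", "_")


def read_sensory_table(path: str | Path) -> list[SensoryRecord]:
    """Parse a sensory ground-truth CSV into :class:`SensoryRecord` rows.

    Column names are matched case-insensitively against documented aliases
    (e.g. ``"Mealiness by hand" -> mealiness_by_hand_mean``).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"sensory table not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"empty sensory table (no header): {path}")
        colmap: dict[str, str] = {}
        for raw in reader.fieldnames:
            norm = _normalize_header(raw)
            for field_name, aliases in _SENSORY_ALIASES.items():
                if norm in aliases:
                    colmap[field_name] = raw
        missing = set(_SENSORY_ALIASES) - set(colmap)
        if missing:
            raise SchemaError(
                f"sensory table {path} missing columns: {sorted(missing)} "
                f"(found {reader.fieldnames})"
            )
        records: list[SensoryRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    SensoryRecord(
                        variety_name=row[colmap["variety_name"]].strip(),
                        flesh_colour_mean=float(row[colmap["flesh_colour_mean"]]),
                        mealiness_by_hand_mean=float(row[colmap["mealiness_by_hand_mean"]]),
                        positive_force_1r=float(row[colmap["positive_force_1r"]]),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{path}:{lineno}: unparsable row {row!r}") from exc
    return records


def _parse_annotation_line(
    line: str, lineno: int, n_fields: int
) -> tuple[AnnotationRecord, float | None]:
    parts = line.split()
    if len(parts) not in (n_fields, n_fields + 1):
        raise AnnotationFormatError(
            f"line {lineno}: expected {n_fields} or {n_fields + 1} fields, got {len(parts)}"
        )
    try:
        class_id = int(parts[0])
        values = [float(p) for p in parts[1:]]
    except ValueError as exc:
        raise AnnotationFormatError(f"line {lineno}: non-numeric field in {line!r}") from exc
    try:
        rec = AnnotationRecord(class_id, *values[:4])
    except AnnotationFormatError as exc:
        raise AnnotationFormatError(f"line {lineno}: {exc}") from exc
    conf = values[4] if len(values) == 5 else None
    if conf is not None and not 0.0 <= conf <= 1.0:
        raise AnnotationFormatError(f"line {lineno}: confidence {conf} outside [0, 1]")
    return rec, conf


def annotation_to_box(rec: AnnotationRecord, image_size: tuple[int, int]) -> BoundingBox:
    """Normalized centre-format record -> pixel box (0-based, half-open)."""
    h, w = image_size
    x_min = int(round((rec.centre_x - rec.width / 2) * w))
    x_max = int(round((rec.centre_x + rec.width / 2) * w))
    y_min = int(round((rec.centre_y - rec.height / 2) * h))
    y_max = int(round((rec.centre_y + rec.height / 2) * h))
    return BoundingBox(x_min, y_min, x_max, y_max)


def box_to_annotation(
    box: BoundingBox, image_size: tuple[int, int], class_id: int = 0
) -> AnnotationRecord:
    """Pixel box -> normalized centre-format record."""
    h, w = image_size
    return AnnotationRecord(
        class_id=class_id,
        centre_x=(box.x_min + box.x_max) / 2 / w,
        centre_y=(box.y_min + box.y_max) / 2 / h,
        width=box.width / w,
        height=box.height / h,
    )


def read_annotations(
    path: str | Path, image_size: tuple[int, int]
) -> list[BoundingBox]:
    """Read normalized centre-format annotations as pixel boxes."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    boxes: list[BoundingBox] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        rec, _ = _parse_annotation_line(line, lineno, 5)
        boxes.append(annotation_to_box(rec, image_size))
    return boxes


def write_annotations(
    boxes: Sequence[BoundingBox],
    image_size: tuple[int, int],
    path: str | Path,
    confidences: Sequence[float] | None = None,
) -> None:
    """Write pixel boxes as normalized centre-format text (6 decimals).

    When ``confidences`` is given a sixth column is appended per line
    (detection export dialect).
    """
    lines = []
    for i, box in enumerate(boxes):
        rec = box_to_annotation(box, image_size)
        line = (
            f"{rec.class_id} {rec.centre_x:.6f} {rec.centre_y:.6f} "
            f"{rec.width:.6f} {rec.height:.6f}"
        )
        if confidences is not None:
            line += f" {confidences[i]:.6f}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detection_file(
    path: str | Path, image_size: tuple[int, int]
) -> list[tuple[BoundingBox, float]]:
    """Read a detection export (centre format + confidence column)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"detection file not found: {path}")
    out: list[tuple[BoundingBox, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        rec, conf = _parse_annotation_line(line, lineno, 5)
        out.append((annotation_to_box(rec, image_size), 1.0 if conf is None else conf))
    return out


_PREDICTION_HEADER = [
    "image_name", "mean_r", "mean_g", "mean_b",
    "predicted_score", "height", "width", "attribute",
]


def write_predictions_csv(
    records: Iterable[PredictionRecord], path: str | Path
) -> None:
    """Export prediction records; RGB serialized as three integer columns."""
    records = list(records)
    if not records:
        raise EmptyInputError("no prediction records to write")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PREDICTION_HEADER)
        for rec in records:
            r, g, b = rec.mean_rgb
            h, w = rec.image_size
            writer.writerow(
                [rec.image_name, int(r), int(g), int(b),
                 repr(float(rec.predicted_score)), h, w, rec.attribute]
            )


def read_predictions_csv(path: str | Path) -> list[PredictionRecord]:
    """Inverse of :func:`write_predictions_csv` (lossless round trip)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"predictions file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _PREDICTION_HEADER:
            raise SchemaError(f"unexpected predictions header: {reader.fieldnames}")
        return [
            PredictionRecord(
                image_name=row["image_name"],
                mean_rgb=(int(row["mean_r"]), int(row["mean_g"]), int(row["mean_b"])),
                predicted_score=float(row["predicted_score"]),
                image_size=(int(row["height"]), int(row["width"])),
                attribute=row["attribute"],
            )
            for row in reader
        ]
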