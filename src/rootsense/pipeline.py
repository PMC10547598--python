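"""End-to-end stage orchestration shared by the CLI and the test harness.

Each helper runs one pipeline stage (detect -> segment -> features ->
model) on in-memory arrays; the CLI wraps them with file I/O.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .detection import Detection, DetectorParams, detect_roots
from .errors import RootsenseError
from .features_colour import (
    MODEL_FEATURE_NAMES,
    ColourFeatureConfig,
    assemble_colour_features,
)
from .features_texture import TEXTURE_FEATURE_NAMES, EdgeParams, graininess_features
from .geometry import BoundingBox
from .modelling import TrainedModel, predict_scores
from .segmentation import SegmentationParams, segment_image

logger = logging.getLogger(__name__)

ALL_FEATURE_NAMES = MODEL_FEATURE_NAMES + TEXTURE_FEATURE_NAMES

#: Feature subsets per prediction attribute.
ATTRIBUTE_FEATURES = {
    "flesh_colour": MODEL_FEATURE_NAMES,
    "mealiness": ALL_FEATURE_NAMES,
    "positive_force": ALL_FEATURE_NAMES,
}


@dataclass
class StageParams:
    """Parameter blocks of the image-processing stages."""

    detector: DetectorParams = field(default_factory=DetectorParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    colour: ColourFeatureConfig = field(default_factory=ColourFeatureConfig)
    edges: EdgeParams = field(default_factory=EdgeParams)


def image_to_mask(
    image: np.ndarray, params: StageParams | None = None
) -> tuple[np.ndarray, np.ndarray, list[Detection]]:
    """Detect and segment one image -> (masked image, mask, detections).

    Falls back to a full-frame box when the detector finds nothing, so a
    tightly cropped image still segments.
    """
    params = params or StageParams()
    detections = detect_roots(image, params.detector)
    if detections:
        boxes = [d.box for d in detections]
    else:
        h, w = image.shape[:2]
        logger.warning("no detections; falling back to the full frame")
        boxes = [BoundingBox(0, 0, w, h)]
    masked, mask = segment_image(image, boxes, params.segmentation)
    return masked, mask, detections


def image_to_features(
    image: np.ndarray, params: StageParams | None = None
) -> dict[str, float]:
    """Full per-image feature row (9 colour + 4 texture values)."""
    params = params or StageParams()
    _, mask, _ = image_to_mask(image, params)
    colour = assemble_colour_features(image, mask, params.colour)
    texture = graininess_features(image, mask, params.edges)
    values = np.concatenate([colour.as_model_vector(), texture.as_model_vector()])
    return dict(zip(ALL_FEATURE_NAMES, values))


def build_feature_table(
    image_paths: list[str | Path],
    params: StageParams | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature matrix for a list of image files.

    When ``ground_truth`` (columns ``image``, ``colour_score``,
    ``mealiness_score``) is given, target columns are merged in by image
    basename.
    """
    rows = []
    for path in image_paths:
        image = data_io.read_image(path)
        row = {"image": Path(path).name}
        row.update(image_to_features(image, params))
        rows.append(row)
    table = pd.DataFrame(rows)
    if ground_truth is not None:
        table = table.merge(ground_truth, on="image", how="left", validate="1:1")
    return table


def predict_images(
    image_paths: list[str | Path],
    model: TrainedModel,
    attribute: str,
    params: StageParams | None = None,
) -> tuple[list[data_io.PredictionRecord], list[str], dict[str, float]]:
    """Predict one score per image with the fitted model.

    Returns (records, failed image names, timing summary).  An undecodable
    or unprocessable image produces a failure entry and the run continues.
    """
    records: list[data_io.PredictionRecord] = []
    failures: list[str] = []
    clip = None if attribute == "positive_force" else (0.0, 10.0)
    t0 = time.perf_counter()
    for path in image_paths:
        name = Path(path).name
        try:
            image = data_io.read_image(path)
            _, mask, _ = image_to_mask(image, params)
            colour = assemble_colour_features(image, mask)
            texture = graininess_features(image, mask)
            features = dict(
                zip(
                    ALL_FEATURE_NAMES,
                    np.concatenate([colour.as_model_vector(), texture.as_model_vector()]),
                )
            )
            X = np.array([[features[n] for n in model.feature_names]])
            score = float(predict_scores(model, X, clip=clip)[0])
            records.append(
                data_io.PredictionRecord(
                    image_name=name,
                    mean_rgb=tuple(int(round(c)) for c in colour.mean_rgb),
                    predicted_score=score,
                    image_size=image.shape[:2],
                    attribute=attribute,
                )
            )
        except RootsenseError as exc:
            logger.error("prediction failed for %s: %s", name, exc)
            failures.append(name)
    elapsed = time.perf_counter() - t0
    timing = {
        "total_seconds": elapsed,
        "per_image_seconds": elapsed / max(1, len(image_paths)),
        "n_images": len(image_paths),
        "n_failed": len(failures),
    }
    return records, failures, timing
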