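"""Root region detection and detector evaluation.

The detector here is training-free: it builds a background-contrast map
(distance of each pixel from the border-estimated background colour),
thresholds it with Otsu's method, cleans the foreground morphologically and
emits one detection per connected component.  Externally produced
detections can be imported through :func:`rootsense.data_io.read_detection_file`
and scored with the same IoU / mean-average-precision evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import InputError, UndefinedMetricError
from .geometry import BoundingBox, iou

__all__ = [
    "BoundingBox",
    "Detection",
    "DetectorParams",
    "DetectionEvalReport",
    "iou",
    "detect_roots",
    "evaluate_map",
]


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class DetectorParams:
    """Tuning knobs of the classical detector."""

    morph_radius: int = 2
    min_area_fraction: float = 0.003  # drop components smaller than this
    min_contrast: float = 10.0        # intensity levels; below -> "blank" image
    border_width: int = 2             # rows/cols used to estimate background


@dataclass
class DetectionEvalReport:
    map_at_iou: float
    iou_threshold: float
    per_image: list[tuple[int, int, int]]  # (TP, FP, FN) per image


def _background_contrast(image: np.ndarray, border_width: int) -> np.ndarray:
    """Per-pixel RGB distance from the median border colour."""
    b = border_width
    border = np.concatenate(
        [
            image[:b].reshape(-1, 3),
            image[-b:].reshape(-1, 3),
            image[:, :b].reshape(-1, 3),
            image[:, -b:].reshape(-1, 3),
        ]
    )
    bg = np.median(border.astype(float), axis=0)
    return np.linalg.norm(image.astype(float) - bg, axis=-1)


def detect_roots(
    image: np.ndarray, params: DetectorParams | None = None
) -> list[Detection]:
    """Locate root-like regions; confidence is normalized component contrast.

    Returns an empty list on a blank (near-uniform) image.  Raises
    :class:`InputError` when the image is smaller than the morphology kernel.
    """
    params = params or DetectorParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected (H, W, 3) image, got shape {image.shape}")
    h, w = image.shape[:2]
    kernel_size = 2 * params.morph_radius + 1
    if min(h, w) < kernel_size:
        raise InputError(f"image {h}x{w} smaller than morphology kernel {kernel_size}")

    contrast = _background_contrast(image, params.border_width)
    if contrast.max() < params.min_contrast:
        return []

    fg = contrast > threshold_otsu(contrast)
    selem = disk(params.morph_radius).astype(bool)
    fg = ndimage.binary_opening(fg, structure=selem)
    fg = ndimage.binary_closing(fg, structure=selem)
    if not fg.any():
        return []

    labels, n = ndimage.label(fg)
    if n == 0:
        return []
    min_area = params.min_area_fraction * h * w
    comps = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        area = int(comp.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(comp)
        box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        comps.append((box, float(contrast[comp].mean())))
    if not comps:
        return []
    max_contrast = max(c for _, c in comps)
    return [
        Detection(box, min(1.0, c / max_contrast)) for box, c in comps
    ]


def _average_precision(
    tp_flags: np.ndarray, n_truth: int
) -> float:
    """All-point-interpolated AP from confidence-ordered TP/FP flags."""
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    # Precision envelope: at each recall level use the max precision to the right.
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def evaluate_map(
    detections_per_image: list[list[Detection]],
    truths_per_image: list[list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> DetectionEvalReport:
    """Single-class mean average precision at a fixed IoU threshold.

    Detections are pooled across images, sorted by descending confidence
    (ties broken by larger best-IoU, then input order), and matched greedily
    one-to-one to unmatched ground-truth boxes at IoU >= threshold.  AP is
    the area under the precision-recall curve with all-point interpolation.
    """
    if len(detections_per_image) != len(truths_per_image):
        raise InputError("detections and truths must cover the same images")
    n_truth = sum(len(t) for t in truths_per_image)
    if n_truth == 0:
        raise UndefinedMetricError("no ground-truth boxes: recall undefined")

    pooled: list[tuple[float, float, int, int]] = []  # (conf, best_iou, img, det_idx)
    for img_idx, dets in enumerate(detections_per_image):
        truths = truths_per_image[img_idx]
        for det_idx, det in enumerate(dets):
            best = max((iou(det.box, t) for t in truths), default=0.0)
            pooled.append((det.confidence, best, img_idx, det_idx))
    pooled.sort(key=lambda rec: (-rec[0], -rec[1], rec[2], rec[3]))

    matched: list[set[int]] = [set() for _ in truths_per_image]
    tp_flags = np.zeros(len(pooled), dtype=bool)
    tp_per_image = [0] * len(truths_per_image)
    fp_per_image = [0] * len(truths_per_image)
    for i, (_, _, img_idx, det_idx) in enumerate(pooled):
        det = detections_per_image[img_idx][det_idx]
        truths = truths_per_image[img_idx]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if j in matched[img_idx]:
                continue
            v = iou(det.box, t)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[img_idx].add(best_j)
            tp_flags[i] = True
            tp_per_image[img_idx] += 1
        else:
            fp_per_image[img_idx] += 1

    ap = _average_precision(tp_flags, n_truth) if len(pooled) else 0.0
    per_image = [
        (tp_per_image[i], fp_per_image[i], len(truths_per_image[i]) - tp_per_image[i])
        for i in range(len(truths_per_image))
    ]
    return DetectionEvalReport(map_at_iou=ap, iou_threshold=iou_threshold, per_image=per_image)
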