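"""Background elimination inside detected ROIs via 2-cluster K-means.

Within each bounding box the pixels are clustered in RGB space (k=2), the
cluster holding the majority of the box's border pixels is declared
background, and every non-root pixel of the output image is set to black.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, EmptyInputError, InputError, UndefinedMetricError
from .geometry import BoundingBox

__all__ = [
    "SegmentationParams",
    "kmeans_pixels",
    "select_root_cluster",
    "segment_image",
    "dice",
    "iou_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    k: int = 2
    seed: int = 0
    n_init: int = 4
    max_iter: int = 300
    tol: float = 1e-4
    colour_space: str = "rgb"  # or "lab"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InputError(f"k must be >= 2, got {self.k}")
        if self.n_init < 1:
            raise InputError(f"n_init must be >= 1, got {self.n_init}")
        if self.colour_space not in {"rgb", "lab"}:
            raise InputError(f"unknown colour space {self.colour_space!r}")


def kmeans_pixels(
    pixels: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster an (N, 3) pixel array; returns (labels, centroids).

    Lloyd's algorithm with k-means++ initialization and ``n_init`` restarts
    (best inertia kept); deterministic for a fixed seed.  Raises
    :class:`DegenerateInputError` when there are fewer distinct pixels than
    clusters.
    """
    params = params or SegmentationParams()
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise InputError(f"expected (N, 3) pixel array, got {pixels.shape}")
    n_distinct = np.unique(pixels, axis=0).shape[0]
    if n_distinct < params.k:
        raise DegenerateInputError(
            f"{n_distinct} distinct pixels < k={params.k} clusters"
        )
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=params.n_init,
        max_iter=params.max_iter,
        tol=params.tol,
        random_state=params.seed,
        algorithm="lloyd",
    ).fit(pixels)
    return km.labels_.astype(int), km.cluster_centers_


def _saturation(rgb: np.ndarray) -> float:
    mx = float(np.max(rgb))
    if mx <= 0:
        return 0.0
    return (mx - float(np.min(rgb))) / mx


def select_root_cluster(
    labels: np.ndarray, centroids: np.ndarray, roi_shape: tuple[int, int]
) -> int:
    """Pick the root cluster of a 2-cluster ROI labelling.

    The cluster holding the majority of the ROI's 1-pixel border is declared
    background; the other cluster is the root.  An exact border tie is broken
    toward the higher-saturation centroid (the root is assumed more
    saturated than the imaging board).
    """
    if centroids.shape[0] != 2:
        raise InputError("select_root_cluster requires a 2-cluster labelling")
    lab = np.asarray(labels).reshape(roi_shape)
    border = np.concatenate([lab[0], lab[-1], lab[1:-1, 0], lab[1:-1, -1]])
    counts = np.bincount(border, minlength=2)
    if counts[0] == counts[1]:
        return int(np.argmax([_saturation(c) for c in centroids]))
    background = int(np.argmax(counts))
    return 1 - background


def segment_image(
    image: np.ndarray,
    boxes: list[BoundingBox],
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mask the background of every box; returns (masked image, bool mask).

    Per-box root masks are unioned; all pixels outside the union (including
    pixels outside every box) are set to (0, 0, 0).  A box whose pixels are
    degenerate for clustering is skipped with a warning.
    """
    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected (H, W, 3) image, got shape {image.shape}")
    if not boxes:
        raise EmptyInputError("segment_image requires at least one box")
    h, w = image.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    for box in boxes:
        box = box.clip(h, w)
        roi = image[box.y_min : box.y_max, box.x_min : box.x_max]
        pixels = roi.reshape(-1, 3)
        if params.colour_space == "lab":
            from .features_colour import rgb_to_lab_array

            pixels = rgb_to_lab_array(pixels)
        try:
            labels, centroids = kmeans_pixels(pixels, params)
        except DegenerateInputError as exc:
            logger.warning("skipping box %s: %s", box, exc)
            continue
        if params.colour_space == "lab":
            # Saturation tie-break needs RGB centroids.
            centroids = np.stack(
                [roi.reshape(-1, 3)[labels == i].mean(axis=0) for i in range(params.k)]
            )
        root = select_root_cluster(labels, centroids, (box.height, box.width))
        roi_mask = (labels == root).reshape(box.height, box.width)
        mask[box.y_min : box.y_max, box.x_min : box.x_max] |= roi_mask
    masked = image.copy()
    masked[~mask] = 0
    return masked, mask


def _check_masks(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() and not b.any():
        raise UndefinedMetricError("both masks empty: overlap undefined")
    return a, b


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|)."""
    a, b = _check_masks(mask_a, mask_b)
    inter = np.logical_and(a, b).sum()
    return 2.0 * inter / (a.sum() + b.sum())


def iou_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Mask intersection over union |A∩B| / |A∪B|."""
    a, b = _check_masks(mask_a, mask_b)
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union
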