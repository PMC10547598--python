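"""Axis-aligned pixel bounding boxes.

Coordinates are 0-based and half-open: a box covers pixels with
``x_min <= x < x_max`` and ``y_min <= y < y_max``, so its area is
``(x_max - x_min) * (y_max - y_min)`` with no off-by-one ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Half-open pixel box ``[x_min, x_max) x [y_min, y_max)``."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InputError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BoundingBox") -> int:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0
        return iw * ih

    def clip(self, height: int, width: int) -> "BoundingBox":
        """Clip to an image of the given size."""
        return BoundingBox(
            max(0, self.x_min),
            max(0, self.y_min),
            min(width, self.x_max),
            min(height, self.y_max),
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0.0 when disjoint."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union if union else 0.0
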