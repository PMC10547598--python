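"""Colour features of masked root pixels.

Pools every masked pixel of an image (all roots together, since the panel
scores one sample per genotype) and derives: mean RGB, per-channel
histograms, dominant colours via K-means, and mean HSV / CIELAB colours.

Colour-space conversions are implemented from the standard closed forms:
HSV is the hexcone model with hue in degrees [0, 360); CIELAB goes through
the IEC 61966-2-1 sRGB transfer function and the D65 white point (the
imaging cabinet uses 6500 K illumination, so D65 is the faithful choice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DomainError, EmptyInputError, InputError
from .segmentation import SegmentationParams, kmeans_pixels
from .synthgen import ColourScale

__all__ = [
    "ColourFeatureConfig",
    "ColourFeatureVector",
    "rgb_histogram",
    "mean_rgb",
    "dominant_colours",
    "rgb_to_hsv",
    "rgb_to_lab",
    "rgb_to_lab_array",
    "assemble_colour_features",
    "nearest_scale_class",
    "MODEL_FEATURE_NAMES",
]

# Order of the default 9-value model feature block (schema version 1).
MODEL_FEATURE_NAMES = [
    "mean_r", "mean_g", "mean_b",
    "mean_h", "mean_s", "mean_v",
    "mean_l", "mean_a", "mean_b_lab",
]

_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])


@dataclass(frozen=True)
class ColourFeatureConfig:
    histogram_bins: int = 0       # 0 disables the histogram block
    k_dominant: int = 2           # 0 disables dominant-colour clustering
    seed: int = 0


@dataclass
class ColourFeatureVector:
    mean_rgb: tuple[float, float, float]
    mean_hsv: tuple[float, float, float]
    mean_lab: tuple[float, float, float]
    hist_rgb: np.ndarray | None = None           # (3, B) counts
    dominant: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def as_model_vector(self) -> np.ndarray:
        """The fixed-order 9-value block consumed by the models."""
        return np.array([*self.mean_rgb, *self.mean_hsv, *self.mean_lab])


def _pixels_2d(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise InputError(f"expected (N, 3) pixel array, got {pixels.shape}")
    if pixels.shape[0] == 0:
        raise EmptyInputError("no pixels")
    return pixels


def rgb_histogram(pixels: np.ndarray, bins: int = 256) -> np.ndarray:
    """Per-channel histograms with equal-width bins over [0, 255].

    Returns a (3, bins) integer array; each channel's counts sum to N.
    """
    pixels = _pixels_2d(pixels)
    out = np.empty((3, bins), dtype=int)
    for c in range(3):
        out[c], _ = np.histogram(pixels[:, c], bins=bins, range=(0, 256))
    return out


def mean_rgb(pixels: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic per-channel mean."""
    pixels = _pixels_2d(pixels)
    return tuple(pixels.mean(axis=0))


def dominant_colours(
    pixels: np.ndarray, k: int = 2, seed: int = 0
) -> list[tuple[np.ndarray, float]]:
    """K-means dominant colours, sorted by descending cluster share."""
    pixels = _pixels_2d(pixels)
    if k == 1:
        # K-means with a single cluster is just the mean.
        return [(pixels.mean(axis=0), 1.0)]
    labels, centroids = kmeans_pixels(pixels, SegmentationParams(k=k, seed=seed))
    counts = np.bincount(labels, minlength=k)
    props = counts / counts.sum()
    order = np.argsort(-props, kind="stable")
    return [(centroids[i], float(props[i])) for i in order]


def rgb_to_hsv(rgb: tuple[float, float, float]) -> tuple[float, float, float]:
    """Hexcone HSV: H in degrees [0, 360), S and V in [0, 1]; H=0 when S=0."""
    r, g, b = (float(c) / 255.0 for c in rgb)
    for c in rgb:
        if not 0 <= c <= 255:
            raise DomainError(f"RGB component {c} outside [0, 255]")
    mx, mn = max(r, g, b), min(r, g, b)
    v = mx
    delta = mx - mn
    s = 0.0 if mx == 0 else delta / mx
    if delta == 0:
        h = 0.0
    elif mx == r:
        h = 60.0 * (((g - b) / delta) % 6)
    elif mx == g:
        h = 60.0 * ((b - r) / delta + 2)
    else:
        h = 60.0 * ((r - g) / delta + 4)
    return (h % 360.0, s, v)


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def rgb_to_lab_array(pixels: np.ndarray) -> np.ndarray:
    """Vectorized sRGB (0-255) -> CIE L*a*b* under D65/2-degree."""
    pixels = np.asarray(pixels, dtype=float)
    if np.any(pixels < 0) or np.any(pixels > 255):
        raise DomainError("RGB components outside [0, 255]")
    linear = _srgb_to_linear(pixels / 255.0)
    xyz = linear @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _D65_WHITE)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(rgb: tuple[float, float, float]) -> tuple[float, float, float]:
    """Single-colour sRGB -> CIELAB (see :func:`rgb_to_lab_array`)."""
    return tuple(rgb_to_lab_array(np.asarray(rgb, dtype=float)))


def _circular_mean_deg(angles: np.ndarray, weights: np.ndarray) -> float:
    rad = np.deg2rad(angles)
    s = np.average(np.sin(rad), weights=weights)
    c = np.average(np.cos(rad), weights=weights)
    if s == 0 and c == 0:
        return 0.0
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def assemble_colour_features(
    image: np.ndarray,
    mask: np.ndarray,
    config: ColourFeatureConfig | None = None,
) -> ColourFeatureVector:
    """Pool all masked pixels of the image into one colour feature vector.

    Mean HSV uses a saturation-weighted circular mean for hue; mean LAB is
    the arithmetic mean of per-pixel L*a*b*.  Pixel order never matters.
    """
    config = config or ColourFeatureConfig()
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise InputError(f"image {image.shape[:2]} vs mask {mask.shape}")
    if not mask.any():
        raise EmptyInputError("empty mask")
    pixels = image[mask].astype(float)

    mrgb = mean_rgb(pixels)
    hsv = np.array([rgb_to_hsv(tuple(p)) for p in pixels])
    sat_w = hsv[:, 1] + 1e-12
    mhsv = (
        _circular_mean_deg(hsv[:, 0], sat_w),
        float(hsv[:, 1].mean()),
        float(hsv[:, 2].mean()),
    )
    mlab = tuple(rgb_to_lab_array(pixels).mean(axis=0))

    hist = rgb_histogram(pixels, config.histogram_bins) if config.histogram_bins else None
    dom: list[tuple[np.ndarray, float]] = []
    if config.k_dominant:
        try:
            dom = dominant_colours(pixels, config.k_dominant, config.seed)
        except DegenerateInputError:
            # Perfectly uniform region: a single cluster holds everything.
            dom = [(pixels.mean(axis=0), 1.0)]
    return ColourFeatureVector(
        mean_rgb=mrgb, mean_hsv=mhsv, mean_lab=mlab, hist_rgb=hist, dominant=dom
    )


def nearest_scale_class(score: float, scale: ColourScale | None = None) -> int:
    """Nearest anchor code to a real score; exact midpoints round down.

    E.g. 6.5 is equidistant from codes 5 and 8 and returns 5.
    """
    scale = scale or ColourScale()
    if not np.isfinite(score):
        raise DomainError(f"score {score} is not finite")
    best_code, best_dist = None, np.inf
    for code in scale.codes:
        d = abs(score - code)
        if d < best_dist:  # strict: earlier (lower) code wins ties
            best_code, best_dist = code, d
    return int(best_code)
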