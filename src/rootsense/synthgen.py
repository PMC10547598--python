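"""Synthetic boiled-root scene generator with exact ground truth.

Renders root cross-sections as smooth convex blobs whose fill colour encodes
a 0-10 flesh-colour score and whose speckle texture encodes a 0-10 mealiness
score, over a uniform dark background.  Every render returns the pixel-exact
mask, per-root bounding boxes and the generating scores, so detection,
segmentation, feature extraction and modelling can all be validated without
any external image data.

Colour anchors
--------------
The six-point flesh-colour scale has named anchors at codes
``0=white, 1=cream, 3=yellow, 5=yellow-orange, 8=orange, 10=deep orange``.
The anchor RGB triples are a documented default palette (only their relative
ordering matters for the pipeline); scores between anchors interpolate
linearly per channel.

Mealiness encoding
------------------
``mealiness_to_grain`` maps mealiness ``m`` affinely to a speckle density of
``m / 10 * MAX_SPECKLE_DENSITY`` dots per pixel^2 and a speckle contrast of
``m / 10 * MAX_SPECKLE_CONTRAST`` intensity levels, so mealiness 0 renders a
perfectly smooth root and every grain statistic is monotone in ``m``.  This
is a test-harness encoding, not a biological claim.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, InputError, PlacementError
from .geometry import BoundingBox

__all__ = [
    "DEFAULT_ANCHORS",
    "DEFAULT_CLASS_NAMES",
    "ColourScale",
    "SyntheticSpec",
    "GroundTruth",
    "GrainParams",
    "colour_score_to_rgb",
    "mealiness_to_grain",
    "render_scene",
    "generate_dataset",
    "MAX_SPECKLE_DENSITY",
    "MAX_SPECKLE_CONTRAST",
]

DEFAULT_ANCHORS: dict[int, tuple[int, int, int]] = {
    0: (235, 231, 222),   # white
    1: (238, 222, 180),   # cream
    3: (240, 205, 90),    # yellow
    5: (238, 170, 60),    # yellow-orange
    8: (230, 125, 35),    # orange
    10: (200, 85, 20),    # deep orange
}

DEFAULT_CLASS_NAMES: dict[int, str] = {
    0: "white",
    1: "cream",
    3: "yellow",
    5: "yellow-orange",
    8: "orange",
    10: "deep orange",
}

#: Speckle dots per pixel^2 at mealiness 10.
MAX_SPECKLE_DENSITY = 0.05
#: Speckle amplitude in intensity levels at mealiness 10.
MAX_SPECKLE_CONTRAST = 80.0

#: Maximum relative radial boundary perturbation of a rendered blob; the
#: blob pixel count then matches the analytic ellipse area pi*a*b to within
#: ~5% (tested).
BOUNDARY_PERTURBATION = 0.05


@dataclass(frozen=True)
class ColourScale:
    """Six-anchor ordinal flesh-colour scale (codes 0,1,3,5,8,10)."""

    anchors: Mapping[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_ANCHORS)
    )
    class_names: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_NAMES)
    )

    def __post_init__(self) -> None:
        codes = list(self.anchors)
        if len(codes) != 6:
            raise DomainError(f"scale needs exactly six anchors, got {len(codes)}")
        if codes != sorted(codes):
            raise DomainError("anchor codes must be strictly increasing")
        for code, rgb in self.anchors.items():
            if len(rgb) != 3 or any(not (0 <= c <= 255) for c in rgb):
                raise DomainError(f"anchor {code} RGB {rgb} outside [0,255]")

    @property
    def codes(self) -> list[int]:
        return list(self.anchors)

    def code_for_name(self, name: str) -> int:
        """Class code for an anchor name, e.g. ``'orange' -> 8``."""
        for code, cname in self.class_names.items():
            if cname == name:
                return code
        raise DomainError(f"unknown class name {name!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scene."""

    image_size: tuple[int, int] = (96, 128)  # (height, width)
    n_roots: int = 1
    colour_score: float = 5.0
    mealiness_score: float = 0.0
    background_rgb: tuple[int, int, int] = (12, 12, 12)
    pixel_noise_sd: float = 0.0
    include_label_patch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise DomainError(f"n_roots must be >= 1, got {self.n_roots}")
        for name in ("colour_score", "mealiness_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise DomainError(f"{name}={v} outside [0, 10]")
        if self.pixel_noise_sd < 0:
            raise DomainError("pixel_noise_sd must be >= 0")


@dataclass(frozen=True)
class GrainParams:
    """Speckle texture parameters derived from a mealiness score."""

    density: float   # dots per pixel^2
    contrast: float  # intensity levels


@dataclass
class GroundTruth:
    """Exact per-scene labels produced alongside a render."""

    boxes: list[BoundingBox]
    mask: np.ndarray  # bool, H x W
    colour_score: float
    mealiness_score: float


def colour_score_to_rgb(
    score: float, scale: ColourScale | None = None
) -> tuple[int, int, int]:
    """Map a 0-10 flesh-colour score to an RGB triple.

    Anchor codes return the anchor colour exactly; other scores interpolate
    linearly per channel between the two bracketing anchors (rounded to the
    nearest integer level).
    """
    scale = scale or ColourScale()
    if not 0.0 <= score <= 10.0:
        raise DomainError(f"colour score {score} outside [0, 10]")
    codes = scale.codes
    if score in scale.anchors:
        return tuple(scale.anchors[int(score)])
    hi_idx = next(i for i, c in enumerate(codes) if c > score)
    lo, hi = codes[hi_idx - 1], codes[hi_idx]
    t = (score - lo) / (hi - lo)
    lo_rgb = np.asarray(scale.anchors[lo], dtype=float)
    hi_rgb = np.asarray(scale.anchors[hi], dtype=float)
    mixed = lo_rgb + t * (hi_rgb - lo_rgb)
    return tuple(int(round(c)) for c in mixed)


def mealiness_to_grain(mealiness: float) -> GrainParams:
    """Affine mealiness -> (speckle density, speckle contrast) encoding."""
    if not 0.0 <= mealiness <= 10.0:
        raise DomainError(f"mealiness {mealiness} outside [0, 10]")
    frac = mealiness / 10.0
    return GrainParams(
        density=frac * MAX_SPECKLE_DENSITY,
        contrast=frac * MAX_SPECKLE_CONTRAST,
    )


def _blob_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    axes: tuple[float, float],
    harmonics: Sequence[tuple[int, float, float]],
) -> np.ndarray:
    """Rasterize one ellipse with low-frequency radial perturbation.

    ``harmonics`` is a list of (order k, amplitude, phase); a pixel is inside
    when its normalized elliptical radius is <= 1 + sum_k amp*cos(k*theta+phase).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - centre[0]) / axes[0]
    dx = (xx - centre[1]) / axes[1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    boundary = np.ones_like(r)
    for k, amp, phase in harmonics:
        boundary += amp * np.cos(k * theta + phase)
    return r <= boundary


def render_scene(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a fixed ``spec.seed``.

    Returns an ``(H, W, 3)`` uint8 image and the exact :class:`GroundTruth`.
    Raises :class:`PlacementError` if ``n_roots`` non-overlapping roots do
    not fit after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(spec.background_rgb, dtype=float)

    root_rgb = np.asarray(colour_score_to_rgb(spec.colour_score), dtype=float)
    grain = mealiness_to_grain(spec.mealiness_score)

    # Root size scales down with root count so n_roots scenes remain feasible.
    base = max(min(h, w) / (2.4 * spec.n_roots**0.7), 3.0)
    margin = 2

    boxes: list[BoundingBox] = []
    masks: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * spec.n_roots
    while len(boxes) < spec.n_roots:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_roots} non-overlapping roots "
                f"in a {h}x{w} image after {max_attempts} attempts"
            )
        attempts += 1
        # Roots shrink as retries accumulate so crowded scenes still resolve.
        shrink = 1.0 - 0.5 * attempts / max_attempts
        ay = rng.uniform(0.6, 1.0) * base * shrink
        ax = rng.uniform(0.6, 1.0) * base * shrink
        reach_y = ay * (1 + BOUNDARY_PERTURBATION * 3)
        reach_x = ax * (1 + BOUNDARY_PERTURBATION * 3)
        if 2 * reach_y + 2 * margin >= h or 2 * reach_x + 2 * margin >= w:
            continue
        cy = rng.uniform(reach_y + margin, h - reach_y - margin)
        cx = rng.uniform(reach_x + margin, w - reach_x - margin)
        harmonics = [
            (k, rng.uniform(0.0, BOUNDARY_PERTURBATION), rng.uniform(0, 2 * np.pi))
            for k in (2, 3, 4)
        ]
        mask = _blob_mask((h, w), (cy, cx), (ay, ax), harmonics)
        if not mask.any():
            continue
        ys, xs = np.nonzero(mask)
        box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        # Keep a clear gap between roots, as on a real imaging board; this
        # also guarantees pairwise-disjoint ground-truth boxes.
        gap = 6
        padded_box = BoundingBox(
            box.x_min - gap, box.y_min - gap, box.x_max + gap, box.y_max + gap
        )
        if any(padded_box.intersection_area(b) > 0 for b in boxes):
            continue
        boxes.append(box)
        masks.append(mask)

    full_mask = np.zeros((h, w), dtype=bool)
    for mask in masks:
        full_mask |= mask
        img[mask] = root_rgb
        # Speckle grain: balanced +/- dots so the mean stays near the anchor.
        area = int(mask.sum())
        n_dots = int(round(grain.density * area))
        if n_dots > 0 and grain.contrast > 0:
            ys, xs = np.nonzero(mask)
            idx = rng.choice(len(ys), size=n_dots, replace=False if n_dots <= len(ys) else True)
            signs = rng.choice([-1.0, 1.0], size=n_dots)
            img[ys[idx], xs[idx]] += signs[:, None] * grain.contrast

    if spec.include_label_patch:
        # Bright distractor rectangle placed outside every root box.
        for _ in range(50):
            ph, pw = max(4, h // 12), max(6, w // 10)
            py = int(rng.integers(0, h - ph))
            px = int(rng.integers(0, w - pw))
            patch = BoundingBox(px, py, px + pw, py + ph)
            if all(patch.intersection_area(b) == 0 for b in boxes):
                img[py : py + ph, px : px + pw] = (250, 250, 250)
                break

    if spec.pixel_noise_sd > 0:
        img += rng.normal(0.0, spec.pixel_noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        boxes=boxes,
        mask=full_mask,
        colour_score=spec.colour_score,
        mealiness_score=spec.mealiness_score,
    )
    return img, truth


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_dataset(
    n_images: int,
    out_dir: str | Path,
    seed: int = 0,
    score_distribution: Mapping[str, tuple[float, float]] | None = None,
    image_size: tuple[int, int] = (96, 128),
    n_roots: int = 1,
    pixel_noise_sd: float = 0.0,
) -> list[dict]:
    """Write a reproducible synthetic dataset and return its manifest.

    Per image: a PNG under ``images/``, a normalized centre-format
    annotation under ``annotations/``, and one ground-truth row in
    ``ground_truth.csv``.  ``manifest.csv`` lists every path plus a SHA-256
    checksum of the PNG.  ``score_distribution`` maps ``colour_score`` /
    ``mealiness_score`` to uniform (low, high) ranges; default (0, 10).
    """
    from . import data_io  # local import: data_io depends on geometry only

    if n_images < 1:
        raise InputError(f"n_images must be >= 1, got {n_images}")
    dist = {"colour_score": (0.0, 10.0), "mealiness_score": (0.0, 10.0)}
    if score_distribution:
        dist.update(score_distribution)

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    manifest: list[dict] = []
    for i in range(n_images):
        colour = float(rng.uniform(*dist["colour_score"]))
        mealiness = float(rng.uniform(*dist["mealiness_score"]))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        spec = SyntheticSpec(
            image_size=image_size,
            n_roots=n_roots,
            colour_score=colour,
            mealiness_score=mealiness,
            pixel_noise_sd=pixel_noise_sd,
            seed=scene_seed,
        )
        image, truth = render_scene(spec)
        name = f"syn_{i:04d}"
        img_path = out_dir / "images" / f"{name}.png"
        ann_path = out_dir / "annotations" / f"{name}.txt"
        data_io.write_image(image, img_path)
        data_io.write_annotations(truth.boxes, image_size, ann_path)
        manifest.append(
            {
                "image": str(img_path),
                "annotation": str(ann_path),
                "variety": f"SYN-{i:04d}",
                "colour_score": colour,
                "mealiness_score": mealiness,
                "seed": scene_seed,
                "sha256": _file_sha256(img_path),
            }
        )

    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image", "variety", "colour_score", "mealiness_score"])
        for row in manifest:
            writer.writerow(
                [Path(row["image"]).name, row["variety"],
                 f"{row['colour_score']:.6f}", f"{row['mealiness_score']:.6f}"]
            )
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
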