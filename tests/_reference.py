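"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (loops, exhaustive enumeration) and
shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# K-means: exhaustive-restart Lloyd's algorithm
# ---------------------------------------------------------------------------

def lloyd_to_convergence(points: np.ndarray, centroids: np.ndarray, max_iter: int = 500):
    centroids = centroids.astype(float).copy()
    for _ in range(max_iter):
        d = np.linalg.norm(points[:, None, :] - centroids[None, :, :], axis=2)
        labels = d.argmin(axis=1)
        new = centroids.copy()
        for k in range(len(centroids)):
            if np.any(labels == k):
                new[k] = points[labels == k].mean(axis=0)
        if np.allclose(new, centroids):
            break
        centroids = new
    d = np.linalg.norm(points[:, None, :] - centroids[None, :, :], axis=2)
    labels = d.argmin(axis=1)
    inertia = float(np.sum((points - centroids[labels]) ** 2))
    return labels, centroids, inertia


def brute_force_kmeans2(points: np.ndarray):
    """Best 2-means over Lloyd runs seeded from every distinct point pair."""
    points = np.asarray(points, dtype=float)
    distinct = np.unique(points, axis=0)
    best = (None, None, np.inf)
    for i in range(len(distinct)):
        for j in range(i + 1, len(distinct)):
            init = np.stack([distinct[i], distinct[j]])
            labels, cents, inertia = lloyd_to_convergence(points, init)
            if inertia < best[2]:
                best = (labels, cents, inertia)
    return best


# ---------------------------------------------------------------------------
# Average precision by direct PR-curve enumeration
# ---------------------------------------------------------------------------

def brute_force_ap(ordered_is_tp: list[bool], n_truth: int) -> float:
    """AP = sum over TP ranks of (recall step) * interpolated precision."""
    precisions, recalls = [], []
    tp = fp = 0
    for flag in ordered_is_tp:
        tp, fp = tp + flag, fp + (not flag)
        precisions.append(tp / (tp + fp))
        recalls.append(tp / n_truth)
    ap = 0.0
    prev_r = 0.0
    for i, r in enumerate(recalls):
        p_interp = max(precisions[i:])  # max precision at recall >= r
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


# ---------------------------------------------------------------------------
# Naive Canny: explicit loops following the documented recipe
# ---------------------------------------------------------------------------

def naive_canny(gray, sigma, low, high, mask):
    gray = np.asarray(gray, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    h, w = gray.shape
    if not mask.all():
        fill = gray[mask].mean()
        gray = gray.copy()
        gray[~mask] = fill
    smoothed = ndimage.gaussian_filter(gray, sigma, mode="nearest") if sigma > 0 else gray

    padded = np.pad(smoothed, 1, mode="edge")
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            gx[i, j] = (padded[i + 1, j + 2] - padded[i + 1, j]) / 2.0
            gy[i, j] = (padded[i + 2, j + 1] - padded[i, j + 1]) / 2.0
    mag = np.hypot(gx, gy)

    interior = naive_erode(mask, 2)
    mag[~interior] = 0.0

    nms = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if mag[i, j] <= 0:
                continue
            ang = np.rad2deg(np.arctan2(gy[i, j], gx[i, j])) % 180.0
            if ang < 22.5 or ang >= 157.5:
                dy, dx = 0, 1
            elif ang < 67.5:
                dy, dx = 1, 1
            elif ang < 112.5:
                dy, dx = 1, 0
            else:
                dy, dx = 1, -1
            m1 = mag[i + dy, j + dx] if 0 <= i + dy < h and 0 <= j + dx < w else 0.0
            m2 = mag[i - dy, j - dx] if 0 <= i - dy < h and 0 <= j - dx < w else 0.0
            nms[i, j] = mag[i, j] >= m1 and mag[i, j] >= m2

    strong = nms & (mag >= high)
    weak = nms & (mag >= low)
    # BFS hysteresis: weak pixels 8-connected to strong survive.
    edges = strong.copy()
    stack = list(zip(*np.nonzero(strong)))
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and weak[ni, nj] and not edges[ni, nj]:
                    edges[ni, nj] = True
                    stack.append((ni, nj))
    return edges


def naive_erode(mask, iterations):
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for _ in range(iterations):
        out = np.zeros_like(mask)
        for i in range(h):
            for j in range(w):
                ok = mask[i, j]
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                            ok = False
                mask_val = ok
                out[i, j] = mask_val
        mask = out
    return mask


# ---------------------------------------------------------------------------
# Inverse colour transforms (test-only, for round-trip checks)
# ---------------------------------------------------------------------------

def hsv_to_rgb(h, s, v):
    c = v * s
    x = c * (1 - abs((h / 60.0) % 2 - 1))
    m = v - c
    if h < 60:
        r, g, b = c, x, 0
    elif h < 120:
        r, g, b = x, c, 0
    elif h < 180:
        r, g, b = 0, c, x
    elif h < 240:
        r, g, b = 0, x, c
    elif h < 300:
        r, g, b = x, 0, c
    else:
        r, g, b = c, 0, x
    return tuple(255.0 * (u + m) for u in (r, g, b))


_XYZ_TO_SRGB = np.linalg.inv(
    np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
)
_D65 = np.array([0.95047, 1.0, 1.08883])


def lab_to_rgb(L, a, b):
    delta = 6.0 / 29.0
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0

    def finv(t):
        return t**3 if t > delta else 3 * delta**2 * (t - 4.0 / 29.0)

    xyz = np.array([finv(fx), finv(fy), finv(fz)]) * _D65
    linear = _XYZ_TO_SRGB @ xyz
    srgb = np.where(
        linear <= 0.0031308, 12.92 * linear, 1.055 * np.clip(linear, 0, None) ** (1 / 2.4) - 0.055
    )
    return tuple(255.0 * np.clip(srgb, 0, 1))


# ---------------------------------------------------------------------------
# Definitional metric oracles
# ---------------------------------------------------------------------------

def oracle_regression_metrics(y, yhat):
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    errs = [yh - yi for yi, yh in zip(y, yhat)]
    mae = sum(abs(e) for e in errs) / len(errs)
    mse = sum(e * e for e in errs) / len(errs)
    ybar = sum(y) / len(y)
    r2 = 1.0 - sum(e * e for e in errs) / sum((yi - ybar) ** 2 for yi in y)
    return mae, mse, r2


def oracle_classification_metrics(y, yhat, classes):
    y = list(y)
    yhat = list(yhat)
    table = {}
    for cls in classes:
        if cls not in y and cls not in yhat:
            continue
        tp = sum(1 for a, b in zip(y, yhat) if a == cls and b == cls)
        fp = sum(1 for a, b in zip(y, yhat) if a != cls and b == cls)
        fn = sum(1 for a, b in zip(y, yhat) if a == cls and b != cls)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        table[cls] = (p, r, f1)
    n = len(table)
    macro = tuple(sum(v[i] for v in table.values()) / n for i in range(3))
    return macro, table
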