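"""Fiducial marker detection and trackable-feature selection.

The first frame of a run is segmented for high-contrast markers by
intensity thresholding (Otsu by default) followed by connected-component
labelling and area/contrast filters; each surviving component is reported
with an intensity-weighted sub-pixel centroid.  On every marker, corner
points suitable for optical-flow tracking are then picked by the
Shi-Tomasi criterion: the minimum eigenvalue of the local structure
tensor (the windowed sum of gradient outer products), with non-maximum
suppression to keep points apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .grids import ImageGrid, central_gradients

__all__ = [
    "MarkerCandidate",
    "FeaturePoint",
    "DetectionConfig",
    "FeatureConfig",
    "FeatureSelection",
    "detect_markers",
    "structure_tensor",
    "shi_tomasi_score",
    "shi_tomasi_response",
    "select_features",
]


@dataclass(frozen=True)
class MarkerCandidate:
    """A detected fiducial marker.

    ``centroid_px`` is the intensity-weighted sub-pixel centre (x, y);
    ``bbox`` is (x_min, y_min, x_max, y_max) inclusive pixel bounds;
    ``contrast`` is mean foreground minus local background intensity.
    """

    marker_id: int
    centroid_px: tuple[float, float]
    area_px: int
    bbox: tuple[int, int, int, int]
    contrast: float


@dataclass(frozen=True)
class FeaturePoint:
    """A trackable corner point belonging to a marker."""

    position_px: tuple[float, float]
    shi_tomasi_score: float
    marker_id: int


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for the shape detector.

    ``threshold`` is either the string ``'otsu'`` or a fixed intensity in
    [0, 1].  Markers are assumed brighter than the background unless
    ``bright_markers`` is False.
    """

    threshold: float | str = "otsu"
    min_area_px: int = 25
    max_area_px: int = 1_000_000
    min_contrast: float = 0.1
    bright_markers: bool = True


@dataclass(frozen=True)
class FeatureConfig:
    """Shi-Tomasi feature selection settings.

    ``quality_level`` is the fraction of the best score within a marker
    below which candidates are rejected (the same convention as common
    good-features-to-track implementations); ``window_halfwidth`` 3 gives
    a 7x7 structure-tensor window.  ``refine_subpixel`` moves each
    selected point from the integer score peak to the sub-pixel corner
    where the local gradients are orthogonal to the offset (the score
    peak of a step corner sits a couple of pixels inside the true edge
    intersection).
    """

    max_per_marker: int = 4
    window_halfwidth: int = 3
    quality_level: float = 0.2
    min_separation_px: float = 7.0
    bbox_dilation_px: int = 7
    refine_subpixel: bool = True
    refine_halfwidth: int = 4


class FeatureSelection(NamedTuple):
    points: list[FeaturePoint]
    markers_without_features: list[int]


def detect_markers(
    frame: ImageGrid, config: DetectionConfig = DetectionConfig()
) -> list[MarkerCandidate]:
    """Find high-contrast marker candidates in a frame.

    Returns candidates ordered by (centroid y, then x).  An empty list is
    a valid result for a frame with no markers.
    """
    img = frame.pixels
    if config.threshold == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = float(threshold_otsu(img))
    else:
        thr = float(config.threshold)
    fg = img > thr if config.bright_markers else img < thr
    if not np.any(fg):
        return []
    labels, n = ndimage.label(fg)
    candidates: list[MarkerCandidate] = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        area = int(mask.sum())
        if area < config.min_area_px or area > config.max_area_px:
            continue
        y0, x0 = sl[0].start, sl[1].start
        y1, x1 = sl[0].stop - 1, sl[1].stop - 1
        # local background from a 2 px dilated bounding box around the component
        by0, bx0 = max(y0 - 2, 0), max(x0 - 2, 0)
        by1 = min(y1 + 2, img.shape[0] - 1)
        bx1 = min(x1 + 2, img.shape[1] - 1)
        patch = img[by0 : by1 + 1, bx0 : bx1 + 1]
        patch_mask = labels[by0 : by1 + 1, bx0 : bx1 + 1] == lab
        bg_pixels = patch[~patch_mask]
        background = float(bg_pixels.mean()) if bg_pixels.size else 0.0
        foreground = float(patch[patch_mask].mean())
        contrast = (foreground - background) if config.bright_markers else (
            background - foreground
        )
        if contrast < config.min_contrast:
            continue
        # sub-pixel centroid: intensity-weighted mean over the dilated
        # patch with background subtracted, so anti-aliased rims count
        weights = (patch - background) if config.bright_markers else (background - patch)
        weights = np.clip(weights, 0.0, None)
        ys, xs = np.mgrid[by0 : by1 + 1, bx0 : bx1 + 1]
        wsum = weights.sum()
        cx = float((weights * xs).sum() / wsum)
        cy = float((weights * ys).sum() / wsum)
        candidates.append(
            MarkerCandidate(
                marker_id=-1,
                centroid_px=(cx, cy),
                area_px=area,
                bbox=(x0, y0, x1, y1),
                contrast=contrast,
            )
        )
    candidates.sort(key=lambda c: (c.centroid_px[1], c.centroid_px[0]))
    return [
        MarkerCandidate(i, c.centroid_px, c.area_px, c.bbox, c.contrast)
        for i, c in enumerate(candidates)
    ]


def structure_tensor(
    frame: ImageGrid, p: tuple[int, int], window_halfwidth: int = 3
) -> np.ndarray:
    """Windowed gradient outer-product sum G at integer pixel p = (x, y).

    G = sum over the (2w+1)^2 window of [[Ix^2, Ix Iy], [Ix Iy, Iy^2]]
    with central-difference gradients (border replication).  Symmetric
    positive semi-definite by construction.
    """
    x, y = int(p[0]), int(p[1])
    w = window_halfwidth
    h, wd = frame.shape
    if x - w < 0 or y - w < 0 or x + w >= wd or y + w >= h:
        raise ValueError("structure tensor window extends outside the frame")
    gx, gy = central_gradients(frame.pixels)
    sl = (slice(y - w, y + w + 1), slice(x - w, x + w + 1))
    ix, iy = gx[sl], gy[sl]
    return np.array(
        [
            [float((ix * ix).sum()), float((ix * iy).sum())],
            [float((ix * iy).sum()), float((iy * iy).sum())],
        ]
    )


def shi_tomasi_score(G: np.ndarray) -> float:
    """Minimum eigenvalue of a symmetric 2x2 matrix, in closed form.

    lambda_min = trace/2 - sqrt((trace/2)^2 - det); non-negative for a
    positive semi-definite structure tensor up to rounding.
    """
    G = np.asarray(G, dtype=np.float64)
    half_trace = (G[0, 0] + G[1, 1]) / 2.0
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    disc = max(half_trace * half_trace - det, 0.0)
    return float(half_trace - np.sqrt(disc))


def shi_tomasi_response(frame: ImageGrid, window_halfwidth: int = 3) -> np.ndarray:
    """Per-pixel minimum-eigenvalue corner score map.

    Vectorized equivalent of evaluating :func:`structure_tensor` +
    :func:`shi_tomasi_score` at every pixel where the window fits
    (the border of width ``window_halfwidth`` is set to 0).
    """
    w = window_halfwidth
    gx, gy = central_gradients(frame.pixels)
    size = 2 * w + 1
    n = size * size
    sxx = ndimage.uniform_filter(gx * gx, size=size, mode="constant") * n
    sxy = ndimage.uniform_filter(gx * gy, size=size, mode="constant") * n
    syy = ndimage.uniform_filter(gy * gy, size=size, mode="constant") * n
    half_trace = (sxx + syy) / 2.0
    det = sxx * syy - sxy * sxy
    disc = np.clip(half_trace * half_trace - det, 0.0, None)
    score = half_trace - np.sqrt(disc)
    score[:w, :] = 0.0
    score[-w:, :] = 0.0
    score[:, :w] = 0.0
    score[:, -w:] = 0.0
    return score


def refine_corner_subpixel(
    frame: ImageGrid,
    p: tuple[float, float],
    halfwidth: int = 4,
    max_iter: int = 20,
    eps_px: float = 1e-3,
) -> tuple[float, float]:
    """Refine a corner estimate to sub-pixel accuracy.

    Solves the orthogonality condition ``sum_i (grad I_i) (grad I_i)^T
    (x_i - q) = 0`` over a window around the current estimate: at the
    true corner every gradient vector in the window is perpendicular to
    the offset from the corner to its pixel.  Iterates until the update
    falls below ``eps_px``; falls back to the input position if the
    window leaves the frame.
    """
    from .grids import bilinear_sample

    gx_map, gy_map = central_gradients(frame.pixels)
    h, w = frame.shape
    r = np.arange(-halfwidth, halfwidth + 1, dtype=np.float64)
    ox, oy = np.meshgrid(r, r)
    ox, oy = ox.ravel(), oy.ravel()
    q = np.array(p, dtype=np.float64)
    for _ in range(max_iter):
        xs, ys = q[0] + ox, q[1] + oy
        if xs.min() < 1 or ys.min() < 1 or xs.max() > w - 2 or ys.max() > h - 2:
            break
        gx = bilinear_sample(gx_map, xs, ys)
        gy = bilinear_sample(gy_map, xs, ys)
        a = float((gx * gx).sum())
        b = float((gx * gy).sum())
        c = float((gy * gy).sum())
        det = a * c - b * b
        if det <= 1e-12:
            break
        bx = float((gx * gx * xs + gx * gy * ys).sum())
        by = float((gx * gy * xs + gy * gy * ys).sum())
        new_q = np.array([c * bx - b * by, a * by - b * bx]) / det
        step = float(np.hypot(*(new_q - q)))
        q = new_q
        if step < eps_px:
            break
    return float(q[0]), float(q[1])


def select_features(
    frame: ImageGrid,
    markers: list[MarkerCandidate],
    config: FeatureConfig = FeatureConfig(),
) -> FeatureSelection:
    """Pick up to k best Shi-Tomasi corners on each marker.

    Candidates within a marker's dilated bounding box are ranked by
    score; non-maximum suppression enforces ``min_separation_px`` with
    ties broken towards lower (y, x).  Markers yielding no point above
    the quality threshold are reported in ``markers_without_features``
    (and a warning is emitted), never silently dropped.
    """
    score = shi_tomasi_response(frame, config.window_halfwidth)
    h, w = frame.shape
    points: list[FeaturePoint] = []
    flagged: list[int] = []
    d = config.bbox_dilation_px
    for marker in markers:
        x0, y0, x1, y1 = marker.bbox
        x0, y0 = max(x0 - d, 0), max(y0 - d, 0)
        x1, y1 = min(x1 + d, w - 1), min(y1 + d, h - 1)
        patch = score[y0 : y1 + 1, x0 : x1 + 1]
        best = patch.max()
        if best <= 0:
            flagged.append(marker.marker_id)
            continue
        thr = config.quality_level * best
        ys, xs = np.nonzero(patch > thr)
        vals = patch[ys, xs]
        # sort by descending score, ties towards lower (y, x)
        order = np.lexsort((xs, ys, -vals))
        accepted: list[tuple[float, float, float]] = []
        min_sep2 = config.min_separation_px**2
        for idx in order:
            px, py = float(xs[idx] + x0), float(ys[idx] + y0)
            if any((px - ax) ** 2 + (py - ay) ** 2 < min_sep2 for ax, ay, _ in accepted):
                continue
            accepted.append((px, py, float(vals[idx])))
            if len(accepted) >= config.max_per_marker:
                break
        if not accepted:
            flagged.append(marker.marker_id)
            continue
        for px, py, s in accepted:
            if config.refine_subpixel:
                px, py = refine_corner_subpixel(frame, (px, py), config.refine_halfwidth)
            points.append(FeaturePoint((px, py), s, marker.marker_id))
    if flagged:
        warnings.warn(
            f"markers without usable feature points: {flagged}", stacklevel=2
        )
    return FeatureSelection(points, flagged)
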