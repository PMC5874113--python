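"""Camera calibration: pixel-to-millimetre conversion and lens distortion.

The marker plane is treated as fronto-parallel at treatment distance, so
a single scalar pixel scale (px/mm) converts image displacements to
millimetres; the residual perspective error at 2-4 m is far below the
millimetre accuracy goal.  Radial lens distortion follows the standard
two-coefficient model ``x_d = x_u (1 + k1 r^2 + k2 r^4)`` around the
principal point, inverted by fixed-point iteration.  An axis map assigns
each image axis to a signed anatomical axis: for a lateral camera, image
x maps to superior-inferior (SI) and image y — which increases downward
— maps to anteroposterior (AP) with a negative sign so that upward
(anterior) motion is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CameraModel",
    "undistort",
    "distort",
    "px_to_mm",
    "mm_to_px",
    "calibrate_scale",
]

ANATOMICAL_AXES = ("AP", "SI", "LR")

# lateral camera: x -> SI (positive toward image right), y -> AP with the
# sign flipped because image y grows downward
LATERAL_AXIS_MAP = {"x": ("SI", 1.0), "y": ("AP", -1.0)}
CEILING_AXIS_MAP = {"x": ("LR", 1.0), "y": ("SI", -1.0)}


@dataclass(frozen=True)
class CameraModel:
    """Scalar-scale camera model at the marker plane.

    ``pixel_scale_px_per_mm`` is the image-plane resolution; ``k1`` and
    ``k2`` are radial distortion coefficients in per-px^2 and per-px^4
    units relative to ``principal_point_px``; ``axis_map`` maps each
    image axis to a (anatomical axis, sign) pair.
    """

    pixel_scale_px_per_mm: float
    k1: float = 0.0
    k2: float = 0.0
    principal_point_px: tuple[float, float] = (0.0, 0.0)
    axis_map: dict = field(default_factory=lambda: dict(LATERAL_AXIS_MAP))
    camera_id: str = "lateral"

    def __post_init__(self) -> None:
        if self.pixel_scale_px_per_mm <= 0:
            raise ValueError("pixel_scale_px_per_mm must be positive")
        targets = [ax for ax, _sign in self.axis_map.values()]
        if set(self.axis_map) != {"x", "y"} or len(set(targets)) != 2 or not set(
            targets
        ) <= set(ANATOMICAL_AXES):
            raise ValueError(
                "axis_map must map image x and y onto two distinct anatomical axes"
            )


def distort(p: np.ndarray | tuple, model: CameraModel) -> np.ndarray:
    """Forward radial distortion of undistorted pixel positions."""
    p = np.asarray(p, dtype=np.float64)
    pp = np.asarray(model.principal_point_px)
    rel = p - pp
    r2 = np.sum(rel * rel, axis=-1, keepdims=True)
    factor = 1.0 + model.k1 * r2 + model.k2 * r2 * r2
    return pp + rel * factor


def undistort(
    p: np.ndarray | tuple, model: CameraModel, tol_px: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Invert the radial model by fixed-point iteration.

    Identity when ``k1 = k2 = 0``; the principal point always maps to
    itself.  Raises on non-convergence (pathologically strong
    distortion).
    """
    p = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    if model.k1 == 0.0 and model.k2 == 0.0:
        return p.copy()
    pp = np.asarray(model.principal_point_px)
    rel_d = p - pp
    rel_u = rel_d.copy()
    for _ in range(max_iter):
        r2 = np.sum(rel_u * rel_u, axis=-1, keepdims=True)
        factor = 1.0 + model.k1 * r2 + model.k2 * r2 * r2
        new_rel_u = rel_d / factor
        if np.max(np.abs(new_rel_u - rel_u)) < tol_px:
            return pp + new_rel_u
        rel_u = new_rel_u
    raise RuntimeError("undistort fixed-point iteration did not converge")


def px_to_mm(displacement_px: np.ndarray | tuple, model: CameraModel) -> dict:
    """Convert an image-plane displacement (dx, dy) px to anatomical mm.

    Divides by the pixel scale and applies the axis map's signs; returns
    e.g. ``{"SI": ..., "AP": ...}`` (vectorized over leading axes).
    """
    d = np.asarray(displacement_px, dtype=np.float64)
    out = {}
    for i, image_axis in enumerate(("x", "y")):
        anat, sign = model.axis_map[image_axis]
        out[anat] = sign * d[..., i] / model.pixel_scale_px_per_mm
    return out


def mm_to_px(displacement_mm: dict, model: CameraModel) -> np.ndarray:
    """Inverse of :func:`px_to_mm` (exact; the maps are linear)."""
    out = np.zeros(
        np.broadcast(*[np.asarray(v) for v in displacement_mm.values()]).shape + (2,)
    )
    for i, image_axis in enumerate(("x", "y")):
        anat, sign = model.axis_map[image_axis]
        out[..., i] = np.asarray(displacement_mm[anat]) * sign * model.pixel_scale_px_per_mm
    return out


def calibrate_scale(
    known_distance_mm: float,
    centroid_a_px: tuple[float, float],
    centroid_b_px: tuple[float, float],
) -> float:
    """Pixel scale from two marker centroids a known distance apart."""
    if known_distance_mm <= 0:
        raise ValueError("known_distance_mm must be positive")
    a = np.asarray(centroid_a_px, dtype=np.float64)
    b = np.asarray(centroid_b_px, dtype=np.float64)
    dist_px = float(np.hypot(*(a - b)))
    if dist_px == 0.0:
        raise ValueError("centroids must be distinct")
    return dist_px / known_distance_mm
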