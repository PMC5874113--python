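"""Single-channel image frames and low-level sampling helpers.

All image math in this package operates on :class:`ImageGrid`: a 2-D
float intensity field with row-major storage, 0-based indices, origin at
the top-left corner and y increasing downward.  Sub-pixel positions use
the convention that pixel ``(i, j)`` is centred at coordinates
``(x=j, y=i)`` and covers the half-open square ``[j-0.5, j+0.5) x
[i-0.5, i+0.5)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ImageGrid:
    """A single-channel frame with an acquisition timestamp.

    Parameters
    ----------
    pixels
        2-D array of finite intensities, typically in [0, 1].
    timestamp_s
        Acquisition time in seconds from the start of the sequence.
    """

    pixels: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("ImageGrid requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageGrid intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def bilinear_sample(img: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample ``img`` at sub-pixel positions with bilinear interpolation.

    Coordinates outside the grid are clamped to the border (replication),
    matching the border handling used for gradients.
    """
    h, w = img.shape
    x = np.clip(np.asarray(x, dtype=np.float64), 0.0, w - 1.0)
    y = np.clip(np.asarray(y, dtype=np.float64), 0.0, h - 1.0)
    x0 = np.floor(x).astype(np.intp)
    y0 = np.floor(y).astype(np.intp)
    x0 = np.minimum(x0, w - 2) if w > 1 else x0 * 0
    y0 = np.minimum(y0, h - 2) if h > 1 else y0 * 0
    fx = x - x0
    fy = y - y0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    top = img[y0, x0] * (1.0 - fx) + img[y0, x1] * fx
    bot = img[y1, x0] * (1.0 - fx) + img[y1, x1] * fx
    return top * (1.0 - fy) + bot * fy


def central_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients (d/dx, d/dy) with border replication."""
    padded = np.pad(img, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return gx, gy
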