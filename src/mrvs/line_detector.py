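"""Oriented line-detector filtering.

The basic line detector assigns each pixel the largest mean gray level over
a set of short digital line segments through the pixel (12 orientations at
15 deg by default, segment length equal to the window side).  The reported
line strength subtracts the mean gray of the surrounding square window, so
elongated bright structures score high while flat regions score zero
regardless of their brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .io_geometry import AngiogramImage, ValidationError, as_pixels

__all__ = ["StrengthMap", "LineDetector", "line_strength", "normalize01", "line_offsets"]


@dataclass
class StrengthMap:
    """Line-strength values plus the filter parameters that produced them."""

    values: np.ndarray
    window_px: int
    n_orientations: int
    angle_step_deg: float


def line_offsets(window_px: int, angle_deg: float) -> np.ndarray:
    """(row, col) offsets of the digital line through the origin at ``angle_deg``.

    The line is rasterized Bresenham-style: the parameter runs over the
    dominant axis, the other coordinate is rounded (round-half-even, which is
    odd-symmetric so the offset set is symmetric about the origin and the set
    family is closed under 90 deg rotation).  angle 0 is horizontal (along
    columns), angles increase counter-clockwise in the (row, col) plane.
    """
    half = window_px // 2
    t = np.arange(-half, half + 1)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    if abs(c) >= abs(s):  # column-dominant
        dc = t
        dr = np.rint(t * (s / c)).astype(int)
    else:  # row-dominant
        dr = t
        dc = np.rint(t * (c / s)).astype(int)
    return np.stack([dr, dc], axis=1)


def _shifted_sum_count(img: np.ndarray, offsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and in-bounds count of ``img`` sampled at each offset, per pixel."""
    h, w = img.shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        acc[r0:r1, c0:c1] += img[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        cnt[r0:r1, c0:c1] += 1.0
    return acc, cnt


def line_strength(
    image: AngiogramImage | np.ndarray,
    window_px: int,
    n_orientations: int = 12,
    angle_step_deg: float = 15.0,
) -> StrengthMap:
    """Oriented line strength S(p) = max-orientation line mean minus window mean.

    Lines and windows are clipped at the image border (means are taken over
    in-bounds pixels only), so there are no padding artifacts at the field
    edge.  S may be negative (e.g. on dark linear structures).
    """
    img = as_pixels(image)
    if window_px < 3 or window_px % 2 == 0:
        raise ValidationError("window_px: must be odd and >= 3")
    if abs(n_orientations * angle_step_deg - 180.0) > 1e-9:
        raise ValidationError("n_orientations * angle_step_deg must equal 180")
    if min(img.shape) < window_px:
        raise ValidationError("image smaller than the filter window")

    best = np.full(img.shape, -np.inf)
    for k in range(n_orientations):
        offs = line_offsets(window_px, k * angle_step_deg)
        acc, cnt = _shifted_sum_count(img, offs)
        np.maximum(best, acc / cnt, out=best)

    # border-clipped window mean: sliding sum / in-bounds pixel count
    size = (window_px, window_px)
    wsum = ndimage.uniform_filter(img, size=size, mode="constant", cval=0.0) * window_px**2
    wcnt = (
        ndimage.uniform_filter(np.ones_like(img), size=size, mode="constant", cval=0.0)
        * window_px**2
    )
    values = best - wsum / wcnt
    return StrengthMap(
        values=values,
        window_px=window_px,
        n_orientations=n_orientations,
        angle_step_deg=angle_step_deg,
    )


def normalize01(map_or_image) -> np.ndarray:
    """Affine min-max rescale to [0, 1]; a constant grid maps to all zeros."""
    if isinstance(map_or_image, StrengthMap):
        arr = map_or_image.values
    else:
        arr = map_or_image
    arr = np.asarray(arr, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValidationError("normalize01: values must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


class LineDetector(TransformerMixin, BaseEstimator):
    """Oriented line-detector filter as a stateless sklearn transformer.

    Parameters
    ----------
    window_px : int, default=25
        Odd side length of the square window; also the digital line length.
    n_orientations : int, default=12
    angle_step_deg : float, default=15.0
        Must satisfy ``n_orientations * angle_step_deg == 180``.
    """

    def __init__(
        self,
        window_px: int = 25,
        n_orientations: int = 12,
        angle_step_deg: float = 15.0,
    ):
        self.window_px = window_px
        self.n_orientations = n_orientations
        self.angle_step_deg = angle_step_deg

    def fit(self, X, y=None):
        as_pixels(X)  # validation only; the filter has no learned state
        self.n_features_in_ = np.asarray(
            X.pixels if isinstance(X, AngiogramImage) else X
        ).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Return the line-strength values for a single 2-D image."""
        return line_strength(
            X, self.window_px, self.n_orientations, self.angle_step_deg
        ).values
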