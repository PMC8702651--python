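"""Foveal avascular zone (FAZ) and non-perfusion area (NPA) detection.

Both detectors operate on the fused binary vessel mask.  The vessel mask is
morphologically closed with a disk to seal normal intercapillary gaps; the
remaining avascular (background) components are then analyzed:

* the FAZ is the avascular 4-connected component containing the image
  center (or, if the center is vascular, the component whose centroid is
  nearest the center, within 0.5 mm);
* non-perfusion regions are the remaining avascular components above a
  minimum physical area, excluding components touching the border strip
  (one closing radius wide) where closing is unreliable.

Ellipse descriptors (axes, orientation, eccentricity) come from the
second-order central moments of the filled FAZ component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.base import BaseEstimator

from .io_geometry import AngiogramImage, ValidationError

__all__ = [
    "FazRegion",
    "NonPerfusionMap",
    "FazNotFoundError",
    "FazDetector",
    "NonPerfusionDetector",
    "detect_faz",
    "detect_nonperfusion",
]


class FazNotFoundError(RuntimeError):
    """No avascular pocket exists at or near the image center."""


@dataclass
class FazRegion:
    """The detected FAZ component and its morphometric descriptors."""

    mask: np.ndarray
    area_mm2: float
    perimeter_mm: float
    circularity: float
    major_axis_mm: float
    minor_axis_mm: float
    orientation_deg: float  # CCW from the row axis, (-90, 90]
    eccentricity: float
    horizontal_diameter_mm: float
    vertical_diameter_mm: float
    centroid: tuple[float, float]


@dataclass
class NonPerfusionMap:
    """Avascular regions outside the FAZ above the minimum area."""

    mask: np.ndarray
    total_area_mm2: float
    n_regions: int


def _closed_background_labels(fused_mask: np.ndarray, close_radius_px: int):
    closed = morphology.closing(
        np.asarray(fused_mask, bool), morphology.disk(close_radius_px)
    )
    labels, n = ndimage.label(~closed, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))  # 4-connectivity
    return labels, n


def detect_faz(
    fused_mask: np.ndarray,
    geometry: AngiogramImage | float,
    faz_close_radius_px: int = 10,
) -> FazRegion:
    """Detect the FAZ from a fused vessel mask.

    ``geometry`` is either the source :class:`AngiogramImage` or the
    mm-per-pixel scale directly.  Raises :class:`FazNotFoundError` when no
    avascular component lies at or within 0.5 mm of the image center.
    """
    mask = np.asarray(fused_mask, bool)
    mm_per_px = (
        geometry.mm_per_px if isinstance(geometry, AngiogramImage) else float(geometry)
    )
    if mm_per_px <= 0:
        raise ValidationError("mm_per_px: must be positive")
    h, w = mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    labels, n = _closed_background_labels(mask, faz_close_radius_px)
    center_label = labels[int(round(cy)), int(round(cx))]
    if center_label == 0:
        if n == 0:
            raise FazNotFoundError("vessel mask has no avascular component")
        centroids = ndimage.center_of_mass(labels > 0, labels, np.arange(1, n + 1))
        d = [math.hypot(r - cy, c - cx) for r, c in centroids]
        best = int(np.argmin(d))
        if d[best] * mm_per_px > 0.5:
            raise FazNotFoundError(
                "no avascular pocket within 0.5 mm of the image center"
            )
        center_label = best + 1
    faz = ndimage.binary_fill_holes(labels == center_label)

    area_px = int(faz.sum())
    area_mm2 = area_px * mm_per_px**2
    # Crofton perimeter estimate; the raw boundary-pixel count is biased for
    # digital disks and would push circularity far outside (0, 1.1]
    perim_px = float(measure.perimeter_crofton(faz, directions=4))
    perimeter_mm = perim_px * mm_per_px
    circularity = 4 * math.pi * area_px / perim_px**2 if perim_px > 0 else float("nan")

    props = measure.regionprops(faz.astype(np.uint8))[0]
    major = props.axis_major_length * mm_per_px
    minor = props.axis_minor_length * mm_per_px
    orientation_deg = math.degrees(props.orientation)
    if orientation_deg <= -90.0:
        orientation_deg += 180.0
    ecc = props.eccentricity
    r0, c0 = props.centroid

    row = faz[int(round(r0)), :]
    col = faz[:, int(round(c0))]
    cols = np.flatnonzero(row)
    rows = np.flatnonzero(col)
    horiz = (cols.max() - cols.min() + 1) * mm_per_px if cols.size else 0.0
    vert = (rows.max() - rows.min() + 1) * mm_per_px if rows.size else 0.0

    return FazRegion(
        mask=faz,
        area_mm2=area_mm2,
        perimeter_mm=perimeter_mm,
        circularity=circularity,
        major_axis_mm=major,
        minor_axis_mm=minor,
        orientation_deg=orientation_deg,
        eccentricity=ecc,
        horizontal_diameter_mm=horiz,
        vertical_diameter_mm=vert,
        centroid=(r0, c0),
    )


def detect_nonperfusion(
    fused_mask: np.ndarray,
    faz: FazRegion | None,
    geometry: AngiogramImage | float,
    npa_close_radius_px: int = 10,
    npa_min_area_mm2: float = 0.015,
) -> NonPerfusionMap:
    """Detect non-perfusion regions: large avascular pockets outside the FAZ."""
    mask = np.asarray(fused_mask, bool)
    mm_per_px = (
        geometry.mm_per_px if isinstance(geometry, AngiogramImage) else float(geometry)
    )
    h, w = mask.shape
    labels, n = _closed_background_labels(mask, npa_close_radius_px)
    out = np.zeros_like(mask)
    total = 0.0
    count = 0
    if n == 0:
        return NonPerfusionMap(out, 0.0, 0)

    margin = npa_close_radius_px
    border = np.zeros_like(mask)
    border[:margin, :] = border[-margin:, :] = True
    border[:, :margin] = border[:, -margin:] = True
    border_labels = set(np.unique(labels[border])) - {0}
    faz_labels: set[int] = set()
    if faz is not None:
        faz_labels = set(np.unique(labels[faz.mask])) - {0}

    min_px = npa_min_area_mm2 / mm_per_px**2
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    for lab in range(1, n + 1):
        if lab in border_labels or lab in faz_labels:
            continue
        if sizes[lab - 1] >= min_px:
            region = labels == lab
            out |= region
            total += sizes[lab - 1] * mm_per_px**2
            count += 1
    out &= ~mask
    return NonPerfusionMap(mask=out, total_area_mm2=total, n_regions=count)


class FazDetector(BaseEstimator):
    """FAZ detector as an sklearn-style estimator over a fused vessel mask.

    ``fit(mask)`` stores the detected region as ``region_`` plus flat
    ``area_mm2_`` ... attributes mirroring :class:`FazRegion`.
    """

    def __init__(self, close_radius_px: int = 10, mm_per_px: float = 3.0 / 320):
        self.close_radius_px = close_radius_px
        self.mm_per_px = mm_per_px

    def fit(self, X, y=None):
        region = detect_faz(X, self.mm_per_px, self.close_radius_px)
        self.region_ = region
        self.mask_ = region.mask
        self.area_mm2_ = region.area_mm2
        self.perimeter_mm_ = region.perimeter_mm
        self.circularity_ = region.circularity
        self.eccentricity_ = region.eccentricity
        self.orientation_deg_ = region.orientation_deg
        self.centroid_ = region.centroid
        return self


class NonPerfusionDetector(BaseEstimator):
    """Non-perfusion detector; ``fit(mask)`` exposes ``map_`` and totals."""

    def __init__(
        self,
        close_radius_px: int = 10,
        min_area_mm2: float = 0.015,
        mm_per_px: float = 3.0 / 320,
        faz: FazRegion | None = None,
    ):
        self.close_radius_px = close_radius_px
        self.min_area_mm2 = min_area_mm2
        self.mm_per_px = mm_per_px
        self.faz = faz

    def fit(self, X, y=None):
        npa = detect_nonperfusion(
            X, self.faz, self.mm_per_px, self.close_radius_px, self.min_area_mm2
        )
        self.map_ = npa
        self.mask_ = npa.mask
        self.total_area_mm2_ = npa.total_area_mm2
        self.n_regions_ = npa.n_regions
        return self
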