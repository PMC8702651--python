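"""Quantification of the 24 segmentation-derived OCTA metrics.

Global metrics are fractions of the full 3 x 3 mm field; ring metrics are
fractions of 1 mm / 2 mm diameter disks centered on the FAZ centroid.
Undefined metrics (e.g. FAZ descriptors when no FAZ is found, diameter
index of an empty skeleton) are reported as NaN sentinels, never as 0.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np

from .faz_npa import FazNotFoundError, detect_faz, detect_nonperfusion
from .io_geometry import AngiogramImage, MrvsConfig, ValidationError
from .segmentation import MrvsSegmenter, perimeter_map, skeletonize

__all__ = [
    "MetricsRecord",
    "METRIC_NAMES",
    "area_density",
    "vessel_perimeter_index",
    "vessel_diameter_index",
    "vessel_complexity_index",
    "box_counting_dimension",
    "circle_roi",
    "quantify_all",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsRecord:
    """The 24 quantified OCTA metrics for one en-face image."""

    vessel_density: float
    vessel_skeleton_density: float
    vessel_perimeter_index: float
    vessel_diameter_index_px: float
    vessel_complexity_index: float
    vessel_skeleton_fractal_dimension: float
    big_vessel_density: float
    small_vessel_density: float
    big_vessel_skeleton_density: float
    small_vessel_skeleton_density: float
    non_perfusion_area_mm2: float
    faz_area_mm2: float
    faz_perimeter_mm: float
    faz_circularity: float
    faz_major_axis_mm: float
    faz_minor_axis_mm: float
    faz_orientation_deg: float
    faz_eccentricity: float
    faz_horizontal_diameter_mm: float
    faz_vertical_diameter_mm: float
    vd_circle_1mm: float
    vd_circle_2mm: float
    vsd_circle_1mm: float
    vsd_circle_2mm: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


METRIC_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(MetricsRecord)
)


def area_density(mask: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Foreground fraction |mask ∩ roi| / |roi| (roi defaults to the field)."""
    mask = np.asarray(mask, bool)
    if roi_mask is None:
        roi_mask = np.ones_like(mask)
    roi = np.asarray(roi_mask, bool)
    if roi.shape != mask.shape:
        raise ValidationError("roi_mask shape differs from mask")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValidationError("roi_mask: empty ROI")
    return float((mask & roi).sum()) / n_roi


def vessel_perimeter_index(
    perimeter_mask: np.ndarray, roi_mask: np.ndarray | None = None
) -> float:
    """Boundary-pixel fraction of the ROI."""
    return area_density(perimeter_mask, roi_mask)


def vessel_diameter_index(vessel_mask: np.ndarray, skeleton_mask: np.ndarray) -> float:
    """Mean vessel caliber proxy: foreground area per skeleton length (px)."""
    n_skel = int(np.asarray(skeleton_mask, bool).sum())
    if n_skel == 0:
        return float("nan")
    return float(np.asarray(vessel_mask, bool).sum()) / n_skel


def vessel_complexity_index(
    vessel_mask: np.ndarray, perimeter_mask: np.ndarray
) -> float:
    """Shape complexity P^2 / (4 pi A) from pixel counts (disk -> minimum)."""
    a = int(np.asarray(vessel_mask, bool).sum())
    if a == 0:
        return float("nan")
    p = int(np.asarray(perimeter_mask, bool).sum())
    return p**2 / (4.0 * math.pi * a)


def box_counting_dimension(
    skeleton_mask: np.ndarray, box_sizes: tuple[int, ...] = (2, 4, 8, 16, 32, 64)
) -> float:
    """Box-counting fractal dimension of a skeleton raster.

    Counts occupied s x s boxes on a fixed grid anchored at (0, 0) for each
    box size, then returns the negated slope of the least-squares fit of
    log N(s) on log s.
    """
    mask = np.asarray(skeleton_mask, bool)
    if not mask.any():
        return float("nan")
    counts = []
    for s in box_sizes:
        h, w = mask.shape
        ph, pw = (-h) % s, (-w) % s
        padded = np.pad(mask, ((0, ph), (0, pw)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    log_s = np.log(np.asarray(box_sizes, dtype=float))
    log_n = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(log_s, log_n, 1)[0]
    return float(-slope)


def circle_roi(
    shape: tuple[int, int],
    center: tuple[float, float],
    diameter_mm: float,
    mm_per_px: float,
) -> np.ndarray:
    """Disk ROI of the stated physical diameter centered at (row, col)."""
    h, w = shape
    if diameter_mm > min(h, w) * mm_per_px + 1e-9:
        raise ValidationError("diameter_mm: circle exceeds the imaged field")
    radius_px = diameter_mm / 2.0 / mm_per_px
    rr, cc = np.ogrid[0:h, 0:w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def quantify_all(
    image: AngiogramImage, config: MrvsConfig | None = None
) -> MetricsRecord:
    """Run the full pipeline and quantify all 24 metrics for one image.

    When no FAZ is found the FAZ metrics are NaN and the ring ROIs fall back
    to the image center.
    """
    config = config or MrvsConfig()
    seg = MrvsSegmenter.from_config(config).fit(image)
    fused = seg.fused_mask_
    skel = seg.skeleton_mask_
    perim = seg.perimeter_mask_
    mm_per_px = image.mm_per_px

    try:
        faz = detect_faz(fused, image, config.faz_close_radius_px)
        roi_center = faz.centroid
    except FazNotFoundError:
        logger.warning("FAZ not found; FAZ metrics set to NaN, ring ROIs centered "
                       "on the image center")
        faz = None
        roi_center = image.center

    npa = detect_nonperfusion(
        fused, faz, image, config.npa_close_radius_px, config.npa_min_area_mm2
    )

    shape = fused.shape
    roi1 = circle_roi(shape, roi_center, 1.0, mm_per_px)
    roi2 = circle_roi(shape, roi_center, 2.0, mm_per_px)

    big_skel = skeletonize(seg.large_mask_)
    small_skel = skeletonize(seg.capillary_mask_)
    nan = float("nan")

    return MetricsRecord(
        vessel_density=area_density(fused),
        vessel_skeleton_density=area_density(skel),
        vessel_perimeter_index=vessel_perimeter_index(perim),
        vessel_diameter_index_px=vessel_diameter_index(fused, skel),
        vessel_complexity_index=vessel_complexity_index(fused, perim),
        vessel_skeleton_fractal_dimension=box_counting_dimension(skel),
        big_vessel_density=area_density(seg.large_mask_),
        small_vessel_density=area_density(seg.capillary_mask_),
        big_vessel_skeleton_density=area_density(big_skel),
        small_vessel_skeleton_density=area_density(small_skel),
        non_perfusion_area_mm2=npa.total_area_mm2,
        faz_area_mm2=faz.area_mm2 if faz else nan,
        faz_perimeter_mm=faz.perimeter_mm if faz else nan,
        faz_circularity=faz.circularity if faz else nan,
        faz_major_axis_mm=faz.major_axis_mm if faz else nan,
        faz_minor_axis_mm=faz.minor_axis_mm if faz else nan,
        faz_orientation_deg=faz.orientation_deg if faz else nan,
        faz_eccentricity=faz.eccentricity if faz else nan,
        faz_horizontal_diameter_mm=faz.horizontal_diameter_mm if faz else nan,
        faz_vertical_diameter_mm=faz.vertical_diameter_mm if faz else nan,
        vd_circle_1mm=area_density(fused, roi1),
        vd_circle_2mm=area_density(fused, roi2),
        vsd_circle_1mm=area_density(skel, roi1),
        vsd_circle_2mm=area_density(skel, roi2),
    )
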