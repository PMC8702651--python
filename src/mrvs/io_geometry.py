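"""Image/mask I/O, physical geometry and pipeline configuration.

En-face OCTA angiograms are exported by the instrument as 8-bit grayscale
rasters covering a square macular field (3 mm x 3 mm by default).  All
physical metrics downstream (areas in mm^2, perimeters in mm) derive from
the single scale factor ``mm_per_px = field_size_mm / width``.

Coordinate convention: (row, col), 0-based, origin at the top-left corner;
the image center is ((h - 1) / 2, (w - 1) / 2).
"""

from __future__ import annotations

import dataclasses
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "AngiogramImage",
    "BinaryMask",
    "MrvsConfig",
    "ValidationError",
    "read_angiogram",
    "write_mask",
    "read_mask",
    "load_config",
    "save_config",
]

MASK_ROLES = frozenset(
    {
        "large_vessel",
        "capillary",
        "fused",
        "skeleton",
        "perimeter",
        "faz",
        "non_perfusion",
        "ground_truth",
    }
)


class ValidationError(ValueError):
    """A domain invariant was violated; the message names the field."""


@dataclass
class AngiogramImage:
    """A 2-D grayscale en-face angiogram with physical geometry.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Gray levels in [0, 255] (dimensionless flow/reflectance signal).
    field_size_mm : float
        Physical side length of the square field, in mm.
    """

    pixels: np.ndarray
    field_size_mm: float = 3.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels: expected 2-D, got {self.pixels.ndim}-D")
        if self.pixels.size == 0:
            raise ValidationError("pixels: empty image")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("pixels: gray levels must lie in [0, 255]")
        if not self.field_size_mm > 0:
            raise ValidationError("field_size_mm: must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def mm_per_px(self) -> float:
        return self.field_size_mm / self.width

    @property
    def center(self) -> tuple[float, float]:
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)


@dataclass
class BinaryMask:
    """A role-tagged boolean raster sharing the shape of its parent image."""

    pixels: np.ndarray
    role: str = "ground_truth"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError(f"mask pixels: expected 2-D, got {self.pixels.ndim}-D")
        if self.role not in MASK_ROLES:
            raise ValidationError(f"role: {self.role!r} not one of {sorted(MASK_ROLES)}")


@dataclass
class MrvsConfig:
    """Tunable parameters of both segmentation branches and FAZ/NPA detection.

    Defaults: a 25x25 line-detector window for large vessels, 7x7 for
    capillaries, structural/intensity combination weights 1/3 and 2/3,
    background attenuation by half, large-vessel fill gray 45, and 12 line
    orientations at 15 deg spacing.
    """

    n_orientations: int = 12
    angle_step_deg: float = 15.0
    win_large_px: int = 25
    win_cap_px: int = 7
    w_struct: float = 1.0 / 3.0
    w_intensity: float = 2.0 / 3.0
    background_atten: float = 0.5
    large_vessel_fill_gray: float = 45.0
    tophat_se_radius_px: int = 8
    faz_close_radius_px: int = 10
    npa_close_radius_px: int = 10
    npa_min_area_mm2: float = 0.015
    kmeans_k: int = 2
    kmeans_seed: int = 0

    def __post_init__(self) -> None:
        if self.kmeans_k != 2:
            raise ValidationError("kmeans_k: fixed at 2")
        for name in ("win_large_px", "win_cap_px"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValidationError(f"{name}: window size must be odd and >= 3")
        if not self.win_cap_px < self.win_large_px:
            raise ValidationError("win_cap_px: must be smaller than win_large_px")
        if not (0 < self.w_struct < 1 and 0 < self.w_intensity < 1):
            raise ValidationError("w_struct/w_intensity: weights must lie in (0, 1)")
        if abs(self.w_struct + self.w_intensity - 1.0) > 1e-9:
            raise ValidationError("w_struct: w_struct + w_intensity must equal 1")
        if abs(self.n_orientations * self.angle_step_deg - 180.0) > 1e-9:
            raise ValidationError(
                "n_orientations: n_orientations * angle_step_deg must equal 180"
            )
        if not 0 <= self.background_atten <= 1:
            raise ValidationError("background_atten: must lie in [0, 1]")
        if not 0 <= self.large_vessel_fill_gray <= 255:
            raise ValidationError("large_vessel_fill_gray: must lie in [0, 255]")
        for name in ("tophat_se_radius_px", "faz_close_radius_px", "npa_close_radius_px"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name}: must be >= 1")
        if self.npa_min_area_mm2 < 0:
            raise ValidationError("npa_min_area_mm2: must be >= 0")


def read_angiogram(path: str | Path, field_size_mm: float = 3.0) -> AngiogramImage:
    """Read an exported en-face angiogram (TIFF or PNG) as an 8-bit image.

    16-bit inputs are rescaled to 0-255.  RGB exports are collapsed to a
    single channel: if the three channels are identical one is taken,
    otherwise a luminance average is used and a warning is emitted.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3]
        if (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 0] == rgb[..., 2]).all():
            arr = rgb[..., 0]
        else:
            warnings.warn(
                f"{path.name}: RGB channels differ; collapsing by luminance average",
                stacklevel=2,
            )
            arr = rgb.mean(axis=-1)
    if arr.ndim != 2:
        raise OSError(f"{path}: multi-frame or volumetric image is unsupported")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    arr = np.asarray(arr, dtype=np.float64)
    return AngiogramImage(pixels=arr, field_size_mm=field_size_mm)


def write_mask(path: str | Path, mask: BinaryMask | np.ndarray) -> None:
    """Write a binary mask losslessly: foreground 255, background 0."""
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    out = np.where(pixels, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path, role: str = "ground_truth") -> BinaryMask:
    """Read a stored mask; any nonzero pixel counts as foreground."""
    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(pixels=arr > 0, role=role)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(MrvsConfig)}


def load_config(path: str | Path) -> MrvsConfig:
    """Load an MrvsConfig from a TOML or YAML mapping; absent keys default."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path}: expected a mapping at top level")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    return MrvsConfig(**data)


def save_config(config: MrvsConfig, path: str | Path) -> None:
    """Save a config as YAML; round-trips through :func:`load_config`."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


def as_pixels(image: AngiogramImage | np.ndarray) -> np.ndarray:
    """Return the float64 pixel grid of an image-like argument."""
    if isinstance(image, AngiogramImage):
        return np.asarray(image.pixels, dtype=np.float64)
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"image: expected 2-D, got {arr.ndim}-D")
    return arr
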