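"""Synthetic OCTA-like angiogram phantoms with pixel-exact ground truth.

The phantom emulates a 3 mm x 3 mm en-face superficial-plexus angiogram:
a few large vessel trunks grow inward from the field borders as correlated
random walks, spawn a recursively branching capillary mesh, and a
perifoveal capillary ring encircles a jittered elliptical foveal avascular
zone (FAZ).  Optional dropout pockets emulate capillary non-perfusion.
Foreground intensity is drawn per pixel from caliber-class gray ranges and
the whole field is multiplied by unit-mean gamma speckle.

Every stochastic element is keyed off ``spec.seed`` through independent
named RNG streams; in particular each branch decision and each branch
trajectory is keyed by its position in the vessel tree, so raising
``branching_prob`` at a fixed seed grows a strict superset of vessels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_geometry import AngiogramImage, ValidationError

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom", "phantom_repeat_series"]

# stream tags (arbitrary distinct non-negative ints)
_GEOM, _TRUNK, _BRANCH_DECIDE, _BRANCH_WALK, _INTENSITY, _SPECKLE = 3, 5, 7, 11, 13, 17


@dataclass
class PhantomSpec:
    """Generation parameters; ranges are inclusive (lo, hi) pairs."""

    size_px: int = 320
    field_size_mm: float = 3.0
    n_large_trunks: tuple[int, int] = (2, 4)
    large_width_px: tuple[int, int] = (5, 9)
    cap_width_px: tuple[int, int] = (1, 2)
    branching_prob: float = 0.08
    step_px: float = 3.0
    turn_sigma_deg: float = 12.0
    faz_semi_axes_mm: tuple[float, float] = (0.25, 0.20)
    faz_jitter: float = 0.1
    dropout_patches: tuple[int, int] = (0, 3)
    dropout_area_mm2: tuple[float, float] = (0.05, 0.15)
    large_gray: tuple[int, int] = (180, 255)
    cap_gray: tuple[int, int] = (90, 160)
    background_gray_mean: float = 40.0
    speckle_shape: float = 4.0
    seed: int = 0
    # tree-structure bounds (kept realistic yet bounded; see docs/methods.md)
    trunk_max_steps: int = 200
    branch_max_steps: int = 60
    max_branch_depth: int = 3
    perifoveal_ring: bool = True

    def __post_init__(self) -> None:
        if self.size_px < 32:
            raise ValidationError("size_px: must be >= 32")
        if self.field_size_mm <= 0:
            raise ValidationError("field_size_mm: must be positive")
        for name in ("n_large_trunks", "large_width_px", "cap_width_px",
                     "dropout_patches", "dropout_area_mm2", "large_gray", "cap_gray"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: range lo must be <= hi")
        if min(self.large_width_px[0], self.cap_width_px[0]) < 1:
            raise ValidationError("vessel widths must be >= 1 px")
        if max(self.faz_semi_axes_mm) >= self.field_size_mm / 4:
            raise ValidationError("faz_semi_axes_mm: must be < field_size_mm / 4")
        if not 0 <= self.branching_prob <= 1:
            raise ValidationError("branching_prob: must lie in [0, 1]")
        if self.step_px <= 0:
            raise ValidationError("step_px: must be positive")
        if self.speckle_shape <= 0:
            raise ValidationError("speckle_shape: must be positive")
        if self.faz_jitter < 0:
            raise ValidationError("faz_jitter: must be >= 0")

    @property
    def mm_per_px(self) -> float:
        return self.field_size_mm / self.size_px


@dataclass
class PhantomBundle:
    """A rendered phantom image with its exact ground-truth masks."""

    image: AngiogramImage
    gt_vessel: np.ndarray
    gt_large: np.ndarray
    gt_faz: np.ndarray
    gt_dropout: np.ndarray
    spec: PhantomSpec


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    """Stamp a filled disk (Euclidean, inclusive radius) into a bool raster."""
    h, w = mask.shape
    # snap to the pixel grid so a width-1 stamp always covers exactly one
    # pixel and successive unit-spaced stamps stay 8-connected
    r, c = round(r), round(c)
    ir = int(math.ceil(radius))
    r0, r1 = max(0, r - ir), min(h, r + ir + 1)
    c0, c1 = max(0, c - ir), min(w, c + ir + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _width_radius(width: int) -> float:
    # odd widths stamp exactly `width` pixels across; even widths round down
    return max(0.5, (width - 1) / 2.0)


def _faz_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Jittered-ellipse FAZ mask and its polar boundary function."""
    s = spec.size_px
    cy = cx = (s - 1) / 2.0
    a = spec.faz_semi_axes_mm[0] / spec.mm_per_px
    b = spec.faz_semi_axes_mm[1] / spec.mm_per_px
    k = int(rng.integers(2, 5))  # low-frequency boundary roughness
    phi0 = rng.uniform(0, 2 * np.pi)
    amp = spec.faz_jitter

    def boundary_radius(phi):
        m = 1.0 + amp * np.sin(k * np.asarray(phi) + phi0)
        return m / np.sqrt((np.cos(phi) / a) ** 2 + (np.sin(phi) / b) ** 2)

    rr, cc = np.mgrid[0:s, 0:s]
    dy, dx = rr - cy, cc - cx
    phi = np.arctan2(dy, dx)
    m = 1.0 + amp * np.sin(k * phi + phi0)
    faz = (dx / (a * m)) ** 2 + (dy / (b * m)) ** 2 <= 1.0
    return faz, boundary_radius, (cy, cx)


def _walk(
    spec: PhantomSpec,
    start: tuple[float, float],
    heading: float,
    width: int,
    rng: np.random.Generator,
    max_steps: int,
    dist_to_avoid: np.ndarray,
    out_mask: np.ndarray,
    path: tuple[int, ...],
    depth: int,
    cap_mask: np.ndarray,
) -> None:
    """Correlated random walk stamping disks; spawns keyed sub-branches."""
    s = spec.size_px
    turn = math.radians(spec.turn_sigma_deg)
    margin = _width_radius(width) + 0.5
    pos = np.array(start, dtype=float)
    radius = _width_radius(width)
    _stamp_disk(out_mask, pos[0], pos[1], radius)
    for t in range(max_steps):
        heading += rng.normal(0.0, turn)
        new = pos + spec.step_px * np.array([math.sin(heading), math.cos(heading)])
        if not (0 <= new[0] <= s - 1 and 0 <= new[1] <= s - 1):
            break
        if dist_to_avoid[int(round(new[0])), int(round(new[1]))] <= margin:
            break  # terminate at the FAZ / dropout boundary
        # stamp at ~unit spacing along the step so thin vessels stay connected
        nsub = max(1, int(math.ceil(spec.step_px)))
        for j in range(1, nsub + 1):
            p = pos + (new - pos) * (j / nsub)
            _stamp_disk(out_mask, p[0], p[1], radius)
        pos = new
        if depth < spec.max_branch_depth:
            u = np.random.default_rng(
                [spec.seed, _BRANCH_DECIDE, *path, t]
            ).random()
            if u < spec.branching_prob:
                crng = np.random.default_rng([spec.seed, _BRANCH_WALK, *path, t])
                cwidth = int(crng.integers(spec.cap_width_px[0], spec.cap_width_px[1] + 1))
                side = 1.0 if crng.random() < 0.5 else -1.0
                cheading = heading + side * (math.pi / 2 + crng.normal(0.0, 0.3))
                _walk(
                    spec, (pos[0], pos[1]), cheading, cwidth, crng,
                    spec.branch_max_steps, dist_to_avoid, cap_mask,
                    (*path, t), depth + 1, cap_mask,
                )


def _geometry(spec: PhantomSpec):
    """Deterministic phantom geometry: masks and the noise-free gray field."""
    s = spec.size_px
    geom_rng = np.random.default_rng([spec.seed, _GEOM])

    faz, boundary_radius, (cy, cx) = _faz_geometry(spec, geom_rng)

    # dropout pockets: avascular disks away from the FAZ and the borders
    dropout = np.zeros((s, s), dtype=bool)
    n_drop = int(geom_rng.integers(spec.dropout_patches[0], spec.dropout_patches[1] + 1))
    faz_r_px = max(spec.faz_semi_axes_mm) / spec.mm_per_px
    for _ in range(n_drop):
        area = geom_rng.uniform(*spec.dropout_area_mm2)
        pr = math.sqrt(area / math.pi) / spec.mm_per_px
        for _try in range(100):
            # keep pockets well inside the field so they stay measurable
            r = geom_rng.uniform(pr + 30, s - 1 - pr - 30)
            c = geom_rng.uniform(pr + 30, s - 1 - pr - 30)
            if math.hypot(r - cy, c - cx) >= faz_r_px + pr + 12:
                _stamp_disk(dropout, r, c, pr)
                break

    avoid = faz | dropout
    dist_to_avoid = ndimage.distance_transform_edt(~avoid)

    large = np.zeros((s, s), dtype=bool)
    caps = np.zeros((s, s), dtype=bool)

    n_trunks = int(geom_rng.integers(spec.n_large_trunks[0], spec.n_large_trunks[1] + 1))
    starts = []
    for i in range(n_trunks):
        side = int(geom_rng.integers(0, 4))
        u = geom_rng.uniform(0.1, 0.9) * (s - 1)
        if side == 0:   # top edge, heading downward
            start, base = (0.0, u), math.pi / 2
        elif side == 1:  # bottom edge, heading upward
            start, base = (s - 1.0, u), -math.pi / 2
        elif side == 2:  # left edge, heading right
            start, base = (u, 0.0), 0.0
        else:            # right edge, heading left
            start, base = (u, s - 1.0), math.pi
        heading = base + geom_rng.uniform(-math.pi / 6, math.pi / 6)
        starts.append((start, heading))

    for i, (start, heading) in enumerate(starts):
        trng = np.random.default_rng([spec.seed, _TRUNK, i])
        width = int(trng.integers(spec.large_width_px[0], spec.large_width_px[1] + 1))
        _walk(
            spec, start, heading, width, trng, spec.trunk_max_steps,
            dist_to_avoid, large, (i,), 0, caps,
        )

    if spec.perifoveal_ring:
        # anatomical capillary arcade hugging the FAZ boundary
        phi = np.linspace(0.0, 2 * np.pi, 1440, endpoint=False)
        rho = boundary_radius(phi) + 1.5
        ring_r = cy + rho * np.sin(phi)
        ring_c = cx + rho * np.cos(phi)
        for r, c in zip(ring_r, ring_c):
            _stamp_disk(caps, r, c, 1.0)

    large &= ~avoid
    caps &= ~avoid
    caps &= ~large  # caliber classes are disjoint; trunks win ties
    vessel = large | caps

    int_rng = np.random.default_rng([spec.seed, _INTENSITY])
    large_field = int_rng.integers(spec.large_gray[0], spec.large_gray[1] + 1, (s, s))
    cap_field = int_rng.integers(spec.cap_gray[0], spec.cap_gray[1] + 1, (s, s))
    base = np.full((s, s), float(spec.background_gray_mean))
    base[caps] = cap_field[caps]
    base[large] = large_field[large]

    return vessel, large, faz, dropout, base


def _render(spec: PhantomSpec, base: np.ndarray, repeat_index: int) -> AngiogramImage:
    rng = np.random.default_rng([spec.seed, _SPECKLE, repeat_index])
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, base.shape)
    pixels = np.clip(np.rint(base * speckle), 0, 255).astype(np.uint8)
    return AngiogramImage(pixels=pixels, field_size_mm=spec.field_size_mm)


def generate_phantom(spec: PhantomSpec | None = None, **overrides) -> PhantomBundle:
    """Generate one phantom bundle; bit-identical for identical spec + seed."""
    if spec is None:
        spec = PhantomSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    vessel, large, faz, dropout, base = _geometry(spec)
    return PhantomBundle(
        image=_render(spec, base, 0),
        gt_vessel=vessel,
        gt_large=large,
        gt_faz=faz,
        gt_dropout=dropout,
        spec=spec,
    )


def phantom_repeat_series(spec: PhantomSpec, n_repeats: int) -> list[PhantomBundle]:
    """Repeated acquisitions of one eye: shared geometry, fresh speckle.

    Emulates repeated OCTA imaging of the same retina within minutes: the
    vasculature (and hence every ground-truth mask) is identical across
    repeats while the speckle realization is independent per repeat.
    """
    if n_repeats < 2:
        raise ValidationError("n_repeats: must be >= 2")
    vessel, large, faz, dropout, base = _geometry(spec)
    return [
        PhantomBundle(
            image=_render(spec, base, r),
            gt_vessel=vessel,
            gt_large=large,
            gt_faz=faz,
            gt_dropout=dropout,
            spec=spec,
        )
        for r in range(n_repeats)
    ]
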