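# Methods

## Segmentation model

The segmenter assumes an 8-bit en-face angiogram in which flowing blood is
bright, elongated and locally line-like, while background speckle is
bright but isotropic. Both branches exploit this with an oriented line
detector: for each pixel the mean gray level is taken along digital lines
(Bresenham rasterization, length equal to the window side, round-half-even
offsets so the orientation set is closed under 90° rotation) at 12
orientations spaced 15°, and the maximum line mean minus the mean of the
surrounding square window is the line strength. Subtracting the window
mean makes the response zero on flat regions regardless of brightness and
invariant to additive gray shifts; the raw max-line-mean variant (without
subtraction) would make the later vessel/background separation ill-posed
on bright backgrounds. Lines and windows are clipped at the image border
and means are taken over in-bounds pixels only, avoiding padding artifacts
at the edge of the 3 mm field.

The stage chain shared by both branches is: convex combination
`C = w_s·norm(S) + w_i·norm(I)` of min–max-normalized strength and
intensity (weights 1/3 and 2/3), Otsu binarization of `C`
into a rough vessel/background split, multiplication of rough-background
pixels by 0.5 (rounded half-up, stated explicitly for bit
reproducibility), and a deterministic 1-D two-means clustering of the
resulting gray levels. The clustering initializes centroids at the 25th
and 75th percentile gray values and runs Lloyd iterations until both
centroids move < 1e-6 (or 100 rounds); the brighter cluster is vessel.
Percentile initialization removes the run-to-run variance of random
K-means starts; the 1-D optimum is a contiguous split, which the
iteration reaches from any separated start.

The capillary branch first paints detected large vessels to gray 45
(mid-gray on the 0–255 scale, so they are neither bright outliers nor
holes) and enhances thin detail with `E = clip(I + tophat − bothat, 0,
255)` using a disk structuring element. After each branch, connected
components smaller than `win_cap_px²` pixels (8-connectivity — thin
vessels are 8-connected curvilinear chains) are removed as speckle
residue. The fused mask is the union of the branch masks; the capillary
mask excludes large-vessel pixels so big/small caliber metrics partition
exactly.

Degenerate inputs are defined behavior: a constant combined map yields an
all-background rough mask with a warning; a constant gray image yields an
empty vessel mask; an all-zero image propagates to empty masks.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `win_large_px` | 25 | px | large-trunk scale at 320 px / 3 mm (≈230 µm) |
| `win_cap_px` | 7 | px | capillary scale (≈66 µm) |
| `n_orientations`, `angle_step_deg` | 12, 15° | — | full 180° coverage |
| `w_struct`, `w_intensity` | ⅓, ⅔ | — | intensity carries most evidence; structure disambiguates lines from speckle |
| `background_atten` | 0.5 | — | halve detected background |
| `large_vessel_fill_gray` | 45 | gray | neutral fill before capillary pass |
| `tophat_se_radius_px` | 8 | px | ≈75 µm: larger than any capillary, smaller than background undulations; scale with resolution |
| `faz_close_radius_px`, `npa_close_radius_px` | 10 | px | seals normal intercapillary gaps (<2r ≈ 190 µm) |
| `npa_min_area_mm2` | 0.015 | mm² | ignores residual intercapillary pockets |

All physical outputs scale through `mm_per_px = field_size_mm / width`;
the exported pixel resolution is a free parameter (320 px assumed in the
defaults above).

## FAZ and non-perfusion detection

The vessel mask is closed with a disk to seal capillary gaps; 4-connected
avascular components of the complement are labeled. The FAZ is the
component containing the image center (or the one whose centroid lies
within 0.5 mm of it), hole-filled. Area is pixel count × mm_per_px²;
perimeter uses the Crofton estimate (4 directions) because the raw
boundary-pixel count is biased for digital disks (a disk would score
circularity ≈ 1.2 by count, vs 0.96–1.00 by Crofton); circularity is
`4πA/P²`; axes, orientation (degrees counter-clockwise from the row axis,
range (−90°, 90°]) and eccentricity come from second-order central
moments; horizontal/vertical diameters are the mask extents along the
centroid row/column. The vessel-perimeter-index metric deliberately keeps
the raw boundary-pixel count (foreground pixels 8-adjacent to in-image
background; a full-field mask has no perimeter) — it is a density-like
index, not a shape statistic.

Non-perfusion regions are the remaining avascular components with area ≥
`npa_min_area_mm2`, excluding the FAZ component and any component touching
the border strip one closing radius wide, where closing is unreliable.

## Quantified metrics

Densities are foreground fractions of the field or of 1 mm / 2 mm
*diameter* disks centered on the FAZ centroid (image center if no FAZ is
found). The diameter index is vessel area per skeleton length (Lee
thinning; Zhang–Suen can leave 3×3 junction blocks in dense meshes,
breaking the 1-px-width contract). The complexity index is `P²/(4πA)`
from pixel counts. The skeleton fractal dimension is the box-counting
slope over box sizes {2, 4, 8, 16, 32, 64} px on a grid anchored at
(0, 0) (no origin averaging, for determinism); it is exact on the
closed-form rasters used in tests (line → 1, plane → 2, Sierpinski →
log₂3). Undefined metrics (no FAZ, empty skeleton) are NaN sentinels,
never 0, so downstream statistics can exclude them.

## Evaluation and repeatability

Confusion counts give SE, SP, ACC, `DSC = 2TP/(2TP+FP+FN)`, MCC (0 when a
marginal is empty), and the vessel volume difference relative to the
ground-truth volume, `VVD = |(TP+FP)−(TP+FN)|/(TP+FN)` ("absolute" is
read as the absolute value of the relative difference). Repeatability of
a metric over balanced subjects × repeats tables uses
`Sw = sqrt(mean per-subject variance)` (ddof = 1; identical to pooled
ANOVA MSW for balanced data), `CoV = 100·Sw/mean`, and one-way
random-effects `ICC(1,1) = (MSB−MSW)/(MSB+(k−1)·MSW)` — the standard
test–retest choice when the same device re-scans; the estimator can be
slightly negative and is swappable.

## Phantom design

The generator emulates a 3 × 3 mm superficial-plexus angiogram: 2–4
trunks grow inward from the borders as correlated random walks (heading
jitter σ = 12°/step, step 3 px) stamped as disks (odd widths exact; even
widths round down to the nearest odd); branches spawn with probability
0.08 per step and branch recursively to depth 3 with up to 60 steps each
— bounds calibrated so ground-truth vessel density spans ≈0.13–0.42
(mean 0.31), matching published SCP densities; a perifoveal capillary
ring hugs the FAZ boundary, emulating the anatomical arcade and making
FAZ detection well-posed; the FAZ is a jittered ellipse (low-frequency
sinusoidal radial perturbation, so its area stays ≈ πab·(1+amp²/2));
optional dropout pockets are avascular disks placed ≥30 px from borders
and away from the FAZ. Foreground gray is drawn per pixel from
caliber-class ranges (large 180–255, capillary 90–160; background mean
40) and the field is multiplied by unit-mean gamma speckle (shape 4 by
default — the standard OCT speckle surrogate). Every stochastic element
is keyed off the seed through named RNG streams; branch decisions and
trajectories are keyed by tree position, so raising `branching_prob`
grows a strict superset of vessels, and repeat series share geometry
while redrawing only speckle.

The phantom does **not** emulate projection or motion artifacts, depth
(SCP/DCP) mixing, vessel-coherent intensity (gray is i.i.d. per pixel,
harsher than real flow signal), or physically modeled speckle
correlation. Passing phantom tests therefore demonstrates algorithmic
correctness and scale behavior, not clinical-grade accuracy.

## Known limitations

* Vessel density is systematically under-estimated by ≈0.05 on default
  phantoms: capillary pixels drawn below ≈100 gray fall under the
  two-means threshold (midpoint between background ≈15 and bright-vessel
  ≈200 centroids). This is intrinsic to gray-level clustering, not a bug;
  specificity is 1.0 and large vessels are fully covered.
* On phantoms whose capillaries are bright (the default gray ranges), the
  large branch also captures capillaries, so the big/small caliber split
  is meaningful only when capillary contrast is realistically low.
* Near-vesselless, strongly speckled inputs degenerate: two-means then
  splits background speckle and reports bright speckle as vessel. The
  capillary-free contracts hold exactly in the noise-free limit.
* Detected non-perfusion areas carry a positive bias (closing against a
  ragged capillary wall) of roughly +30 % on 0.1 mm² pockets, plus
  0.05–0.3 mm² of intercapillary residue on under-segmented masks.
* Circularity is quantization-biased for FAZs only a few pixels across;
  diameters below ≈0.2 mm should be interpreted with care at 320 px.
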