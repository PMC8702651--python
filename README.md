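# mrvs — multi-branch retinal vessel segmentation for en-face OCTA

`mrvs` segments retinal blood vessels in en-face optical coherence
tomography angiography (OCTA) images of the superficial capillary plexus
(3 mm × 3 mm macular field) and quantifies the standard panel of 24
vascular and foveal-avascular-zone (FAZ) biomarkers used in diabetic
retinopathy research. It is aimed at ophthalmic-imaging researchers who
need a transparent, fully reproducible alternative to instrument-bundled
black-box software.

## Method

Segmentation runs two parallel branches that share one stage chain and are
fused by union:

1. **Large-vessel branch (LVSB).** An oriented line detector assigns every
   pixel the strength `S(p) = max_θ L_θ(p) − W̄(p)`, where `L_θ(p)` is the
   mean gray level along a digital line of window length through `p` at
   orientation `θ ∈ {0°, 15°, …, 165°}` and `W̄(p)` is the mean of the
   surrounding square window (25 × 25 px). The combined map
   `C = ⅓·norm(S) + ⅔·norm(I)` is Otsu-binarized to a rough vessel mask,
   the detected background is halved to boost contrast, and a deterministic
   1-D 2-means clustering of gray levels yields the final mask (brighter
   cluster = vessel).
2. **Capillary branch.** Detected large vessels are painted to gray 45, the
   image is enhanced with a top–bottom-hat transform
   `E = I + tophat(I) − bothat(I)` (disk radius 8 px), and the same chain
   runs at a 7 × 7 window. The final capillary mask excludes large-vessel
   pixels, so the branches partition caliber classes.

From the fused mask the package derives the skeleton (Lee thinning),
boundary map, FAZ (morphological closing + center component analysis, with
area, Crofton perimeter, circularity `4πA/P²`, moment-based ellipse axes,
orientation and eccentricity), non-perfusion regions, box-counting fractal
dimension, and densities/indices globally and in 1 mm / 2 mm circles
centered on the FAZ.

A synthetic phantom generator (`mrvs.phantom`) grows a branching vascular
tree with pixel-exact ground-truth masks under multiplicative gamma
speckle, so every stage is testable without clinical data. Test–retest
repeatability of any metric is summarized by Sw, CoV and one-way ICC(1,1).

## Worked example

```bash
mrvs phantom --seed 42 --out demo/            # synthetic angiogram + ground truth
mrvs segment demo/image.tiff --out demo/seg/  # fused/large/capillary/skeleton masks
mrvs metrics demo/image.tiff --out demo/metrics.csv
mrvs eval demo/seg/fused.png demo/gt_vessel.png --out demo/eval.json
```

The same analysis through the library:

```python
import mrvs

bundle = mrvs.generate_phantom(seed=42, speckle_shape=50.0)
seg = mrvs.MrvsSegmenter().fit(bundle.image)
report = mrvs.evaluate_masks(seg.fused_mask_, bundle.gt_vessel)
record = mrvs.quantify_all(bundle.image)
print(f"DSC vs ground truth: {report.dsc:.3f}")
print(f"vessel density:      {record.vessel_density:.3f}"
      f"  (ground truth {bundle.gt_vessel.mean():.3f})")
print(f"FAZ area:            {record.faz_area_mm2:.3f} mm^2")
```

prints

```
DSC vs ground truth: 0.950
vessel density:      0.241  (ground truth 0.267)
FAZ area:            0.156 mm^2
```

i.e. on a low-noise phantom the fused mask overlaps the true vasculature
with Dice 0.95, under-estimates vessel density by ~0.03 (dim capillary
pixels below the gray-clustering threshold), and recovers the FAZ area
within ~1 % of the stamped ellipse (π·0.25·0.20 ≈ 0.157 mm²).

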