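# roireg — regional registration of whole-slide image stacks

Serial histology sections can be stacked into a 3-D tissue volume only after
the slices are registered, and real slides carry severe artifacts — tears,
folds, missing tissue, stray stains — that derail whole-slide registration.
`roireg` takes the opposite approach: it registers only a **user-defined
region of interest** (ROI), typically a blood vessel, and is by construction
insensitive to artifacts elsewhere on the slide.  It is aimed at researchers
reconstructing microvasculature or other local structures from serial
brightfield/IHC whole-slide images (WSIs).

## Method

Three stages run per consecutive slice pair, all rigid
(rotation θ + translation (dx, dy), no scale or shear):

1. **Surrounding-artifact removal.**  Each slide `I_i` is converted to
   grayscale, Gaussian-smoothed (σ = 10 px), thresholded at its mean
   intensity, and morphologically opened/closed with a 20 px disc.  The
   contours that are large and central are kept, and everything outside
   their convex hull is replaced by the background median, giving the
   cleaned slide `Ĩ_i`.

2. **Rough whole-tissue alignment.**  Each cleaned slide is reduced to a
   piecewise-constant Mumford–Shah (Potts) segmentation `Ĩ_i^MS` — a
   denoised, stain-normalized image of a few constant phases.  The rigid
   transform is then found by *exhaustive* search over a (θ, dx, dy) grid:

       argmin_{θ,dx,dy}  Σ_{x,y} ( T_{θ,dx,dy}[Ĩ_{i+1}^MS](x,y) − Ĩ_i^MS(x,y) )²

   at a coarse pyramid level, producing the roughly aligned `I'_{i+1}`.

3. **Multi-scale attention ROI registration.**  The ROI box keeps a *fixed
   pixel size* across pyramid levels r = k … 0 while its center rescales as
   (x/2^r, y/2^r): at coarse levels the window covers most of the tissue
   (context), at level 0 only the structure of interest.  Per level, SIFT
   keypoints are detected inside the ROI of both images and matched on
   descriptors augmented with their spatial coordinates; the **8 strongest
   matches** yield C(8,3) = **56 candidate rigid transforms** (one per
   3-match combination, a rigid fit needing a minimum of 3 point pairs);
   the candidate with the least sum of squared ROI intensity differences
   `D` wins:

       F_r = argmin_{F_m} D_ROI( I'_i^r, F_m(I'_{i+1}^r) )

   The per-level transforms compose into `F* = F_0 F_1 … F_k`, applied at
   full resolution.  Accuracy is quantified as the Dice similarity
   coefficient of independently segmented vessel-lumen masks,
   `DSC = 2|A∩B| / (|A|+|B|)`.

Because no real clinical stacks ship with the package, a seeded phantom
generator (`roireg.generate_phantom`) renders textured tissue sections with
a drifting vessel, per-slice stain variation, known rigid mounting
perturbations, and optional injected artifacts — every number below is
computed on such stacks.

## Worked example

```bash
roireg simulate --out phantom --seed 7 --n-slices 10
roireg register-stack --input phantom/stack --roi phantom/roi.yaml \
    --levels 4 --seed 7 --out results
roireg evaluate --masks phantom/masks --transforms results --out report.csv
```

The last command prints

```
mean DSC 0.9717 ± 0.0053 over 9 pairs
```

meaning the warped lumen masks of consecutive registered slices overlap
with mean Dice 0.97 — versus 0.33 before registration on the same stack
(`roireg evaluate` with an identity transform file, or
`evaluate_stack(stack.lumen_masks)` in Python).  `results/` holds the
per-slice transform JSON, the resolved `config.yaml`, registered ROI crops
(`roi_crops.tif`) and a QC report with per-level match counts, candidate
counts and SSD values.  `roireg export-volume` stacks registered slices
into a multi-page TIFF for 3-D viewing.

The same pipeline is available as a library:

```python
from roireg import (PhantomConfig, PipelineConfig, generate_phantom,
                    register_stack, warp_mask_stack, evaluate_stack)

stack = generate_phantom(PhantomConfig(seed=7))
result = register_stack(stack.pyramids, stack.roi0, PipelineConfig(seed=7))
report = evaluate_stack(warp_mask_stack(stack.lumen_masks, result))
print(report.mean)   # 0.9717
```

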