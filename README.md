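# bendseg

Automated localization and segmentation of brain tumors in 2D
cross-sectional images (CT/MR slices), built from four cooperating stages:

1. **Bendlet transform** — a cone-adapted *second-order shearlet* system
   whose shear map `S_{s,b}(x1,x2) = (x1 + s·x2 + b·x2², x2)` adds a
   quadratic *bending* parameter `b` to the usual shear `s`.  Elements
   align with curved boundaries, and the band whose response survives
   across scales identifies the local edge geometry; the boundary
   curvature follows from the matched pair as

   `K = 2|b′| / (1 + s′²)^{3/2}`  (units 1/px).

2. **Bendlet-feature registration** — scale-stable response maxima are
   matched against the dense coefficient field of the second image
   (sub-pixel, with aperture-ambiguity rejection) and densified into a
   non-rigid warp by a regularized thin-plate spline.

3. **SSIM unit localization** — the registered pair is scanned with an
   overlapping sliding window (stride 50 px); each block pair is scored by
   the structural-similarity index

   `SSIM = [l]^α · [c]^β · [s]^γ`,
   `l = (2μxμy+C1)/(μx²+μy²+C1)`, `c = (2σxσy+C2)/(σx²+σy²+C2)`,
   `s = (σxy+C3)/(σxσy+C3)`,

   and the minimum-SSIM block is the tumor unit.

4. **Chan–Vese segmentation by Shannon-Cosine wavelet collocation** — the
   CV gradient flow
   `∂φ/∂t = δ_ε(φ)[μ div(∇φ/|∇φ|) − λ1(I−c1)² + λ2(I−c2)²]`,
   `δ_ε(φ) = ε/(π(ε²+φ²))`,
   is solved inside the located block on a dyadic collocation grid
   carrying an interval Shannon-Cosine interpolatory basis (windowed sinc
   with boundary correction); time stepping is a first-order homotopy
   (perturbation) expansion realized as a trapezoidal predictor–corrector.
   A plain finite-difference CV solver is kept as the reference oracle.

Masks are scored by Accuracy, Jaccard (JSC) and Dice (DSC),
`DSC = 2·JSC/(1+JSC)`, with a paired t-test for method comparison.

No clinical data ships with the package: a seeded phantom generator
produces brain-like cross-sections (skull rim, textured tissue,
ventricles, optional planted lesion, smooth mass-effect deformations with
known truth), so every stage is testable offline.

## Worked example

```python
from bendseg import (PhantomSpec, LesionSpec, DeformationSpec, make_phantom,
                     make_displacement_field, warp_image, segment_tumor,
                     confusion, metrics)

spec = PhantomSpec(seed=0,
                   lesion=LesionSpec(center=(150, 150), radius=12, contrast=0.2),
                   deformation=DeformationSpec(max_displacement=6.0))
normal, tumor, truth = make_phantom(spec)
field = make_displacement_field(spec.shape, spec.deformation, spec.seed + 7919,
                                center=spec.lesion.center)
observed = warp_image(tumor, field)                       # the "patient" image
truth_obs = warp_image(truth.astype(float), field) >= 0.5  # truth on that image

result = segment_tumor(normal, observed)
acc, jsc, dsc = metrics(confusion(result.mask, truth_obs))
print(f"tumor block: {result.bbox}, min SSIM {result.ssim_map.min_score:.4f}")
print(f"matches: {result.registration.n_matches}, "
      f"residual {result.registration.mean_residual:.2f} px")
print(f"accuracy {acc:.4f}  JSC {jsc:.4f}  DSC {dsc:.4f}")
```

prints

```
tumor block: (50, 50, 178, 178), min SSIM 0.9178
matches: 89, residual 0.39 px
accuracy 0.9993  JSC 0.8847  DSC 0.9388
```

The 128-px block at (50,50) is the most dissimilar unit between reference
and patient image; 89 feature matches left a mean residual displacement of
0.39 px after the thin-plate-spline warp; the segmented mask overlaps the
planted lesion with Dice 0.94.

A command-line interface mirrors the stages:

```sh
bendseg phantom --seed 7 --lesion 128,110,12,0.2 --out-dir fx/
bendseg locate --normal fx/normal.png --tumor fx/tumor.png --out bbox.json
bendseg segment --image fx/tumor.png --bbox bbox.json --out mask.png
bendseg evaluate --pred mask.png --truth fx/truth.png --out report.json
```

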