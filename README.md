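# druscan

Automated segmentation of **drusen** — the small bright sub-retinal
deposits that mark early age-related macular degeneration — in color
fundus photographs, with a synthetic-phantom test bed and a two-level
evaluation battery.

The pipeline combines four classical ingredients:

1. **Optic-disc detection & macular ROI** — the disc is the largest
   8-connected component brighter than 200 in the green channel; the ROI
   is the circle centered midway between the disc centroid and the
   opposite image edge (the geometric fovea estimate), with radius equal
   to that fovea–disc distance.
2. **Dual-scale median difference** — `median₅(I) − median₃₀(I)`,
   clamped at 0 and min–max stretched: structures smaller than the large
   window survive, background and illumination cancel, impulse noise is
   removed by the small window.
3. **Rényi-entropy thresholding** — for each order α, the cut t(α)
   maximizes the summed class entropies
   `H^α_{A1}(t) + H^α_{A2}(t)`, with
   `H^α_{A1}(t) = (1/(1−α)) ln Σ_{i≤t}(P_i/P_{A1})^α`.
   Components for α = 0.5, α → 1 (Shannon / maximum-entropy-sum) and
   α = 2 (entropic correlation) are sorted into t[1] ≤ t[2] ≤ t[3] and
   blended into
   `t_c = t[1](P(t[1]) + ¼ωβ₁) + ¼ t[2]ωβ₂ + t[3](1 − P(t[3]) + ¼ωβ₃)`
   with ω = P(t[3]) − P(t[1]) and gap-dependent weights
   (β₁,β₂,β₃) ∈ {(1,2,1), (0,1,3), (3,1,0)}.
4. **Vessel removal** — region growing seeded at the darkest pixels in an
   annulus around the disc (vessels are the darkest structures leaving
   it); the dilated vessel ∪ disc mask is subtracted from the thresholded
   candidates.

Clinical fundus data is not redistributable, so the package ships a
seeded phantom generator (`druscan.phantom`) producing disc, vessels,
drusen, illumination gradient and salt noise with exact ground-truth
masks, plus an evaluation module with pixel- and lesion-level confusion
metrics (sensitivity, specificity, accuracy, DSC), Pearson r, ICC(2,1)
and Bland–Altman limits for paired area measurements.

## Worked example

```python
import druscan as d

# a high-contrast phantom: 10 drusen, flat illumination, seed 42
bundle = d.generate_phantom(
    d.PhantomSpec(seed=42, drusen_contrast=60, gradient_amplitude=0)
)
res = d.segment_drusen(bundle.image)
print("disc centroid:", res.disc.centroid, "side:", res.disc.side)
print("ROI:", res.roi)
print("thresholds:", res.threshold.components, "->", res.threshold.t_c)
print("drusen area:", res.drusen_area, "px")

roi = d.roi_mask(res.roi, 768, 512)
pix = d.conditional_probabilities(
    d.confusion_pixelwise(res.drusen_mask, bundle.drusen_mask, roi))
reg = d.conditional_probabilities(
    d.confusion_regionwise(res.drusen_mask, bundle.drusen_mask, roi))
print(f"pixel:  sens {pix.sensitivity:.2f}%  spec {pix.specificity:.2f}%  "
      f"acc {pix.accuracy:.2f}%  DSC {pix.dsc:.2f}")
print(f"region: sens {reg.sensitivity:.2f}%  DSC {reg.dsc:.2f}")
```

prints

```
disc centroid: (302, 124) side: left
ROI: RoiCircle(center=(302, 445), radius=321.0)
thresholds: (0, 0, 14) -> 0
drusen area: 609 px
pixel:  sens 100.00%  spec 99.94%  acc 99.94%  DSC 0.83
region: sens 100.00%  DSC 1.00
```

All ten planted drusen are recovered (region sensitivity 100%); the
pixel DSC of 0.83 reflects the soft 1-px rim around each druse that the
threshold partially admits. The component thresholds (0, 0, 14) on the
stretched difference image combine to t_c = 0 — everything strictly
brighter than the (overwhelmingly zero) background is a candidate, and
the vessel/disc exclusion plus the minimum-area filter remove the rest.

The same pipeline is available from the shell:

```sh
druscan phantom --seed 42 --difficulty easy --out phantom/
druscan segment phantom/image.png --out-mask drusen.png --sidecar result.json
druscan eval drusen.png phantom/drusen_mask.png --roi-from result.json
```

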