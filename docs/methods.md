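# Methods

## Problem and overall model

Drusen — small bright extracellular deposits visible in color fundus
photographs — are the hallmark of early age-related macular degeneration,
and their quantitative measurement is tedious to do by hand. `druscan`
segments them automatically under three structural assumptions about a
fundus image:

1. the optic disc is the brightest structure (green-channel intensity
   above ~200 in 8-bit data);
2. drusen are *small* bright spots (a few to ~15 px at the working
   resolution), smaller than any other bright anatomy;
3. vessels are the darkest structures and form a connected tree rooted at
   the disc.

The pipeline is: green channel → disc detection (threshold > 200, largest
8-connected component) → macular ROI (circle centered midway between the
disc centroid and the opposite image edge, radius equal to that half
distance, i.e. the estimated fovea–disc distance) → dual-scale median
difference image → min–max histogram stretch → Rényi-entropy threshold on
the ROI histogram → removal of the dilated vessel/disc mask → minimum-area
filter.

## Scale selection by median difference

A k×k median filter erases any structure whose support covers fewer than
half the window pixels. The difference

    subtract = clamp( median₅(I) − median₃₀(I), 0, 255 )

therefore keeps bright blobs between roughly the two window scales: the
5×5 filter removes impulse noise but not drusen, the 30×30 filter removes
drusen (and noise) but keeps the background and illumination field, which
cancel in the subtraction. A bright disk of diameter d yields a positive
center response iff it survives the small window but not the large one;
with the soft-edged drusen rendering used here that holds down to d = 3
(the 1-px intensity taper lifts the small-window median above background)
and fails at d = 40, as the tests verify. Dark structures (vessels)
produce negative residuals and clamp to zero.

Even window sizes need a convention: the output pixel is anchored at
offset (s/2−1, s/2−1) inside the window and the *lower* median (the
(n/2)-th smallest of n values) is taken. Borders use replicate padding.
The filter is computed with a sliding-histogram rank filter, which is
exact for 8-bit data; the even case reduces to the odd-style centered
filter through the identity
`lower_median(I) = 255 − upper_median(255 − I)` under a 180° flip.

## Rényi-entropy thresholding

For the 256-bin ROI histogram P₀…P₂₅₅ and cut t, classes A1 = {0..t} and
A2 = {t+1..255} have Rényi entropies

    H^α_{A1}(t) = (1/(1−α)) ln Σ_{i≤t} (P_i / P_{A1})^α ,

and symmetrically for A2. Each order α yields a component threshold
t(α) = argmax_t H^α_{A1}(t) + H^α_{A2}(t); cuts that leave a class empty
are excluded, ties take the smallest t. Three components are computed:
α = 0.5 (sub-unity order), the Shannon limit α → 1 (the classic
maximum-entropy-sum criterion, computed directly rather than as a
numerical limit), and α = 2 (entropic correlation). Sorted ascending into
t[1] ≤ t[2] ≤ t[3], they blend into

    t_c = t[1]·(P(t[1]) + ¼ω β₁) + ¼ t[2] ω β₂ + t[3]·(1 − P(t[3]) + ¼ω β₃)

with P(t) the cumulative mass through t, ω = P(t[3]) − P(t[1]), and the
weights (β₁,β₂,β₃) chosen by the gaps between components: (1,2,1) when
the two gaps are both ≤ 5 or both > 5, (0,1,3) when only the second gap
exceeds 5, (3,1,0) when only the first does. t_c rounds half-up to an
integer gray level; foreground is every ROI pixel strictly brighter than
t_c. When all three components agree the formula collapses to t_c = t
exactly. An Otsu and a plain maximum-entropy threshold are available as
baselines (`threshold_method="otsu" | "max_entropy"`).

Numerical choices: histograms are normalized on entry (so thresholds are
invariant to scaling counts); the α-order sums are evaluated through
cumulative sums in log form; P_{A1} = 0 or P_{A2} = 0 cuts are assigned
−∞ in the argmax. The two α defaults (0.5 and 2) are exposed as
`renyi.alpha_low` / `renyi.alpha_high`.

## ROI geometry and mirror symmetry

The ROI midpoint rounds half-pixels *toward the disc* (floor for a
left-side disc, ceil for a right-side one). This makes the construction
exactly equivariant under horizontal mirroring, which the pipeline
otherwise preserves stage by stage; a plain floor would displace the
mirrored ROI by one column whenever the centroid-to-edge span is odd.

One asymmetry remains by construction: an even median window cannot be
centered, so the 30×30 default is anchored one pixel off-center. Under a
flat background this is invisible and the full pipeline is exactly
mirror-equivariant; under a strong illumination gradient the anchoring can
shift isolated difference-image values by one gray level and perturb a few
boundary pixels. With odd windows (e.g. 31) equivariance is exact in all
conditions. The symmetry tests exercise both regimes.

## Vessel removal

Seeds are sought in the annulus (r_disc, 2·r_disc] around the disc
centroid (r_disc = √(area/π)), where every vessel must cross. The annulus
is split into 8 angular sectors; in each sector *all* pixels attaining the
sector's minimum intensity become seeds — taking the full minimum set
avoids an arbitrary tie-break and keeps the procedure
reflection-equivariant. A sector is used only when its minimum is at least
`tolerance` darker than the image median (a brighter minimum means no
vessel crosses that sector). Each seed grows by seed-fixed similarity:
pixel p joins iff |I(p) − I(seed)| ≤ tolerance (default 15), 8-connected;
the region is the seed's connected component of that similarity set,
computed by geodesic binary propagation. A region exceeding
`max_region_fraction` (default 0.25) of the image is a background match
and is discarded (the standalone `region_grow` raises instead, flagging a
tolerance too lax). The union of grown regions and the disc mask, dilated
by a Chebyshev ball of radius 2, is subtracted from the thresholded
candidates; a final 8-connected component filter drops blobs under
`min_drusen_area` (default 4 px; set 0 to disable).

## Phantom generator

Phantoms emulate the structures the pipeline depends on, at half clinical
scale (768×512, keeping the default test suite fast; all parameters admit
full-size 1536×1024 use): background 120 with a linear illumination ramp
of seeded orientation; an anti-aliased disc of radius 40 at intensity 230
placed at 12–18% of the width from a seeded side; six vessels grown as
angle-jittered random walks (step 2 px, angular σ 0.12) stamped 3 px wide
at intensity 40 with ±5 jitter; ten drusen with diameters uniform in
4–14 px and a 1-px linear edge taper, placed uniformly in a disk around
the geometric fovea estimate and clamped to the macular half, pairwise
separated and clear of vessels and disc; salt-only impulse noise at
density 10⁻³. Red/blue planes are scaled copies of green. Ground-truth
masks record the exact planted pixels (drusen mask = taper weight ≥ 0.5),
and all randomness derives from a single seed.

Difficulty presets fix the study conditions: easy = contrast +60, no
gradient; medium = +40, gradient 20; hard = +20, gradient 40, salt 3·10⁻³.
The end-to-end recovery checks run on the easy suite; the hard preset is
deliberately at the failure edge (low-contrast drusen against a strong
gradient), mirroring the known difficulty of soft drusen with ambiguous
boundaries.

What the phantoms do *not* model: textured retinal background, vessel
branching statistics and central reflexes, bright disc rim reflections,
soft/confluent drusen shapes, and camera vignetting. Passing the phantom
suite therefore demonstrates the algorithmic contracts (scale selectivity,
threshold optimality, geometric recovery), not clinical-grade accuracy.

## Evaluation battery

Pixel-level confusion counts are taken over the ROI only and partition it
(tp+fp+tn+fn = |ROI|). Region-level counts compare 8-connected lesions: a
true lesion touched by ≥ 1 predicted pixel (configurable minimum overlap
fraction) is a TP, untouched ones FN, predicted components touching
nothing FP; TN is undefined at region level, so specificity and accuracy
are only reported pixel-wise. Derived rates: sensitivity = 100·tp/(tp+fn),
specificity = 100·tn/(tn+fp), accuracy = 100·(tp+tn)/total,
DSC = 2tp/(2tp+fp+fn). Undefined metrics (zero denominators) are reported
as missing, never as 0.

Area agreement between paired manual/automatic measurements uses Pearson
r, the two-way random-effects absolute-agreement single-measures
ICC(2,1) with 95% CI, and Bland–Altman limits (mean difference ±
1.96 SD, differences taken automatic − manual). On phantoms the automatic
areas carry a small systematic positive bias — the threshold admits part
of each druse's soft rim — so r stays near 1 while the
absolute-agreement ICC is noticeably lower (~0.8); this is a property of
the phantom's soft-edge rendering, not a numerical artifact.

## Known limitations

* The disc detector assumes an over-200 bright disc; over/under-exposed
  images raise `NoOpticDiscError` rather than guessing.
* Seed-fixed region growing is not robust to strong intensity drift along
  a vessel; a mean-adaptive criterion would be, but changes the oracle
  semantics.
* The even-window median anchoring breaks exact mirror symmetry under
  illumination gradients (see above).
* Region-level matching counts any-overlap by default; a single merged
  prediction spanning two lesions counts both as detected.
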