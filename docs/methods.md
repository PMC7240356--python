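# Methods

This note records the modelling and numerical choices behind the toolkit:
what each component computes, the parameters that matter, what the phantom
world does and does not emulate, and the places where the design was
genuinely open and a convention had to be fixed.

## Image and patch model

Images are flat 8-bit RGB rasters; pyramidal WSI containers are out of
scope. Coordinates are 0-based (row, col), top-left origin, half-open
extents. Patchify tiles a slide with square patches of size `patch_size`
(canonically 1024 px; 64 px for desk-scale work) at stride ≤ patch_size; the
slide is reflect-padded on the bottom and right so the grid covers it
exactly, and the padding is recorded on the grid and cropped away on
stitching. Images smaller than one patch are reflect-padded up rather than
rejected, which keeps small fixtures usable. The default stride equals the
patch size (non-overlapping tiling); where patches overlap, stitching takes
the unweighted mean of contributors, rounded half away from zero — the
simplest seam-reduction rule and one that is exactly testable. With
non-overlapping tiling the patchify→stitch round trip is bit-exact.

## The translation GAN

A U-Net generator with skip connections: a stem convolution, `depth`
encoder levels (2× average pooling between levels), a bottleneck, `depth`
decoder levels (2× nearest-neighbour upsampling, skip concatenation), and a
tanh output head. All convolutions are stride-1 "same" 3×3. The tracked
layer inventory — the layers whose activations the explainability tooling
captures — is the generator's convolutions in forward order; with the
canonical depth 4 and two convolutions per level this counts
2·4·2 + 3 = 19 layers. Shallower desk-scale models (depth 2, one
convolution per level, 8 base channels) track 7. Which internal layers of a
pix2pix generator one should count is a convention; ours is declared here
and is configurable.

The discriminator is a conditional patch discriminator over the stacked
(input, candidate) 6-channel image, emitting a logits grid; its loss is
binary cross-entropy on logits.

The generator objective is

L_G = λ_adv·L_cGAN + λ_L1·L1 + λ_PCC·(1 − PCC),

defaults λ_adv = 1, λ_L1 = 100 (the customary pix2pix weighting),
λ_PCC = 10. The exact published form and weight of the PCC term were not
available, so this is a declared reconstruction, kept configurable so that
λ_PCC = 0 reproduces the plain pix2pix objective exactly (asserted to
machine precision in the tests). PCC in the loss is computed over all
pixels and channels of each image jointly, then averaged over the batch —
the simplest differentiable reading — with a per-channel variant behind
`LossConfig.per_channel_pcc`. A zero-variance image is assigned correlation
0 (loss contribution 1) and logged rather than produced silently.

Pixels are normalised to [−1, 1] inside the model; conversion back to 8-bit
rounds half away from zero. Staining and destaining are two independently
trained models (whether the original system was bidirectional is not
stated; independence is the simpler assumption and lets each direction be
ablated alone). All randomness — initialisation, shuffling — flows from the
single `TrainingConfig.seed`, making training deterministic on one machine;
checkpoints (weights + configs in one `.npz`) reload to bit-identical
inference.

The network substrate is a small reverse-mode autodiff on NumPy arrays
(im2col convolution, 2× pooling/upsampling, the elementwise ops the losses
need, Adam with β₁ = 0.5). Its gradients are verified against central
finite differences in the test suite.

Optimiser defaults: Adam, learning rate 2×10⁻³ for both networks, batch 8.
These are desk-scale settings chosen for the 64 px phantom problem, where
training converges in ~6 epochs on 200 pairs (≈40 s on one CPU).

## Quality metrics

PCC is the Pearson correlation of the two images' jointly flattened pixel
vectors; a constant image makes it undefined and raises rather than
returning 0. PSNR is 10·log₁₀(255²/MSE), +∞ for identical images. SSIM uses
the canonical parameterisation (11×11 Gaussian window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, dynamic range 255, population covariance), computed per channel
and averaged; the implementation delegates to scikit-image and is checked
against a direct windowed-formula oracle to 1×10⁻⁶. Although PCC and SSIM
are often described as ranging over [0, 1], both can be negative; the true
signed value is returned and reporting decides what to clamp or flag.

Intensity deltas are mean(first) − mean(second), per channel and overall —
an audit of whether generated renders reproduce the global brightness shift
dye staining causes (red and blue drop strongly; green barely moves).

Summaries use the arithmetic mean and the sample SD (n−1), which reproduces
the published totals; a single row reports SD 0 and is flagged by n = 1.
Table-style rounding is PCC/SSIM to 1 decimal on the ×100 scale and PSNR to
3 decimals. Two bundled per-slide tables carry the published values for the
13 evaluation slides. Two cells of the published summary row do not follow
from their printed columns: the destained-PSNR total (printed 25.646; the
column averages to 25.030) is excluded as a probable typo, and the overall
any-tumor IoU (printed 0.79; the column averages to 0.798) is asserted only
to within one unit in its last printed digit — it was plausibly pooled over
pixels rather than averaged over images, which per-image data cannot
reproduce.

## Annotations and agreement

The annotation dialect is a minimal session XML — polygon `graphic`
elements with a `pen` colour and an `x,y` point list — modelled on the kind
of file slide-viewer annotation tools emit; the pen-colour → grade mapping
is configuration with a documented default. Rasterization uses even-odd
fill with half-open pixel-centre containment (a pixel belongs to a region
when its centre is inside), so an axis-aligned square of side s covers
exactly s² pixels; this rule is hand-rolled because library polygon fills
include boundary pixels and would break that exactness. Overlapping grades
resolve by severity (G5 > G4 > G3 > benign); degenerate polygons are
skipped with a warning.

IoU for a class is |A∩B|/|A∪B| over that class's pixel sets, NA when the
union is empty. "Any tumor" is the grade-agnostic union of G3/G4/G5 (this
choice reproduces the published column). "Healthy" defaults to explicitly
annotated benign outlines, with a complement-of-tumor mode (optionally
restricted to a tissue mask) behind `healthy_mode="complement"` — the
published definition is not stated, so both are exposed. Aggregation
excludes NA entries, reports n per class, uses the sample SD with SD 0 for
a single value, and rounds to 2 decimals.

Error overlays colour true positives green, false negatives blue and false
positives red, alpha-blended over the base image at a configurable opacity.

## Synthetic phantoms

A phantom is procedural geometry with an exact per-pixel class map over
{background, stroma, gland epithelium, lumen, nucleus}: elliptical glands
with epithelial rims and lumens, disk nuclei on the rims and scattered in
stroma, a background margin. Grade architecture follows Gleason intuition:
G3 draws disjoint glands (so the connected-component count equals the gland
count), G4 fuses several ellipses into cribriform clusters with multiple
lumens per mass, G5 draws lumenless sheets densely packed with nuclei, and
benign tissue gets large glands with sparse nuclei. Ground-truth outlines
(one polygon per gland/cluster, labelled with its grade, or `benign`) are
carried alongside the mask.

The stained render maps each class to an H&E-hue colour (nuclei
blue-purple, stroma/epithelium pink, lumens near-white); the nonstained
render is a dim gray-green. The palette is constructed so the nonstained
image is darker on the red and blue channels while green barely moves —
the direction of the measured intensity shift of real staining (its
magnitudes are not calibrated to tissue). Additive Gaussian noise
(sd 3 by default, 0 for analytic work) is the only stochasticity in a
render. Because the stain relationship is a deterministic per-class colour
map, the analytic render is an exact target: a perfect translator would hit
it, and metric values against it have analytic references.

Simulated raters trace each mask region's exact pixel-boundary polygon (the
outline of the union of its pixel squares, computed with shapely, so
rasterizing it reproduces the region exactly — interior holes are not
traced), optionally dilate it uniformly with square corners (a side-s
square becomes side s + 2r, giving the closed-form IoU s²/(s+2r)²), jitter
every vertex with zero-mean Gaussian noise, and drop each region with a
fixed probability. All of it is a pure function of (mask, seed,
parameters).

What the phantom world does **not** emulate: photorealistic texture,
scanner optics, focus variation, staining-protocol variability, or
registration error (pairs are born registered — the published pipeline's
registration step has no counterpart here). Passing the recovery study
therefore shows the translation machinery, losses and benchmarking work as
specified; it does not certify performance on real tissue.

## Activation maps

Capture records each tracked layer's post-activation maps for one input.
The "consolidated" map is the per-pixel channel mean, min-max scaled to
[0, 255] (channel max available as an option); the published consolidation
operator was not specified, so this is a declared reconstruction, and the
scaling is what makes the >200 "hot channel" threshold meaningful. Channel
ranking scales a layer's maps jointly, sorts by mean scaled activation
descending with ties broken by ascending channel index, and flags channels
whose scaled maximum exceeds the threshold. Montages are near-square,
row-major, with 1-px separators. The layer NMSE profile divides the MSE
between consolidated maps by 255²; between cohorts it is averaged over
matched pairs. The shape of the profile across layers is reported as a
diagnostic (plotted and tabulated by the pipeline), not asserted as a hard
test.

## Experiments and problem sizes

The recovery study trains both directions on ~200 noise-free 64 px phantom
pairs for 6 epochs (depth-2 generator, 8 base channels) and evaluates on 20
held-out phantoms per seed, 3 seeds, reporting medians; these sizes were
chosen so the full study runs in a few minutes on one CPU while leaving a
wide margin over its SSIM ≥ 0.7 / PCC ≥ 0.8 pass bands. The round-trip
check destain(stain(x)) vs x is compared against the cross-stain baseline
PCC(stained, x) on the same held-out phantoms. The rater-jitter curve uses
one 128 px G3 phantom and 20 simulated raters per radius. The end-to-end
determinism check runs the bundled pipeline twice at one seed (12 training
pairs, 1 epoch) and compares all CSV tables byte for byte.

## Known limitations

- The NumPy network substrate is single-threaded BLAS-bound and desk-scale
  by design; it is not a route to training on ~87 000 real 1024 px patch
  pairs.
- The PCC-loss form, generator layer inventory, activation consolidation
  and NMSE normalisation are declared reconstructions of under-specified
  published choices; each is configurable where a reasonable alternative
  exists.
- Phantom realism is deliberately minimal (exactness over fidelity); all
  claims about real tissue remain with the published study.
- The even-odd rasterizer is O(vertices × bounding-box pixels) per region —
  fine for annotation-scale polygons, not for million-vertex outlines.
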