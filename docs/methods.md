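# Methods

`staincycle` implements a weakly supervised virtual-staining pipeline: given
unpaired hematoxylin–eosin (HE) and Ki-67 immunohistochemistry microscopy
images, it learns to translate HE images into synthetic Ki-67 images whose
clinically relevant statistic — the fraction of Ki-67-positive cells — tracks
the real stain. This note documents the models, the synthetic world the
package is validated on, and the numerical choices.

## Pipeline

1. **Preprocessing.** Tissue foreground is separated from the bright slide
   background by Otsu's threshold on the 256-bin grayscale histogram
   (Rec. 601 luma weights 0.299/0.587/0.114; tissue is the *darker* class).
   Images are cut at two scales: large patches (default 2240 px) on a
   non-overlapping grid, each carrying one weak tumour/normal label, and
   small patches (default 224 px, a 10×10 grid per large patch). Border
   remainders are dropped, never padded. Large patches are retained when at
   least `min_fg_fraction` (default 0.05) of their pixels are foreground.
   For GAN training the *whole* image is tiled, background included, because
   the generator must synthesize background too.

2. **Multiple-instance learning (MIL).** One binary tumour/normal small-patch
   classifier is trained per domain from bag-level labels only. Each
   iteration: (a) *evaluation* — the current classifier scores every
   instance of every bag with its tumour-class probability and the top
   instance per bag inherits the bag's weak label (argmax ties break to the
   lowest index); (b) *training* — cross-entropy/Adam epochs on the selected
   instances. Scoring NORMAL bags by the same tumour probability makes their
   selected instances the hardest negatives, the standard max-instance MIL
   reading. Bag-level validation accuracy (bag called tumour iff its max
   instance probability ≥ 0.5) selects the best iteration. The classifier is
   fine-tuned across iterations rather than re-initialized (a `restart`
   switch exposes the alternative). The desk-scale backbone is a small CNN
   (three stride-2 conv/ReLU blocks, 16/32/64 channels, global average pool,
   linear head). A ResNet34 backbone identifier exists for fidelity to
   GPU-scale practice but is unavailable here: no deep-learning framework is
   installed, and all networks run on a hand-written numpy layer library.

3. **Class-conditioned CycleGAN.** Two generators and two discriminators
   with a fixed topology: the generator is a 7×7 stem → two stride-2
   downsampling convs → two plain 3×3 bottleneck convs at 256 channels (the
   second ends at its InstanceNorm with no activation; it is deliberately
   *not* a residual block — a `residual` flag exposes that variant) → two
   stride-2 transposed convs → 7×7 head → Tanh, with InstanceNorm (no affine
   parameters) throughout. The discriminator is a 7×7 stem + three stride-2
   convs (LeakyReLU 0.2), a k=4 conv to one channel, and a global average
   pool to a scalar. At width multiplier 1.0 the parameter counts are
   1,936,899 (generator, 3-channel input), 1,940,035 (4-channel conditioned
   input) and 1,566,849 (discriminator); these integers are asserted in the
   tests against a hand computation. A width multiplier scales hidden
   channels for CPU-scale runs.

   Conditioning: each real patch is labelled by its domain's MIL classifier
   and the label is appended to the generator input as a constant plane
   (+1 tumour, −1 normal, matching the x/127.5−1 pixel normalization). The
   fake patch re-entering the reverse generator carries the *same* label as
   its source patch — the true class is known there, and re-classifying a
   half-trained fake would only add noise. Discriminators see plain
   3-channel images; conditioning the discriminator is classic conditional-
   GAN practice but is not part of this design.

   Losses: binary cross-entropy for the discriminators (real→1, fake→0,
   sigmoid applied to the raw score), least-squares `mean((s−1)²)` for the
   generator's adversarial term — an asymmetric objective kept exactly as
   specified, with a `symmetric_lsgan` switch for the conventional LSGAN —
   plus an L1 cycle-consistency term with weight λ_cyc = 10 (the canonical
   value; an L2 option exists). Optimizer: Adam, β = (0.5, 0.999), default
   learning rate 1e-4 over 100 epochs. No identity loss, no replay buffer,
   no LR decay. Each step draws the HE and Ki-67 batches from *independent*
   reshuffled index streams, so the networks never see aligned pairs even
   when the synthetic data are pixel-aligned; the streams are logged and
   asserted in tests. Per-epoch checkpoints are ranked by mean cycle loss on
   a held-out validation split — the only quantitative unsupervised
   criterion available.

4. **Quantification.** The positivity ratio (positive cells / all cells) is
   computed by a deterministic colour rule: a nucleus pixel has HSV
   saturation ≥ 0.15 and value < 0.85 (excluding background and desaturated
   tissue); 8-connected components with area ≥ 9 px are cells; a cell is
   positive iff its mean R−B exceeds 20 (8-bit scale, brown DAB chromogen vs
   blue counterstain). Touching-cell splitting (watershed) is not attempted;
   the synthetic renderer guarantees separation. All four thresholds live in
   `QuantifyConfig`.

## The synthetic world

The generator stands in for clinical slides, which are not distributable.
Each slide pair idealizes two consecutive sections as *pixel-aligned* images
sharing cell geometry and texture noise, differing only in colour mapping:

* background ≥ 240 in all channels; tissue a desaturated field
  (HE ≈ (170,150,158), Ki-67 ≈ (168,158,150)) with ±8 of luminance noise
  applied as a *common* offset to all channels, which preserves R−B and hue —
  the invariants the counting rules need;
* nuclei are filled ellipses (eccentricity 0.75–1.0, random orientation)
  with radius-aware minimum clearance r_i + r_j + 3 px, so connected
  components count cells exactly;
* HE renders every nucleus hematoxylin purple (91,42,134); Ki-67 renders
  positive nuclei DAB brown (139,69,19, R−B = +120) and all others
  counterstain blue (43,75,140, R−B = −97);
* the tumour region is one smoothed-noise blob covering
  `tumor_region_fraction` of the tissue; cells inside it are tumour cells;
* positivity is drawn per tumour cell as Bernoulli(`positive_fraction`) —
  so cohort ratios fluctuate binomially, as real cohorts do — and positive
  cells are rendered with a strictly larger nucleus radius band
  (normal (2,3) < tumour-negative (3.2,4.6) < positive (5.6,7) px at the
  defaults). Ki-67-positive (proliferating) nuclei being the largest is the
  biologically motivated ordering, and it makes positivity a function of
  HE-visible morphology: without such a correlate, no translator could
  recover the positivity ratio from an HE image even in principle.

What the world does **not** emulate: realistic chromatin texture, stain
variability, overlapping nuclei, out-of-focus regions, section-to-section
deformation (an elastic-jitter option was considered and left off), and
pyramid whole-slide formats. A green end-to-end test therefore establishes
that the algorithms are implemented correctly and that the pipeline recovers
a morphology-encoded class signal — not that it would survive real-stain
variability.

## Desk-scale settings

The reference scales (2240/224 patches, ResNet34, 100 epochs at 224²) assume
GPU hardware. Tests run the same geometry at 320/32 (preserving the 10×10
instance grid) with the small CNN, and GAN width multiplier 0.25 at 32² —
the toy scale. At the toy scale the default learning rate 1e-4 is
needlessly conservative (it is tuned to large nets and long schedules), so
the end-to-end toy runs use Adam at 1e-3 for both MIL and GAN; this is a
scale adaptation chosen once, not a tuned quantity.

The default adversarial objective (BCE discriminator on raw scores, MSE-to-1
generator) is unstable in short CPU-scale runs: the discriminator's raw
scores are unbounded, and the generator's adversarial per-pixel gradient was
measured at ~70× the (×10) L1 cycle gradient, so the generator either chases
discriminator noise or, with the adversarial term effectively dominant,
settles into flat-colour equilibria that InstanceNorm makes attractive. The
end-to-end toy runs therefore switch on three stabilizers that the config
exposes as flags while the defaults stay faithful to the reference
configuration: `symmetric_lsgan` (MSE on both sides keeps scores bounded
near the 0/1 targets), `identity_weight = 5` (the canonical CycleGAN
identity term `||G_A→B(b) − b||₁`, which supplies dense per-pixel palette
supervision using only same-domain images — the data stay unpaired), and
`adv_weight = 0.2` (rebalances the adversarial gradient against the L1
terms). Under-weighting the adversarial term leaves negative nuclei at an
uncommitted dark gray (the "brown-first" phase); over-weighting it drives
all nuclei to the majority counterstain blue ("blue-first"); 0.2 at batch 8
holds both colours. Translation stitches non-overlapping tiles; nuclei
straddling tile borders are translated from partial evidence, which is the
dominant remaining error source in toy-scale ratio recovery.

## Numerical choices

* All network arithmetic is float32; losses are accumulated in float64.
* Gradients are computed layer-analytically (no autodiff); every layer's
  backward pass is verified against central finite differences at 1e-6.
* Forward caches form a stack, so a generator can run twice per step (translate
  + reconstruct) with backward passes arriving in LIFO order.
* Otsu on a constant image (no variance to split) returns an all-background
  mask with a warning rather than failing.
* `detect_nuclei` on an image with no detected cells reports an undefined
  ratio (`None`) rather than 0, and comparisons propagate the flag.
* Weight init: N(0, 0.02) for GAN networks (DCGAN convention), He-normal for
  the classifier. All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical seed + config is bit-reproducible.

## Known limitations

* Toy-scale GAN quality is seed-sensitive: with the stabilized recipe the
  translated-image positivity ratio tracked ground truth to within 0.09
  (mean absolute difference over three held-out slides) on the fixed-seed
  test world, but other seeds can land at roughly twice that error after the
  same 800 steps. Longer schedules reduce the variance; the desk-scale runs
  are demonstrations of the mechanism, not converged models.

* No watershed splitting: the counter undercounts touching nuclei on real
  slides; it is exact only under the renderer's separation guarantee.
* The asymmetric BCE/MSE objective is kept for fidelity; the symmetric LSGAN
  flag is usually the more stable choice at tiny batch sizes.
* ResNet34 backbone unavailable (no deep-learning framework in the
  environment); the small CNN is the only trained backbone.
* Tile-seam artifacts in translation are not blended; overlap-stride
  inference is out of scope.
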