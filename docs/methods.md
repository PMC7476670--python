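# Methods

## Model and assumptions

The pipeline predicts one binary molecular label per slide (positive /
negative nBAP1 expression in the motivating uveal-melanoma setting) from an
H&E image and a binary tumor mask. Two assumptions carry the whole design:

* **Weak-label validity.** The label is a slide-level property: every tumor
  patch of a slide is assigned the slide's label for training, and the slide
  posterior is recovered as the arithmetic mean of patch posteriors. This is
  exact when expression status is unified within a slide and approximate
  otherwise.
* **Region correlation.** Neighboring tumor patches are more likely to share
  class status than distant ones. The second stage operationalizes this
  prior: per-patch CNN feature vectors are re-assembled into a per-slide
  grid (the *global feature map*) and refined by an encoder-decoder whose
  receptive field spans several grid cells, so a cell's posterior can borrow
  strength from its neighborhood.

Stage one is an 18-layer residual CNN (4 stages × 2 basic blocks, additive
identity shortcuts, batch normalization, 2-class softmax head); the
per-patch feature is the global-average-pooled activation of the last
residual stage (512-d at full width). Stage two is a U-Net: `depth`
encoder/decoder levels with skip concatenations, one logit per grid cell,
logistic output multiplied element-wise by the tumor-cell mask so that
off-tumor cells are exactly zero. The two stages are trained sequentially;
the feature extractor is frozen during region training (features are
precomputed), and end-to-end fine-tuning is out of scope.

### Losses

Patch stage: class-weighted cross-entropy with inverse-frequency weights
w_pos = N/(2 n_pos), w_neg = N/(2 n_neg), normalized so the mean
per-example weight is 1 — any positive rescaling satisfies the
inverse-ratio requirement; mean-1 keeps loss magnitudes comparable across
imbalance levels. With these weights, each class contributes equally to the
expected loss of a predictor that outputs the prior.

Region stage: binary cross-entropy on the logit map, gated to tumor cells
(off-mask cells contribute exactly zero to value and gradient; an all-zero
mask yields loss 0 and the slide is skipped), with the slide's class weight
applied per step. Class weights are recomputed from training tumor-cell
counts rather than reusing the patch-level weights. A single-logistic
output with weighted binary cross-entropy is used; for a binary label this
is mathematically equivalent to a two-class weighted softmax.

## Reference training configuration

| parameter | value |
|---|---|
| optimizer | SGD, momentum 0.9, weight decay 5·10⁻⁴ (both stages) |
| patch stage | 30 epochs, lr 10⁻³ divided by 5 at epochs 10 and 20 |
| region stage | 100 epochs, constant lr 10⁻⁴ |
| patch transforms | random 224² crop from 256², independent H/V flips (p = 0.5 each), color jitter 0.6–1.4 |
| evaluation transform | deterministic center 224² crop |
| checkpoint | best validation AUC |
| folds | K = 5, stratified at slide level |

Color jitter draws multiplicative brightness/contrast/saturation factors
uniformly from [0.6, 1.4]. Hue is an angle, so the multiplicative range
cannot apply directly; the hue shift is additive, drawn from the same
centered range scaled by 0.1 of the hue circle
(shift ~ U(−0.4, 0.4) · 0.1). The order of the four color sub-operations is
randomized per call. Both choices are documented as approximate conventions,
not tuned to reproduce any external number. Epochs are 0-based; the learning
rate drops take effect at the start of epochs 10 and 20.

## Tiling conventions

Windows are half-open pixel ranges [r·d, (r+1)·d) × [c·d, (c+1)·d),
row-major, 0-based, anchored at the top-left corner of the tumor-mask
bounding box (whole-slide anchoring is available via `anchor="slide"`); only
full-size windows are considered, and a window is kept iff its tumor
fraction is *strictly* greater than the threshold (default 0.9), so a ratio
of exactly 0.9 is excluded. Downscaling is area-averaging (anti-aliased);
upscaling is refused unless explicitly allowed. Grid cells for the feature
maps are the same tile indices; maps are zero-padded symmetrically (extra
row/column on the bottom/right) to spatial dimensions divisible by
2^depth, with the padding recorded and removed from predictions. Empty
(non-tumor or padding) cells are zero-filled in the global feature map.

## Synthetic slide generator

Clinical cohorts cannot ship with the package, so the generator emulates the
statistical structure the pipeline depends on:

* **Class textures.** Each class (positive, negative, background tissue) is
  a base RGB color plus Poisson-placed dark elliptical "nucleus" blobs with
  class-specific density, over Gaussian pixel noise. Defaults (free choices;
  H&E-ish hues): positive (0.72, 0.56, 0.82) with 22 blobs per 64² px,
  negative (0.82, 0.64, 0.78) with 10, pale background (0.92, 0.87, 0.90)
  with 3. The classes are separable from mean tile color alone, which
  guarantees the pipeline has signal to learn and lets a linear classifier
  serve as a reference.
* **Tumor mask.** A Gaussian-smoothed random field thresholded at a sampled
  quantile, reduced to its largest 4-connected component with holes filled;
  coverage is constrained to 20–70% of the slide (resampled otherwise). An
  option snaps the mask to tile boundaries for exact tiling oracles.
* **Within-slide heterogeneity.** A second smoothed random field on the tile
  grid flips the rendering class of a fraction (default 0.3, correlation
  length 3 tiles) of fully-in-mask tiles. Flips are spatially correlated by
  construction — exactly the locally coherent label noise the region stage
  is designed to exploit; rates ≥ 0.5 are rejected because the slide label
  would no longer be the majority tile class.
* **Scanner domains.** A global affine color transform (3×3 matrix + RGB
  offset on [0,1] RGB, clamped) per domain stands in for the color shift
  between scanner models; training and test cohorts use different domains.
* **Ground truth.** Per-tile rendering classes, the in-mask tile set and the
  flip field are stored on every record, giving exact oracles for tiling and
  training tests. Per-slide seeds are derived deterministically from the
  cohort seed and recorded in the manifest, so cohorts are byte-reproducible
  and any single slide can be regenerated alone.

What the generator does *not* emulate: staining physics, nuclear morphology,
pen marks, blur, tissue folds, pyramidal file formats, or realistic
inter-patient variation. Passing tests therefore demonstrate correctness of
the pipeline's mechanics and its ability to exploit spatially correlated
signal — not clinical performance on real slides.

## Desk-scale study configuration

The default end-to-end study is sized to train on a single CPU in minutes:
40 slides (20/20), 512-px slides with 64-px tiles, heterogeneity 0.3 at
3-tile smoothness; 32 training slides from one domain, 8 test slides from
the other; 5-fold CV. Deliberate deviations from the reference
configuration, chosen as experiment design for this scale:

* Tiles are kept at native 64 px (center crop 56) instead of being upscaled
  to 256/224 — upscaling adds no information and multiplies CNN cost ~16×.
* The backbone uses a ¼ width multiplier (feature dimension 128) and trains
  for 5 epochs; the ResNet-18 topology is unchanged.
* The region model is a depth-2 U-Net (grids are ≈8 cells per side; deeper
  pyramids would collapse them), 16 base channels, 30 epochs. Its input
  features are standardized per channel with statistics of the training
  tumor cells (stored with the model). Three further choices stabilize
  training when only ~25 slides are available per fold: plain conv blocks
  without batch normalization (batch statistics of a single small map are
  unreliable and differ systematically between training and inference), a
  constant learning rate of 3·10⁻³ (the reference 10⁻⁴ is matched to a
  ~100× longer optimization; with ~750 one-slide steps it leaves the model
  underfit), and random flips/transposes of the (feature map, mask) pair as
  label-preserving augmentation.
* Checkpoints of the region model are selected on validation tumor-cell AUC
  rather than slide AUC: with ≤8 validation slides the slide-level AUC takes
  so few distinct values that checkpoint selection becomes noise.

## Numerical choices

* AUC is computed as the Mann–Whitney rank statistic with ties counted ½;
  an independent pairwise-enumeration oracle and scikit-learn's
  implementation cross-check it in the tests.
* Confidence intervals are stratified percentile bootstrap (default 2000
  resamples, seeded): positives and negatives are resampled separately, so
  every resample contains both classes. The CI method for the motivating
  study is unknown; results are not claimed method-identical.
* Threshold metrics predict positive iff score > 0.5 (strict): a score of
  exactly 0.5 is called negative. Precision and F1 are defined as 0 when no
  positive predictions exist.
* All training is float32; losses and metrics are accumulated in float64.
  Gradients of every layer are validated against central finite differences.
* Determinism: every stage consumes a `numpy` generator seeded from a single
  experiment seed via `SeedSequence`; identical configuration and seed
  reproduce cohorts byte-identically and training histories exactly on the
  same platform.

## Known limitations

* Pretrained weights are optional user-supplied inputs; tests and the
  desk-scale study use random (He) initialization, so absolute accuracies
  are not comparable to fine-tuning from a large pretraining corpus.
* The slim numpy engine targets clarity and desk-scale problems; full-width
  training on hundreds of thousands of 224² patches is out of its scope.
* Whether the original feature vector was pooled or spatial, the original
  U-Net's depth/width, and the original checkpoint criterion are unknown;
  the choices here (pooled 512-d vector, configurable depth, validation
  AUC) are documented defaults, not claimed faithful.
* Slide-level accuracy at the fixed 0.5 threshold can be poor even when AUC
  is perfect (posteriors may be uncalibrated); no calibration step is
  included.
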