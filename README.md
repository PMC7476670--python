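# histocorr

Weakly supervised prediction of a binary, slide-level molecular label from
H&E-stained whole-slide images, with a second stage that exploits spatial
correlation between neighboring tumor patches.

The motivating application is uveal melanoma, where loss of nuclear BAP1
(nBAP1) expression — normally established by BAP1 immunohistochemistry or
genetic testing — is a strong marker of metastatic risk. A model that reads
the label off routine H&E sections alone is useful for laboratories without
IHC or genetics facilities. The package is aimed at computational-pathology
researchers who want a complete, CPU-testable reference implementation of
this two-stage "region correlation" pipeline, including a synthetic slide
generator so that every stage can be exercised and validated without access
to clinical data.

## The method

1. **Tumor-masked tiling.** Each slide comes with a binary tumor mask. The
   mask bounding box is covered with non-overlapping d×d windows
   (d ∈ {512, 1024, 2048} px at 40× in the motivating setting) and a window
   is kept as a *tumor patch* iff its tumor-pixel fraction exceeds 0.9.
   Kept patches are area-resized to a working size and inherit the slide's
   label (*weak labels*: every tumor patch of an nBAP1⁺ slide is labeled
   positive).

2. **Independent patch classification.** A ResNet-18 patch classifier is
   trained on random 224-crops with flips and 0.6–1.4 color jitter, using
   class-weighted cross-entropy with inverse-frequency weights
   w_c = N/(2 n_c), SGD (momentum 0.9, weight decay 5·10⁻⁴), lr 10⁻³
   divided by 5 at epochs 10 and 20, 30 epochs; the checkpoint with the best
   validation AUC is kept.

3. **Region correlation.** The classifier's 512-d global-average-pooled
   features of all tumor patches in a slide are re-assembled at their grid
   positions into a *global feature map* (zeros elsewhere) and fed to a
   U-Net that outputs one logit per cell. The logistic output is multiplied
   element-wise by the tumor-cell mask, giving a *probability map* that is
   exactly zero off-tumor. Training uses the same class-weighted
   cross-entropy, gated to tumor cells only (every tumor cell carries the
   slide label), SGD with a constant learning rate.

4. **Aggregation and ensembling.** The slide posterior is the arithmetic
   mean of its tumor-patch posteriors. Slides are split 5-fold at the
   *slide* level (stratified; patch-level splitting would leak information
   between train and validation); the five resulting models can be ensembled
   by averaging posteriors. Reported metrics: AUC (Mann–Whitney, ties ½)
   with stratified percentile-bootstrap CIs, plus accuracy / sensitivity /
   specificity / precision / F1 at threshold 0.5.

Because neighboring tumor patches tend to share class status, the U-Net can
correct locally coherent patch-classifier errors that an independent
per-patch decision cannot; on held-out synthetic cohorts with spatially
correlated heterogeneity the region stage raises patch-level AUC
substantially (see below).

All neural-network components (residual CNN, U-Net, SGD, losses) are
implemented in `histocorr.nn` as a compact numpy engine with explicit
forward/backward passes, verified by finite-difference gradient checks;
the full pipeline trains in minutes on one CPU at the desk-scale
configuration.

## Worked example

The built-in desk-scale study generates 40 synthetic H&E-like slides
(20 nBAP1⁺ / 20 nBAP1⁻; 32 training slides from one scanner domain, 8
held-out test slides from a color-shifted domain; 512-px slides, 64-px
tiles, 30% of in-tumor tiles flipped to the opposite texture in spatially
correlated patches), runs 5-fold cross-validated two-stage training and
evaluates each model and the 5-model ensemble on the test cohort:

```bash
histocorr run-all --seed 0 --out runs/demo
```

Ensemble rows of the printed report (abridged):

```
level     variant    model   auc  ci_low  ci_high  accuracy    f1
patch independent ensemble 0.776   0.677    0.858     0.746 0.782
slide independent ensemble 1.000   1.000    1.000     1.000 1.000
patch      region ensemble 0.962   0.924    0.992     0.860 0.892
slide      region ensemble 1.000   1.000    1.000     0.750 0.800
```

Patch-level AUC is capped well below 1 for the independent classifier
because 30% of tiles genuinely show the opposite texture while carrying the
slide's weak label; the region stage recovers most of that gap by smoothing
over spatial context (0.78 → 0.96 here), and both variants separate the
eight test slides perfectly at the slide level. Individual pieces are
available as library calls and as the CLI verbs `synth`, `tile`,
`train-patch`, `train-region`, `eval`, `ensemble`, `render`.

For real data, point `histocorr tile` at a manifest CSV with columns
`slide_id, image_path, mask_path, label (POS|NEG), domain, seed` referencing
RGB slide images and aligned 0/255 tumor-mask PNGs.

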