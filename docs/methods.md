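# Methods

## Scope and model

`brainseg` segments 2-D T1-weighted head slices into cerebrospinal fluid
(CSF), grey matter (GM), white matter (WM) and skull, and evaluates the
result volumetrically against the Visible Chinese Human (VCH) head
reference.  The method assumes the four tissues occupy disjoint grey-level
bands — CSF [40, 57), GM [61, 79.8), WM [86, 110), skull [110, 130], with
image background below 35 — and that the skull is a ring enclosing the
brain.  Grey levels between bands belong to no tissue; the pipeline's job
is to resolve them (and pixels displaced across bands by noise) using
spatial context.  The shared boundary 110 is assigned to skull so the four
bands partition their union.

## The synthetic phantom

Real patient data are not distributed, so all experiments run on a
generator that emulates the target data: 256 × 256 8-bit slices containing
concentric elliptical compartments — skull outermost, then CSF, GM, WM
innermost — with per-subject random semi-axes, rotation and centre, and a
per-slice scale factor standing in for slice position.

Design choices worth knowing:

* **Area proportions.** Band boundaries are placed so tissue areas match
  the VCH percentages (CSF 37.65 %, GM 27.08 %, WM 12.35 %, skull
  12.81 % of the head).  Those four figures sum to 90.89 %, implying a
  head contains ~9 % non-tissue content; the phantom realises it as a thin
  "other soft tissue" ring between skull and CSF, labelled UNASSIGNED in
  the truth and given grey levels (140–190) outside every band.  With this
  ring, percentages computed over non-background pixels are directly
  comparable to the reference column.
* **Intensities.** Each tissue draws from a truncated normal centred
  mid-band with sd = band width / 6 (≈3σ to the band edge, so clipping
  adds no edge pile-up).  A unimodal in-band distribution is what tissue
  histograms look like in practice and is required for the pooled
  histogram to show one peak per tissue; a uniform draw provably produces
  several spurious local maxima per band.
* **Noise.** Additive Gaussian, σ = 5 grey levels by default, rounded and
  clipped to [0, 255]; a Rician option (magnitude of a complex Gaussian
  signal) is available.  σ = 5 against band gaps of 4–6 grey levels makes
  band-crossing frequent enough that thresholding alone is visibly
  imperfect, which is the regime the spatial stages are for.
* **Facial clutter.** 1–3 extracranial blobs with GM-band intensities and
  BACKGROUND truth reproduce the structures (nose, eyes, ears) that skull
  stripping must remove; intensity thresholding alone cannot.

What the phantom does **not** model: cortical folding, partial-volume
mixing at boundaries (each pixel's pre-noise intensity comes from exactly
one tissue), bias fields, 3-D continuity, or off-centre slice anatomy.
Passing tests therefore demonstrate correctness of the pipeline mechanics
and its behaviour under band-structured intensity models with additive
noise — not clinical performance on real MRI.

## Preprocessing

Denoising is wavelet shrinkage: Daubechies-4, 3 decomposition levels, soft
thresholding of all detail scales at `threshold_scale` × the universal
threshold σ̂√(2 ln N), with σ̂ the median absolute deviation of the finest
diagonal subband over 0.6745.  `WaveletSpec` defaults to the full
universal threshold (scale 1.0).  The *pipeline* default is scale 0.25,
calibrated by reconstruction fidelity on phantoms: at σ = 5 the full
universal threshold raises MSE against the clean image (39.2 vs 17.6 for
no denoising at all — the thin skull ring sits between background 0 and a
bright ring, and aggressive shrinkage blurs those edges), while scale 0.25
lowers it to 12.8.  At σ = 15 denoising reduces MSE strongly (≈150 → 68)
at either scale.

Histogram equalization uses the classic CDF-minimum remap
`round((cdf(v) − cdf_min)/(N − cdf_min)·255)`, which is monotone, leaves a
constant image constant and is the identity on an already-uniform
histogram.  It is off by default in the pipeline: the CNN consumes raw
(suppressed) intensities, since the band model is defined on the original
grey scale.

## Thresholding and skull stripping

`classify_by_range` is a 256-entry lookup: below 35 → BACKGROUND, inside a
band → that tissue, otherwise UNASSIGNED.  On clean phantoms it reproduces
the truth exactly (intensities are drawn in-band), which the tests assert.

`skull_strip` encodes the ring prior: the SKULL mask is morphologically
closed (disk radius 5 — noise opens pixel gaps in the ring, and an
unclosed ring has no fillable interior), holes are filled, and the largest
component whose interior holds ≥ 50 % of all CSF+GM+WM pixels is kept;
every labelled pixel outside it becomes BACKGROUND.

`morph_cleanup` opens then closes each tissue mask with a 3 × 3 square
(the square, unlike the cross, leaves solid rectangles unchanged) and
drops connected components below `min_component` (default 10) pixels.  In
the pipeline it runs once, after cluster refinement, so the threshold
stage itself stays exact on clean data.

## The patch classifier

The production network is the classic 32 × 32 LeNet geometry with sigmoid
activations throughout: C1 six 5 × 5 maps (→28), S2 2 × 2 sum-pool with
per-map trainable gain β and bias (→14), C3 sixteen 5 × 5 maps with the
classic partial-connection table (→10), S4 pool (→5), C5 120 maps (5 × 5
on 5 × 5, i.e. fully connected), F6 84 sigmoid units, and a 4-way affine
head trained with softmax cross-entropy.  (The historical radial-basis
output head is incompatible with cross-entropy and is not used.)  A
secondary `SMALL` variant — 4 × 4 input, six 3 × 3 kernels, 2 × 2
down-sampling to six single-pixel features — is kept for fast tests and
selectable by config; 4 × 4 patches carry too little context to be the
production choice.  Everything is numpy: im2col convolutions, hand-written
backpropagation (verified against finite differences in the test suite),
and Adam with β₁ = 0.5, β₂ = 0.999, lr 0.001.

Training details that matter:

* **Image-level batching.** One optimisation step averages gradients over
  patch samples from 5 slices (`batch_size` counts images,
  `patches_per_image` = 50 caps the sample per slice); a subepoch is one
  pass over the training slices, an epoch is 20 subepochs with a
  validation checkpoint per subepoch, and the best-validation parameters
  are restored at the end.  Tiny per-step samples leave the all-sigmoid
  stack on its uniform-prediction plateau (gradient noise dominates);
  image-sized batches escape it within a few hundred steps.
* **Input standardisation.** Patches are scaled to [0, 1] and standardised
  with training-set mean/std (persisted in checkpoints).  Uncentred,
  all-positive inputs measurably stall sigmoid training.
* **Splits are by image, never by patch**, so patches from one slice
  cannot leak across train/validation/test.
* **Class balance.** Per epoch the majority classes are subsampled to at
  most 4 × the rarest class.

Dense prediction evaluates the patch grid at a configurable stride
(pipeline default 2) and fills each pixel from its nearest evaluated
centre; suppressed (grey 0) and border pixels are BACKGROUND.

In the fused segmentation the threshold map is the prior and the CNN
overrides a pixel's label only where its winning softmax probability
reaches `cnn_override_confidence` (default 0.9).  This ensemble rule makes
the pipeline monotone in CNN quality: a weakly trained network changes
almost nothing, a confident one corrects spatial errors the intensity rule
cannot see.

## Cluster refinement

Foreground pixels (grey in [35, 135] — the tissue bands, their gaps, and a
5-level margin above the skull band to recapture edge pixels smoothed
upward by denoising) become feature points (w·row, w·col, grey) with
spatial weight w = 0.01.  Grey level must dominate the metric: cluster
centres are meant to stand for tissues, and in concentric anatomy an
equal-weighted k-means splits space into quadrants instead (the spatial
variance term dominates), leaving cluster means in no band.

The k-means itself follows a master–worker contract: points are processed
in fixed 4096-point chunks, workers compute nearest-centre assignments
(ties to the lowest index) and partial per-cluster distance/coordinate
sums, and the master folds partials in chunk order — so results are
bit-identical for any worker count.  Iteration stops when the summed
Euclidean distance changes by < 10⁻⁹; because centre updates minimise the
*squared* objective, the plain-distance objective is not formally
monotone, and an (empirically rare, sub-10⁻⁴-relative) increase is
rejected by reverting to the last accepted state.  Initialisation is
seeded k-means++ by default; the pipeline instead seeds one centre per
tissue from the current label map's mean features (band midpoints as
fallback), which reliably lands the clusters on the four bands where
k-means++ occasionally merges WM with skull.  After convergence the
core-point filter flags the ⌈∂·n⌉ points nearest each centre (∂ = 0.5,
ties broken by point index).

`refine_labels` maps each cluster to the tissue whose band contains its
mean grey (unmapped clusters change nothing, with a warning), lets
UNASSIGNED pixels inherit their cluster's tissue, and flips an
already-labelled non-core pixel only if it disagrees with its cluster
*and* its own grey lies outside its current label's band.  The guard makes
refinement provably a no-op on clean data and prevents a band-straddling
cluster from overriding intensity-consistent labels.

## Volumetry

Percentages use all non-background pixels as denominator (UNASSIGNED head
content included), matching the reference convention in which the four
tissues sum to 90.89 %.  The GM/WM ratio is counts-based.  Ratio agreement
is `100·(1 − |pred − ref|/ref)`, floored at 0 and rounded to whole
percent.  Jaccard is intersection-over-union per tissue, defined as 1.0
when both masks are empty.  The packaged reference file records the
printed reference values as printed — including the mild internal
inconsistency that the tabulated percentages imply GM/WM = 2.19 while the
printed ratio is 2.22; ratio comparisons use 2.22.

## Default experiment sizes

The default pipeline configuration — 1 subject × 16 slices at σ = 5,
training on 12 slices (10 train / 2 validation) at 10 epochs, evaluation
on 4 held-out slices with prediction stride 2 — is the package's
desk-scale experiment; it completes in a few minutes on one CPU.  The
full-scale recipe (5 × 160 slices, 600/100/100 split, 50 epochs) is
expressible through the same configuration fields.

## Known limitations

* The phantom's crisp single-tissue pixels make range thresholding
  unrealistically strong; real MRI has partial-volume voxels, bias fields
  and anatomy-dependent overlap between tissue intensities.
* The numpy CNN is CPU-bound and meant for method-level experiments, not
  large-scale training.
* Skull Jaccard is the weakest metric (≈0.90 at σ = 5): the ring is thin,
  bordered by the image's strongest edges, and loses a 1–2-pixel shell to
  denoising blur at its boundaries.
* The parallel contract is an in-process worker pool; no distributed
  (multi-machine) execution is provided, and wall-clock scaling is
  deliberately out of scope.
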