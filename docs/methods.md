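# Methods

`bacscan` implements a weakly supervised pipeline for detecting breast
arterial calcifications (BAC) on mammograms and estimating the calcified
burden as a by-product of detection.  Training uses only image-level BAC+/BAC−
labels; localisation and quantification come from Grad-CAM++ relevance maps of
the trained classifier.  Because clinical mammography cohorts with BAC labels
cannot be redistributed, the package ships a synthetic phantom generator that
provides ground-truth calcification masks and lengths, so every stage is
testable end to end.

## Phantom cohorts (`bacscan.phantom`)

Each synthetic patient contributes a four-view screening exam (left/right ×
CC/MLO).  A view is a half-elliptical "breast" of smoothly textured tissue
(low-frequency Gaussian-filtered noise) on a near-zero background, with the
chest-wall side flush against one image edge and the laterality mirrored.
BAC-positive views carry 1–3 arterial tracks: dashed bright segments (mixed
linear dashes of 0.8–2 mm and punctate dots of 0.3–0.8 mm, gaps 0.4–1.2 mm)
along quadratic Bézier paths whose control points are drawn from the eroded
tissue interior, so the curve stays inside tissue.  The recorded
`truth_length` is the summed centerline arc length of the rendered dashes
(dense polyline integration of the Bézier, converted to mm by the pixel
size); the `truth_mask` marks exactly the rasterised dash pixels.

Label-independent confounders are drawn regardless of BAC status: clusters of
benign round calcifications (bright discs, radius 1–3 px) and skin-fold-like
ridges near the tissue boundary carrying a few cutaneous calcification dots.
They share the calcification intensity band, so brightness alone cannot
separate the classes; the arrangement (dashed curvilinear tracks vs isolated
round dots) carries the signal.  Calcification pixels are clamped above the
tissue-texture ceiling, so a learnable contrast is guaranteed by
construction.

Patient-level BAC probability follows a step function over the cohort's four
age-quartile classes; the default rates (6.3 %, 11.6 %, 34.3 %, 38.2 %)
reproduce the steep age gradient of screening populations, giving ≈ 22.6 %
patient prevalence under uniform ages.  Given a positive patient, each view
is positive with probability 0.75 (re-drawn until at least one view is
positive), matching the ~3 positive views per positive patient seen in
four-view exams.  Per-track target lengths are log-uniform on 8–45 mm —
many low-burden, few high-burden patients.  Every patient draws from an
independent substream spawned from the cohort seed, so cohorts are
bit-reproducible and stable under reordering.

What the phantoms do *not* emulate: realistic fibroglandular texture, vessel
anatomy (tracks are geometric curves, not vessels), pectoral muscle, dense
tissue occluding calcifications, scanner-specific noise.  Passing phantom
tests therefore demonstrates that the pipeline's machinery is correct and
that localisation/quantification emerge under weak supervision when a signal
exists; it does not certify clinical performance.

## Preprocessing (`bacscan.preprocess`)

Otsu's threshold is computed from the intensity histogram (exact per-level
histogram for small integer ranges, 256 bins otherwise) as the argmax of
between-class variance, ties resolved to the lowest level.  The breast is the
largest 4-connected suprathreshold component — the largest-component rule
suppresses view markers and labels — and its tightest bounding box is
cropped, resampled bilinearly (anti-aliased on downscale) to the model input
size, and replicated to three identical channels for architecture parity
with RGB-pretrained backbones.  Breast pixels are z-scored with statistics
computed over breast pixels only (per image, robust to inter-unit intensity
shifts); background is set to the minimum normalised breast value.  The
crop+scale affine is retained, giving per-axis mm/pixel in the model frame
and hence the per-pixel area used by quantification.  Aspect ratio is not
preserved (fixed-size matrix, anisotropic scale recorded in the geometry).

## Cohort splitting (`bacscan.split`)

Splitting is at patient level — all four views travel together.  Positives
are shuffled and partitioned 70/15/15 within each age-quartile class
(largest-remainder rounding; remainder ties go in train→val→test order),
preserving the BAC+ age distribution across subsets; negatives are
partitioned globally.  Patients are canonically sorted by id before
shuffling, so assignments are invariant to input row order.  Training
negatives are then randomly undersampled to a 30 % patient-level BAC+
prevalence — keeping all positives and
n_neg = round(n_pos·(1−p)/p) negatives; discarded patients are flagged, not
reassigned — while validation and test keep the natural prevalence.
Quartiles use linear interpolation (the common convention; boundaries are
returned so alternatives can be audited).

## Classifier (`bacscan.nn`, `bacscan.detector`)

The model is a VGG16-style stack: 3×3 convolutions in blocks, 2×2 max
pooling after each block, then two dense layers and a single sigmoid unit.
Leaky-ReLU (α = 0.3) follows every convolution and dense layer; dropout 0.3
regularises the head.  The full profile is the 13-conv / 5-pool VGG16 layout
with a 256-unit head at 1536×768 input.  Partial fine-tuning freezes all but
the deepest `n_finetune_conv_layers` convolutions (default 5); the head is
always trainable.  When no pretrained weights are supplied, layers use
He initialisation with the gain corrected for the leaky slope
(2/(1+α²)) and a near-zero final layer, so initial logits stay near zero at
any depth; the frozen early blocks then act as a fixed multiscale
random-feature extractor.

The layer stack, backpropagation and Adam are implemented in numpy (NHWC
layout).  Convolutions are evaluated as nine shifted GEMMs on the contiguous
input — one per kernel tap — rather than through an im2col buffer; backward
re-extracts patches from a cached input reference, keeping training memory
close to inference memory on a single CPU.  A frozen prefix runs in pure
inference mode, and validation views are pushed through it once per training
run, with only the trainable suffix re-evaluated each epoch.

Training minimises class-weighted binary cross-entropy (w_c = N/2N_c,
inverse class frequency; equal to the unweighted loss on balanced data) with
Adam under cosine annealing lr(t) = lr₀·½(1+cos(πt/(T−1))) from lr₀ at epoch
0 to 0 at the last epoch, no restarts.  Online augmentation applies
geometric transforms first (exact array-reversal flips; rotation ±10°, shift
±5 %, zoom ±10 % composed into one bilinear resampling) and pixel noise
second (Gaussian, SD 1 % of dynamic range; salt-and-pepper, 0.5 % of
pixels), after normalisation.  Validation AUC-PR — the right model-selection
metric under ~10 % view prevalence — is computed on un-augmented views after
every epoch, and the weights of the first epoch attaining the maximum are
returned.  Data order, augmentation and dropout draw from per-epoch
substreams of the training seed, so runs are bit-reproducible.

## Explanation (`bacscan.explain`)

Grad-CAM++ is computed at the deepest convolutional layer's post-activation
feature map A.  The attribution target is Y = exp(S) with S the pre-sigmoid
logit; because the network is piecewise linear in A, higher derivatives of Y
collapse to powers of the first-order gradient g = ∂S/∂A, giving the closed
form α_ij = g²/(2g² + (Σ_ab A_ab)·g³) (α = 0 where the denominator
vanishes within ε = 1e-8), channel weights w_k = Σ_ij α_ij·relu(∂Y/∂A_ij),
and the raw map relu(Σ_k w_k A^k).  The implementation is verified against a
finite-difference oracle that differentiates exp(S) numerically on tiny
networks; the oracle uses a large stencil step (1e-2) because between kinks
the target is exactly polynomial in the perturbation, while the
third-derivative numerator underflows rounding noise at conventional steps.

Raw maps are upsampled to the model frame with pixel-centre-aligned bilinear
interpolation (edge clamping), optionally restricted to the breast region,
and normalised to [0, 1] by the per-image 99th percentile (clipped above 1).
Percentile rather than maximum normalisation is deliberate: with max
normalisation the thresholded area measures the sharpness of the single
strongest cell rather than the spatial extent of relevance, and the
area–length correlation on phantom cohorts degraded accordingly (ρ ≈ 0.5–0.6
vs ≈ 0.63–0.73 with the percentile scale).  `norm="max"` remains available.

## Quantification (`bacscan.quantify`)

For views predicted positive (score > 0.5 by default), the estimated
calcified area is BAC_area = P·Σ_i 1[G(i) > Th] with Th = 0.3 and P the
per-pixel area in mm² in the model frame (product of the per-axis mm/pixel
from the crop/resize geometry).  "Pixel size" is interpreted as an area so
the estimate carries area units; the association with measured lengths is
assessed by Spearman rank correlation, which is invariant to this choice.
Thresholding is strict (G = Th excluded), area is exactly P times the count,
and area is monotone non-increasing in Th.

## Evaluation (`bacscan.evaluate`)

Confusion-count metrics are exact closed forms, rounded only for
presentation (2 decimals, half-up).  ROC curves use a threshold sweep with
trapezoidal AUC, which equals the Mann–Whitney pair-count statistic
(verified exhaustively in tests); AUC-PR is reported as average precision
(step interpolation), with the trapezoidal PR variant also exposed since the
two differ.  Cohort statistics: Kolmogorov–Smirnov normality with the
Lilliefors correction (parameters are estimated), two-sided Mann–Whitney U,
medians and IQRs under the same quartile convention as the splitter, and
Pearson/Spearman correlations annotated with Evans qualitative bands
(< 0.2 very weak, < 0.4 weak, < 0.6 moderate, < 0.8 strong, ≥ 0.8 very
strong).

## Pipeline profiles and scaled-down study conditions (`bacscan.pipeline`)

Two profiles fix consistent geometry across stages.  `paper-parity` uses
1536×768 inputs with the full 13-conv backbone and 256-unit head; it exists
so full-scale geometry is expressible, and is exercised structurally (build,
freeze contract) rather than trained in the test suite.  `desk` is the
CPU-scale study configuration used by the tests and the acceptance script:

* phantoms at 384×192 px, 0.2 mm/px; model input 256×128 (the crop is
  resampled, mirroring native→fixed-size resampling of real pipelines);
* backbone scaled in width (÷8) **and** depth (first 3 of the 5 VGG blocks),
  head 32 units.  Depth scaling is what preserves the full profile's
  receptive-field-to-image ratio (~15 % of image height at the attribution
  layer); at 256×128 a 5-block stack's deepest cells see ~80 % of the image
  and cannot localise, and a wide head on the 16k-dim flatten overfits a
  ~500-view training set badly enough to corrupt checkpoint selection;
* 300 patients, 10 epochs, batch 8, lr₀ = 5e-4 (chosen on validation AUC-PR;
  the full profile's lr₀ = 1e-6 presupposes a pretrained backbone), 5
  fine-tuned conv layers;
* quantification over positive predictions from all subsets — the
  area–length analysis mirrors a cohort-wide subgroup of model-positive
  views rather than the held-out split.

One global seed spawns the phantom, split, initialisation and training
substreams.  A run directory holds plain-file artifacts (CSV/JSON/PNG/TIFF
plus an `.npz` weight snapshot) and a manifest with SHA-256 checksums.
Re-running with an unchanged configuration reloads the stored weights — the
expensive stage — and every other stage recomputes deterministically, so
downstream artifacts are reproduced bit-identically.

Under these desk conditions held-out (test) AUC-ROC lands around 0.91–0.95
across cohort seeds, and the Spearman ρ between estimated area and true
track length over ≥ 140 true-positive views around 0.53–0.69 — typically
above 0.6 but with appreciable cohort-to-cohort variability, since both the
trained features and the per-view heatmap scale are stochastic at this
scale.  A full study completes in under ten minutes on one CPU.  Full-scale
performance figures on clinical data are outside what phantoms can certify.

## Numerical choices and degenerate inputs

* Otsu: single-valued histograms raise a degenerate-input error; ties break
  to the lowest level.
* Normalisation: a zero-variance breast region raises an error rather than
  producing NaNs.
* BCE is computed in float64 with probabilities clipped to [1e-12, 1−1e-12];
  a non-finite loss aborts training with the epoch/batch location.
* Grad-CAM++: α = 0 where its denominator is within 1e-8 of zero; the
  exp(S) factor is capped at exp(80) (it cancels under normalisation);
  all-zero maps are passed through flagged, never renormalised.
* Max-pool gradients split equally across tied maxima (ties have measure
  zero on continuous activations).
* Largest-remainder apportionment breaks ties toward earlier subsets
  (train, then val); undersampling to a target prevalence at or below the
  natural one is a warning no-op.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute
  performance numbers on phantoms do not transfer to clinical data.
* No pretrained backbone is bundled; with random frozen features the desk
  profile's detection is weaker and noisier than a pretrained full-scale
  model would be.
* The numpy training loop is single-threaded CPU code; the paper-parity
  profile builds and runs forward passes but is impractical to train here.
* The classification operating point (0.5) and quantification threshold
  (0.3) are configuration, not learned; AUC-based metrics are unaffected.
* DICOM support covers pixel data and Imager/Pixel Spacing only.
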