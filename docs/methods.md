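# Methods

## Problem and pipeline

`histotex` classifies histology image regions as tumor epithelium or
stroma from texture alone. The pipeline is deliberately classical: local
descriptors on overlapping blocks, a linear SVM on the descriptors, and
simple averaging to go from blocks to images and pixels. Every stage is a
pure function of its inputs and the recorded configuration, so a saved
model file plus the original image reproduces the output bit for bit.

Stage order is fixed: the color image is scaled (bilinear) by
`scale_factor` (default 0.5), converted to luminance with the ITU-R 601
weights 0.2989/0.5870/0.1140, and background is masked. We scale the
color image before grayscale conversion; for bilinear interpolation the
two orders give identical results up to floating rounding, so the choice
is one of bookkeeping, not substance.

### Tissue mask

Pixels with luminance ≥ `background_threshold` (default 240, of 255) are
background; ≥ rather than > so that pure white is always background. The
raw mask is smoothed by closing then erosion with a disk of
`morph_radius` = 5 px at analysis scale. The radius is a free choice (the
operators, not the element, are inherent to the method): 5 px closes slit
artifacts of up to ~10 px while eroding a 5 px rim, which at 0.5× scale
corresponds to a 10 px rim in the original image.

### Blocks

An 80×80 window slides in 40 px steps, row-major from the top-left;
windows that would cross the image edge are dropped (no padding — padded
texture would be synthetic). A block is analyzed iff ≥ 50 % of its pixels
are tissue (`min_tissue_fraction`). Coordinates are 0-based with
half-open windows.

## LBP/C descriptor

For each configuration (P=8, R=1) and (P=16, R=2), neighbor `k` sits at
angle 2πk/P on the circle of radius R — offsets (−R·sin, R·cos) in
(row, col), i.e. neighbor 0 to the right, counter-clockwise order — with
bilinear interpolation at non-integer positions. Pixels within ⌈R⌉ of the
block edge are excluded (no full neighborhood), so an 80×80 block
contributes (80−2⌈R⌉)² pixels.

Numerical detail that matters: we interpolate the *difference*
neighbor − center corner by corner, rather than interpolating the raw
neighbor value and subtracting. Mathematically identical, but at floating
precision only the difference form guarantees that the threshold
(neighbor ≥ center) and the variance are *exactly* invariant to adding a
constant to the whole image — the gray-scale invariance that motivates
LBP in the first place, and a property our tests assert bitwise.

The code's bits (1 iff neighbor ≥ center; equality counts as 1) are
weighted by powers of two. Uniform codes (≤ 2 circular transitions)
minimize under circular shifts to 2^k − 1 for k set bits; the riu2 bin is
therefore the popcount for uniform codes, and P+1 for all others — P+2
bins total.

VAR is the population variance (divide by P; the divisor is a convention
with no downstream effect since quantization is rank-based) of the P
interpolated samples. Quantization into Q = 8 equal-mass levels uses the
i/Q empirical quantiles of per-pixel VAR pooled over the training
images' tissue pixels, pooled across both classes (per-class quantizers
would leak label information into the representation). Equality at an
edge assigns the higher level; values beyond the extreme edges clamp.
Degenerate distributions collapse duplicate edges with a warning.

The block feature is the row-major-flattened (LBP bin major, VAR level
minor) concatenation of the (8+2)×8 and (16+2)×8 joint histograms:
80 + 144 = 224 bins, scaled to unit Euclidean norm. An empty histogram is
an error, not a zero vector — such a block should never have been
emitted.

## Haralick descriptor

Luminance is linearly quantized to 8 levels (`floor(v·8/256)`, clipped).
One symmetric GLCM per offset (0,1), (1,1), (1,0): pairs are counted in
both directions and normalized to probabilities; when a block contains
masked background, pairs with a background member are skipped. The 20
statistics (classic set plus the extended inverse-difference and
information-measure metrics) use 0-based level indices, base-2 logarithms
with an epsilon guard inside logs, and correlation = 0 by convention when
a marginal has zero variance. The 20 metrics are *concatenated* across
the three offsets (60 values) rather than averaged; averaging is a lossy
aggregation we did not need, and the per-offset layout is recoverable
into a 20-dim mean if wanted.

## Gabor descriptor

The bank is 6 orientations × 4 scales. Orientations and scale count are
inherent to the design; the frequencies are not recoverable from the
method description, so we adopt the standard wavelet-style layout:
base frequency 0.25 cycles/px halved per scale (octave spacing),
bandwidth 1 octave, isotropic envelope — all recorded in the model file.
Kernels are DC-corrected by removing a Gaussian-weighted offset from the
real part, so constant regions respond exactly zero. Convolution uses
reflect padding (FFT-based for speed); the descriptor is mean and
standard deviation of the complex response magnitude per filter, 48
values. Equivalence with any particular historical implementation is at
the level of bank structure, not coefficients.

## Classification and aggregation

Blocks are classified by a linear C-SVM: L2-regularized hinge loss
solved by LIBLINEAR's dual coordinate descent (`sklearn.svm.LinearSVC`),
tolerance 1e-4, no class weights, no additional feature standardization,
fixed seed. Epithelium is the positive class. Default costs when tuning
is skipped: C = 300 (LBP/C), 2048 (Haralick), 2 (Gabor). `tune_C` scans
C = 2^0 … 2^20 by block-level validation AUC, breaking ties toward the
smaller C (smaller C = stronger regularization at equal accuracy).

Image call: arithmetic mean of block decision values; class by sign with
exact zero assigned to epithelium (the threshold is *at* zero);
|mean| > 1 strictly is a strong call, |mean| = 1 weak. A background-only
image raises a dedicated error and is reported unclassifiable rather
than silently scored.

## Evaluation

Percent agreement and unweighted Cohen's kappa come from the 2×2
contingency table (rows truth, columns prediction, order stroma then
epithelium). Two quantities are reported where the literature is
ambiguous: the stroma positive predictive value (stroma calls that are
truly stroma) and the conventional specificity (epithelium images called
epithelium) — they differ and both are named explicitly. AUC uses the
Mann–Whitney pair-counting estimator (ties ½), which equals the
trapezoidal ROC area; the confidence interval is DeLong by default, with
a seeded 2000-resample percentile bootstrap as an option. Reported
rounding follows convention: percentages to whole percent, kappa to 3
decimals.

Score maps assign each analyzed block's decision value to all its
pixels, averaging overlaps; uncovered pixels are flagged background. The
heat map uses the "jet" diverging ramp (dark blue → turquoise → light
green at zero → yellow/orange → dark red) with symmetric clipping at the
99th percentile of |score| by default (fixable for cross-image
comparability) and a reserved light-gray background color.

## Synthetic data

The generator emulates the *statistical* contrast between the two tissue
classes, not their appearance: epithelium-like images are smoothed point
processes (dark rounded clusters, isotropic second-order statistics);
stroma-like images are anisotropically smoothed noise (oriented
streaks). Luminance is kept well inside [0, 255] so brightness/contrast
perturbations do not clip. Defaults: 160 px images (one analysis block
at 0.5× scale — the smallest end of realistic region sizes, chosen for
test speed), blob density 0.01 points/px with σ = 4 px bumps, fiber
width 2 px and elongation 12 px, Gaussian sensor noise σ = 4. Each
dataset image gets a unique derived seed, a random orientation, a random
right-angle rotation and ±10 brightness / ±5 % contrast jitter so the
classes are not separable by first-order statistics alone. A
`difficulty` knob blends both classes toward a common isotropic texture
to exercise weak-call and misclassification paths.

What a green end-to-end test establishes: the descriptors order the two
synthetic classes almost perfectly (image-level AUC > 0.95 at 40 test
images per class). What it does not establish: performance on real
stained tissue, robustness to staining variation, scanner artifacts,
mixed-class regions, or the published accuracy on the original image
sets, which would require that data.

## Known limitations

- Whole-slide/tiled pyramid formats are out of scope; inputs are plain
  PNG/TIFF regions.
- The GLCM metric set follows the common extended definitions; other
  codebases differ in indexing (0- vs 1-based) for the polynomial
  metrics, which shifts their absolute values but not their
  discriminative content.
- Gabor filter coefficients are one principled choice among several; use
  the recorded bank parameters when comparing feature values across
  installations.
- The DeLong interval assumes independent images; block-level scores
  within an image are correlated, so block-level CIs would be
  anticonservative (we only report image-level CIs).
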