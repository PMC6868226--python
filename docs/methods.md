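# Methods

This note documents the models and procedures implemented in `seedgrader`,
the defaults and why they were chosen, the numerical details, and what the
synthetic experiments do and do not demonstrate.

## Color representation

RGB images in [0, 1] are mapped to CIE XYZ by the fixed linear matrix with
rows (0.4124, 0.3576, 0.1805), (0.2126, 0.7152, 0.0722),
(0.0193, 0.1192, 0.9505), and then to L\*a\*b\* relative to a reference
white. Two conventions deliberately differ from textbook sRGB→Lab:

* **No gamma linearization.** The matrix is applied to the raw [0, 1]
  values. 8-bit camera output is gamma-encoded, so this makes the "XYZ"
  a monotone distortion of true tristimulus values; for grading this is
  harmless (the k-means vocabulary only needs a consistent, perceptually
  spread embedding) and it keeps the map exactly linear, which the tests
  exploit. `linearize=True` restores the sRGB EOTF for comparison.
* **Companding constants** use the break point 0.0089 and linear branch
  7.7870·t + 0.1379 rather than the higher-precision CIE values
  (0.008856, 7.787·t + 16/116). The two branches then agree to ≈ 3×10⁻⁵
  at the break point — far below 8-bit quantization — and black maps to
  L\* = −0.0036 instead of 0.

The reference white is the image of RGB = (1,1,1) under the same matrix,
(0.9505, 1.0000, 1.0890), so that white maps to exactly L\* = 100 under
the package's own color model.

The spatial color feature is one 5-vector per non-overlapping 16×16-pixel
tile: three per-tile channel means plus the tile center normalized by the
image width and height. Tiles are pixels, not a fixed 16×16 grid, so the
feature count scales with image area like a dense local feature; partial
edge tiles are dropped. The same extractor runs on RGB and HSI images for
the baselines (HSI uses the standard geometric conversion with H ∈ [0, 1)
cyclic, S = 1 − min/I, achromatic pixels assigned H = S = 0).

## SURF

The detector computes the integer box-filter approximation of the Hessian
determinant, det **H** ≈ Dxx·Dyy − (0.9·Dxy)², on an integral image, over
3 octaves × 4 levels (lobe size 2^(o+1)·(i+1)+1, i.e. filter sides
9–27, 15–51, 27–99; sampling stride doubles per octave; scale
s = 1.2·L/9). Interest points are 3×3×3 maxima (position × level) above a
threshold, with no sub-pixel or sub-scale interpolation — detections are
therefore exactly reproducible. Each point carries the sign of the
box-filter Laplacian Dxx + Dyy: +1 for dark structure on a bright
background. Box sums touching the image boundary are clipped; candidate
maxima whose filter support leaves the image are discarded.

The detector threshold default is 5×10⁻⁵ (images in [0, 1]), chosen so a
128-px kernel image yields on the order of 20–60 points — enough that
64-bin word histograms are populated, and the same order as reported
point counts on real scanned kernels.

Orientation: Haar responses of side 4s on a disc of radius 6s (step s),
Gaussian-weighted (σ = 2.5s); a 60° window slides over the response
angles in a fixed scan order (64 start angles) and the orientation is the
angle of the largest summed response vector; ties keep the first window.

Descriptor: a 12×12 grid of sample points spans an orientation-aligned
square window of side 20s (this implementation intentionally uses 3×3
samples per subregion — 12×12 total — rather than canonical SURF's 5×5).
At each sample, axis-aligned Haar responses of side 2s are taken,
Gaussian-weighted (σ = 3.3s), and rotated into the point's frame; each of
the 4×4 subregions sums its 3×3 samples into (Σdx, Σdy, Σ|dx|, Σ|dy|),
and the 64-vector is L2-normalized (flat windows return exact zeros; the
zero cutoff, 10⁻⁷ on the raw norm, sits above integral-image rounding
noise). Points whose descriptor window would leave the image are skipped.
Numerical parity with any existing SURF library is a non-goal; the
properties that matter — exhaustive box-sum correctness, sign flipping
under contrast inversion, ±90° orientation equivariance, descriptor
cosine similarity > 0.8 under rotation, detection stability under noise —
are enforced by tests.

## Bag of features

Per modality, k-means (k-means++ init, fixed seed, run to convergence)
clusters the training-image features into k visual words; images are
encoded as L1-normalized nearest-word histograms. Defaults: k = 800 per
modality (joint descriptor length 1600), read as *per-dictionary* size
since the two dictionaries are built independently; the reference
synthetic experiment uses k = 64 per modality, matched to its much
smaller corpus (≈ 8 000 color patches and ≈ 4 000 SURF descriptors from
126 training images). Dictionaries are fit on training images only; test
images are encoded against the frozen vocabulary. L1 normalization makes
histograms comparable across images with very different SURF point
counts; an image with no features in a modality encodes to the all-zero
histogram rather than failing.

## Low-rank fusion

The joint descriptors (columns of Y, dimension d = k_color + k_surf) are
split into Y = X + E by minimizing ‖X‖\* + λ‖E‖₁, solved with the inexact
augmented-Lagrangian schedule μ₀ = 1.25/‖Y‖₂, μ ← 1.5μ, alternating
singular-value thresholding (X) and soft thresholding (E) with a dual
update, stopping at ‖Y−X−E‖_F/‖Y‖_F ≤ 10⁻⁷ (cap 500 iterations, warning
flag on non-convergence). The solver is scaling-equivariant and its
planted-model recovery (rank 5 + 5 % sparse, 200×200, λ = 1/√200,
relative error < 10⁻³, recovered rank exactly 5) is tested over several
seeds. Note the raw objective is *not* monotone along ALM iterates
started from X = E = 0 — infeasible early iterates under-count it and it
rises toward the constrained optimum — so solver correctness is asserted
via feasibility, residual decrease, and the converged objective beating
feasible reference points, not via objective descent.

**λ for histograms.** The classical λ = 1/√max(d, n) targets gross sparse
corruption. Joint word histograms have entries of order 1/k with
structured variation, and at that λ the sparse term absorbs ≈ 30 % of all
entries, collapsing X essentially onto the class-mean subspace (rank ≈ 5)
and destroying discriminative detail — held-out accuracy drops below a
no-fusion SVM. The pipeline therefore defaults to λ = 4/√max(d, n),
which keeps E genuinely sparse (≈ 1 % of entries) and the 99 %-energy
rank at ≈ 55 of 128. `rpca_decompose` itself keeps the classical default.

**Two consumption modes.** The default is transductive and follows the
program as printed: decompose the *full* descriptor matrix (train + test
columns) jointly and classify the denoised low-rank coordinates; no
labels are involved, so no supervised information leaks, but test images
must be present at decomposition time. The inductive alternative
(`transductive=False`) decomposes the training matrix only, extracts the
orthonormal basis of the smallest rank capturing 99 % of the squared
singular values of X, and projects training and test descriptors onto it
— this is what `PipelineModel.predict` uses for images unseen at fit
time. In synthetic validation the transductive mode was the more
consistent of the two, which motivated the default.

## Classification and evaluation

Features are z-scored with training statistics and classified by an RBF
SVM, one-vs-one multiclass, with C ∈ {0.1, 1, 10, 100} and
γ ∈ {2⁻⁴ … 2²}/p selected by stratified 5-fold cross-validation on the
training partition only (leave-one-out, the k = n special case, is
available but slow and opt-in). Per-class decision scores come from
one-vs-rest vote-margin aggregation of the pairwise machines and feed the
PR curves. The stratified split sends round(0.7·n_c) of each class to
training — 197 of 281, reproducing the canonical 591/252 partition.

Confusion matrices put predicted classes on rows and actual classes on
columns (many toolkits transpose this). Accuracy = 100·trace/total;
precision is row-wise, recall column-wise; percentages compared against
one-decimal published tables are rounded half-up. Average precision is
the step-wise (non-interpolated) area Σ precision·Δrecall over every
distinct score threshold, cross-checked against an independent library
implementation in the tests; mAP is the unweighted three-class mean.

## Synthetic data: what it emulates, and what it does not

Each image is an anti-aliased ellipse kernel (random axes, eccentricity
0.68–0.88, orientation, mild outline waviness) with a yellowish coat,
radial shading, smooth speckle, on a near-black background, quantized to
8 bits. Grade semantics:

* **good** — intact smooth coat; interior luminance never falls below
  0.35 by construction.
* **moderate** — 1–2 thin dark crack curves anchored near the kernel
  center (width 0.9–1.8 px, 50–75 % luminance drop), or with probability
  0.3 a coat-break patch exposing brighter cotyledon.
* **unhealthy** — a decay discoloration (mix 0.60–0.85 toward green-brown
  at *preserved luminance*, plus mild dulling 0.88–0.97) and 2–3 of:
  fine shrivel ridges (sinusoidal, 0.15–0.25 cycles/px, so the dark
  stripes match crack widths), mold bloom spots (luminance-matched
  green), a bite notch, strong outline deformation.

The defect geometry is deliberately arranged so the two modalities carry
complementary information, as they do on real seeds: the decay
discoloration has no intensity gradient, so SURF (luminance-based,
L2-normalized descriptors) is blind to it, while the ridge/crack overlap
makes moderate-vs-unhealthy the natural confusion of the texture
modality. Consequently color-only baselines resolve unhealthy but
confuse good/moderate, SURF resolves good/moderate but confuses
moderate/unhealthy, and only the fusion resolves all three — the same
qualitative ordering reported for the real-image study this package's
design follows. Every defect drawn is logged per image, and generation
is bit-deterministic: image i of grade g derives its RNG from
(seed, grade index, i).

Not emulated: scanner optics, specular highlights, hilum and embryonic
axis detail, dust, inter-cultivar variation, or the long tail of real
defect morphology. Passing the synthetic experiments demonstrates that
the pipeline's machinery is correct and that fusion exploits
complementary modalities; it does not certify field accuracy on real
seed lots.

## Reference experiment and observed variability

The reference experiment (tests and `scripts/acceptance.py`) uses 60
images per grade at 128 px, k = 64 words per modality, a stratified
70/30 split (126/54) and all four baselines; it completes in a few
minutes on one CPU core. Problem sizes were chosen so the whole suite
runs comfortably on a laptop-class machine while keeping every stage
statistically meaningful. With a 54-image test set one sample is 1.85
accuracy points, so held-out numbers move by a few points across
generator seeds: across seven seeds the joint model scored 88.9–96.3 %
(≥ 90 % on five, ≥ every baseline on six), with baselines at 51.9–79.6 %
(color) and 85.2–96.3 % (SURF). At the package-default seed 0 the run
reported in the README gives JMBoF 94.4 % vs best baseline 87.0 %.

## Known limitations

* The SURF margin policy (skip points whose oriented window leaves the
  image) discards outline points near image borders; large-scale points
  on small images may yield no descriptor at all.
* Transductive fusion requires the full image set at decomposition time;
  deployment-style grading of a stream of new images uses the inductive
  basis projection, whose accuracy was slightly less consistent in
  validation.
* Hue is encoded linearly in [0, 1) for the HSI baseline, so the red
  wrap-around is split across the k-means metric — a known weakness of
  that baseline, kept for comparability.
* Leave-one-out model selection on hundreds of samples is quadratically
  expensive and therefore opt-in; the default is 5-fold.
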