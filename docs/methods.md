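# Methods

This note records the models, conventions and numerical choices behind
`nir2dcos`, and what the synthetic-data experiments do and do not show.

## Generalized 2DCOS on a two-row series

For a perturbation series of m spectra stacked as rows of Y (m × n), the
synchronous and asynchronous correlation intensities between wavenumbers
v₁ and v₂ are

    Φ(v₁, v₂) = Y(v₁)ᵀ · Y(v₂) / (m − 1)
    Ψ(v₁, v₂) = Y(v₁)ᵀ · D · Y(v₂) / (m − 1)

where Y(v) is the column of intensities at wavenumber v across the series
and D is the Hilbert–Noda transformation matrix, D_jk = 0 on the diagonal
and 1/(π(k − j)) off it. The integrated map is W = Φ ∘ Ψ elementwise. Φ is
symmetric with non-negative diagonal auto-peaks; Ψ is antisymmetric with a
zero diagonal and vanishes when the series rows are in phase (identical up
to scale-free alignment).

Here the series is {class-mean spectrum, individual spectrum}, so m = 2
and each labelled sample yields one map of each type per grouping
(drying method, region). Class labels are therefore required when maps
are built — including for test and external samples — and partitioning is
done afterwards on the finished images; this mirrors a workflow in which
the map construction is part of feature extraction, not of inference.

**No mean-centering by default.** The equations are applied to raw
intensities. With m = 2, column-centered rows are exact negatives of each
other, which makes Ψ identically zero; since the asynchronous maps of this
construction are decidedly nonzero, the literal (uncentered) form is the
operative one. A `center` flag exists for m > 2 use.

**Numerical form.** For m = 2 the maps are computed as outer products
(Φ = y₁⊗y₁ + y₂⊗y₂, Ψ = (y₁⊗y₂ − y₂⊗y₁)/π), which makes symmetry,
antisymmetry, the zero diagonal and the in-phase zero map exact in
floating point rather than approximate. For general m the matrix form is
used and (anti)symmetrized, which stays within 1e-12 of the elementwise
definition.

**Grid decimation.** Maps are built on a uniform-stride subset of the
1501-point grid (default ≤ 512 points; the imaging transformer defaults to
64 for 64 × 64 rasters). Decimation is pure index selection, so decimated
maps equal the corresponding sub-block of full-grid maps exactly.

**Rendering.** Rasters are deterministic: symmetric min/max scaling about
zero by the per-image absolute maximum, bilinear resize, 256-level
colormap lookup (default jet-like), no axes or margins. An all-constant
map has no scale and renders as the uniform mid-colormap colour. Rendering
resolution, colormap and scaling are configuration; nothing in the method
depends on a particular aesthetic.

## Synthetic spectra generator

The generator emulates the statistical structure of baseline-corrected
FT-NIR absorbance spectra of dried leaf powder on the descending
10,000 → 4,000 cm⁻¹ grid at 4 cm⁻¹ (1501 points):

* a shared Gaussian band inventory — 8300 cm⁻¹ (C–H second overtone),
  6881 cm⁻¹ (O–H first overtone), 5775 cm⁻¹ (C–H of R-OHCH₃), 5172 cm⁻¹
  (water O–H) and three carbohydrate combination bands at 4750, 4400 and
  4100 cm⁻¹; widths and amplitudes are configuration;
* multiplicative, window-scoped class factors. Drying factors interpolate
  linearly between a high-wavenumber value (≥ 7,000 cm⁻¹) and a
  low-wavenumber value (≤ 6,000 cm⁻¹); defaults give the orderings
  40 °C > sun > shade > 60 °C above 7,000 cm⁻¹ and 60 °C > shade > sun >
  40 °C below 6,000 cm⁻¹. Region factors do the same with the low window
  below 5,350 cm⁻¹ and Shaanxi highest there; each region gets a distinct
  (high, low) pair so seven classes are geometrically distinguishable.
  A `separation` exponent scales all factors (f^separation): 1 is the
  default realism level, `GeneratorConfig.strong()` (separation 4, noise
  0.001, scatter 0.005) is the strong-separation regime used in the
  desk-scale recovery experiments;
* noise: per-sample multiplicative scatter (default sd 0.02), additive
  absorbance noise (default sd 0.002), and a deterministic site-level
  multiplicative effect (default sd 0.01) hashed from the site name so it
  is independent of sample order.

Only the *orderings* of the real class intensity differences are known,
not their sizes, so effect magnitudes are free parameters and real-data
metric tables are not reproduction targets. The default manifest
reproduces the study's sampling frame: 534 samples, 7 regions, 16 sites,
4 drying methods (136/133/132/133 per method). One printed per-site row is
internally inconsistent with its row total; the default resolves it in
favour of the stated per-method class totals.

Each sample draws from a counter-derived substream
(`default_rng([seed, row_index])`), so generation is order-independent and
fully reproducible.

What passing tests on this generator show: the pipeline's machinery —
map construction, rendering, splitting, training, evaluation — recovers
known class structure when it is present, with the expected ranking
(synchronous ≥ asynchronous/integrated; CNN ≥ linear baseline on ordered
multiplicative classes). What they do not show: performance on real leaf
spectra, whose within-class covariance (instrument drift, particle-size
scatter curvature, water-band interactions) is richer than multiplicative
jitter plus white noise.

## Kennard–Stone splitting

The classic deterministic algorithm: seed with the pair at maximal
Euclidean distance, then repeatedly add the candidate maximizing its
minimum distance to the selected set. Ties break to the lowest index; if
all pairwise distances are zero the seed pair is (0, 1). Splits are
stratified per class — the percentages apply within each drying method or
region — with round-half-up allocation and the remainder absorbing
rounding error: 60/30/10 for the image pipeline, 70/30 for PLS-DA.
Distances are computed on (decimated) spectra for both schemes, so the two
pipelines share one selection geometry. The three-way scheme requires at
least 3 samples per class, the two-way scheme 2.

## PLS-DA baseline and validation suite

PLS2 regression (NIPALS, via scikit-learn's `PLSRegression`) of a one-hot
class matrix Y on the mean-centered spectral block; unit-variance scaling
is behind a flag, off by default. Hard labels are the row argmax of the
predicted Y, ties to the first class in sorted order. Per-class metrics
are one-vs-rest: SEN = TP/(TP+FN), SPE = TN/(TN+FP),
ACC = (TP+TN)/(TP+TN+FP+FN), plus ROC/AUC (Mann–Whitney form, tied scores
count half).

RMSEE is the root mean square error of the fitted Y-block; RMSECV its
k-fold cross-validated counterpart; R² and Q² the corresponding
1 − SS_res/SS_tot. One scalar per model, computed jointly across all Y
columns. Cross-validation uses venetian-blind fold assignment after
class-stratified ordering (default 7 folds), which is deterministic and
spreads every class across folds; a class with a single member can never
be covered and is rejected up front. The label-permutation test (default
200 iterations) records (|corr(Y_perm, Y)|, R², Q²) per permutation plus
the unpermuted reference at correlation 1, and reports the intercepts of
least-squares lines through all points at correlation 0.

Latent-variable count is chosen by maximum cross-validated Q² with a
parsimony tolerance: the smallest count whose Q² is within 0.01 of the
maximum. Without the tolerance, CV noise of order 1e-3 routinely buys an
extra uninformative component.

A linear caveat worth knowing: when classes form an ordered intensity
family (as the four drying methods do), argmax classification of a
one-hot linear regression masks middle classes — accuracy saturates well
below 1 regardless of components. This is a property of the model class,
visible in both the synthetic experiments and the low sun-drying
sensitivities such baselines report on real data, and it is exactly the
gap the image-CNN route closes.

## The 12-layer residual CNN

Architecture: stem (3×3 conv, 16 channels → BatchNorm → ReLU), then
identity, identity, conv, identity, conv, identity blocks, then global
average pooling → flatten → fully-connected head. An identity block is
x + F(x) with F = conv-BN-ReLU-conv-BN at constant width; a conv block
halves the spatial size and doubles the width through a 3×3 stride-2 main
conv + BN, added to a 1×1 stride-2 shortcut conv + BN. Depth accounting —
stem (1) + 4 identity blocks × 2 convs (8) + 2 conv-block main convs (2) +
fully-connected (1) = 12 — counts weighted layers on main paths; shortcut
1×1 convs and pooling are not counted. This is the unique assignment
consistent with the stated block census and total depth. Channel plan,
kernel size and input resolution are open configuration with these
documented defaults; 64 × 64 inputs are the desk-scale default (224 × 224
works unchanged, at proportionally higher cost).

Training: plain SGD (no momentum, available as config), cross-entropy in
numerically fused softmax form, learning rate 0.01, weight decay 1e-4
applied to conv/FC weights only, batch size 16, no augmentation.
Initialization is He-normal (convs) / Xavier-uniform (FC) from one seeded
stream that also drives epoch shuffling, so training is bit-reproducible
given `random_state`. The exponential curve smoothing (0.6) exists purely
for plots; stored traces are raw. The engine is an in-package numpy
implementation (im2col convolution, explicit backward passes) validated
against central-difference gradients on smooth sub-networks.

Loss monotonicity is not asserted anywhere; the tested property is that
the final training loss falls below the initial one and that strongly
separated classes are fit to 100 % training accuracy within the epoch
budget.

## Problem sizes used

The recovery experiments run at desk scale deliberately: 120 samples
(4 drying classes × 30), 64 × 64 synchronous images, ≤ 30 epochs —
enough for the perfect-classification regime of the strong-separation
generator while keeping a full run in minutes on one CPU core. The
3204-image count identity uses the full 534-sample manifest at 32 × 32.

## Known limitations

* The generator's noise model is multiplicative scatter + white noise;
  real NIR residual structure (baseline curvature, correlated noise,
  water-vapour lines) is absent by design.
* PLS-DA class masking on ordered classes (above) caps the linear
  baseline's multiclass accuracy; this is faithful to the model class,
  not a defect of the implementation.
* m > 2 perturbation series are supported and unit-tested for the
  algebraic identities, but no scientific claims are made for them.
* The CNN engine is CPU-only and sized for small studies; it is not a
  general training framework.
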