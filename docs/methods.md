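# Methods

This note records the models, numerical choices and limitations of the
`osteosae` pipeline in the order data flows through it.

## Pre-filtering

Both smoothers are weighted averages over a truncated window of half-width
`radius` (default `ceil(2·sigma_s)`), renormalised per pixel over the
in-image part of the window. No padding is ever introduced, so every output
pixel is a convex combination of input pixels and outputs are bounded by the
input range.

The kernel convention is `exp(-d²/σ²)` — **without** the factor 2 of the
textbook Gaussian — for both the spatial term (`σ_s`, pixels) and the range
term (`σ_r`, intensity units in [0, 1]). A `sigma_s` here equals
`σ/√2` in the usual parameterisation. The bilateral range term compares the
input intensity at the centre pixel with the guide intensity at the
neighbour; with no guide the filter is self-guided, the classic single-image
bilateral form. As `σ_r → ∞` the bilateral filter converges to the Gaussian
(verified to < 1e-6 at `σ_r = 1e6`).

Contrast enhancement defaults to CLAHE (clip limit 0.01, 8×8 tiles), the
common choice for stain-variable histology; global histogram equalisation
and a min-max stretch are selectable. Constant images pass through
unchanged, avoiding division by zero. Note that any per-patch contrast
normalisation deliberately removes absolute-intensity cues; on synthetic
patches whose classes differ partly by mean brightness this can cost
accuracy (the pipeline config can set `enhance: none`).

Whether "pre-processing" means the pure Gaussian or the bilateral form was
genuinely open; both are implemented and the pipeline default is the
self-guided bilateral filter, the better fit for edge-rich histology.

## Feature extraction

The extractor follows the SqueezeNet v1.1 layout — strided 3×3 stem
convolution, three max pools, eight fire modules — implemented as a NumPy
forward pass (im2col convolutions). A fire module squeezes to a narrow 1×1
bottleneck and expands through parallel 1×1 and 3×3 branches whose outputs
concatenate; replacing 3×3 with 1×1 kernels wherever possible divides that
layer's weight count by 9, which keeps the default 3-class network at
724,035 parameters (about 80× smaller than an AlexNet-scale 60 M).

The network is used **frozen**: transfer-learning style, features are the
global-average-pool activations (512 per image). Weights come from a seeded
He-normal initialisation by default, or from an imported container (mapping
or `.npz`) validated layer-by-layer against the spec. Random frozen
convolutional features are a standard, surprisingly strong baseline for
texture discrimination; they are what makes the pipeline runnable with no
pretrained weights available. Only the softmax head is trainable in-package
(mean cross-entropy, mini-batch gradient descent); the convolutional trunk
has no backward pass — it is a feature extractor, not a trainable CNN.

Images are resized bilinearly to the configured input size (default
128×128; 227×227 selectable for compatibility with common pretrained
containers) and grayscale patches are replicated to three channels.

## The DSSAE classifier

Each sparse autoencoder (SAE) uses log-sigmoid coding and decoding, so its
inputs must live in [0, 1]: the feature matrix is min-max scaled per
dimension with a scaler fitted on the training split only. The loss is

    L = (1/N) Σ_i ||z_i - y_i||^2 + c_s · Σ_j KL(ρ || ρ̂_j) + c_w/2 · (||W_Y||_F^2 + ||W_Z||_F^2)

with ρ̂ clipped to [1e-8, 1-1e-8] so dead or saturated units cannot make
the KL infinite. Defaults: ρ = 0.05, c_s = 1.0, c_w = 1e-4, hidden sizes
(256, 128, 64, 32). The analytic gradient of all three terms is checked
against central finite differences (relative error < 1e-5) — the central
correctness gate for everything downstream.

**Inter-layer code rescaling.** Greedy stacking trains SAE *k* on the codes
of SAE *k−1*. The codes of a sparsity-regularised layer concentrate near ρ,
so their dynamic range is a small fraction of [0, 1]; fed raw into the next
layer, the reconstruction term becomes trivially small, the KL term
dominates, and deep codes collapse to the constant ρ — erasing the class
signal entirely (empirically: majority-class predictions from layer 2
onward). Each layer's codes are therefore min-max rescaled to [0, 1] per
unit (scalers fitted on training data, stored on the model) before feeding
the next layer and the softmax head. With rescaling the same defaults
separate 6-σ Gaussian classes to 0% training error.

**Optimisation.** All layers and the softmax head are trained with Møller's
scaled conjugate gradient (σ = 1e-5, λ₀ = 1e-7): conjugate directions with
a Levenberg–Marquardt-style scaling, no line search. `epochs` caps the SCG
iteration count per layer. `batch_size ≥ N` selects full-batch training
(the default and recommended mode); smaller values run short (3-iteration)
SCG restarts on shuffled mini-batches under the same total iteration
budget — a stochastic approximation that trades stability for cheaper
steps. `learning_rate` only affects the optional plain-gradient-descent
fine-tuning pass over the softmax head (off by default). Softmax argmax
ties break toward the lowest class index for determinism.

Serialisation is a single `.npz` with a JSON header entry (schema version,
dims, hyperparameters, class names, seed) and round-trips bit-exactly.

## Wind Driven Optimization

Candidates ("air parcels") carry position and velocity in the normalised
box [−1, 1]^D; pressure = fitness, lower is better, and parcels are ranked
1…N each iteration (ties by parcel index; non-finite pressure ranks worst
with a warning). The velocity update is the rank form

    u_new = -g x_old + (1-α) u_old + |1 - 1/k| RT (x_max - x_old) - c u_old[d'] / k

where `x_max` is the current rank-1 parcel's position and `d'` is, per
dimension, one uniformly chosen *other* dimension (the same dimension in
1-D) — the standard Coriolis surrogate. The historical pressure-ratio form
of the update is documented but not used: normalising by raw pressures
makes step sizes depend on the fitness scale, which is why the rank form
exists. Velocities clamp elementwise to ±max_velocity; positions advance by
one unit time step and clip to the box, zeroing the violating velocity
component (reflection is available as an option).

Defaults α = 0.4, g = 0.2, RT = 3.0, c = 0.4, max_velocity = 0.3,
population 20, 50 iterations; these follow the WDO literature and are all
config-exposed. `RT = 0` is accepted so the pressure-gradient term can be
ablated; on a sphere shifted off the origin the ablation demonstrably
degrades convergence (on the *centered* sphere the gravitation term alone
solves the problem, which is worth knowing when benchmarking). The
best-so-far fitness is non-increasing by construction and the whole loop is
reproducible from its seed. A failed objective evaluation scores the parcel
at the worst fitness (100) rather than aborting the search.

For hyperparameter tuning, the search space defaults to epochs (log-spaced
integer grid 20…200), batch size {8, 16, 32, 64, full} and learning rate
(log-uniform 1e-4…1e-1); grid dimensions decode by nearest cell. The
objective trains a DSSAE on a stratified 75/25 sub-split of the training
data and returns the held-out error rate; the best configuration is
retrained on the full training split. On a coarse discrete grid a larger
max_velocity (≈0.6) helps parcels cross cell boundaries.

## Synthetic data

The image generator emulates the three appearance regimes with
parameterised random ellipse fields plus Gaussian blur: VT = many small
dark ellipses on a bright background (nuclei-dense), NVT = sparse larger
low-contrast blobs (necrotic fragmentation), NT = smooth low-frequency
background. `separability` ∈ [0, 1] linearly interpolates every texture
parameter between a common midpoint (classes indistinguishable) and the
fully distinct settings; additive Gaussian pixel noise (default sd 0.02) is
applied last. Default class counts 345/263/536 mirror the benchmark
imbalance so the imbalance-sensitive metrics (G-mean, MCC) are exercised
realistically. At separability 0 a trained pipeline sits at the ~33%
3-class chance level; accuracy is non-decreasing in separability.

The feature generator draws Gaussian mixtures whose class means sit on
orthogonal directions at a controllable pairwise distance in units of
within-class sd (isotropic or random-SPD covariance). At separation 6 the
Bayes error is small but not zero: roughly one borderline sample per few
hundred draws, so a single draw can make 0% held-out error unattainable for
*any* hyperparameter setting — which is why multi-draw medians are reported
where that matters.

What passing tests on these generators does **not** show: robustness to
H&E stain variation, scanner artefacts, class-boundary ambiguity of real
necrosis, or patch-level label noise. The generators are controllable
stand-ins for the input *regime*, not for osteosarcoma morphology.

## Pipeline and reproducibility

A run is fully determined by its `PipelineConfig` (data source, filtering,
network, classifier, tuning, split preset, seed); the resolved config is
written next to the outputs so any artifact can be regenerated. One global
seed fans out to per-stage seeds via `SeedSequence([seed, stage_index])`
with fixed indices (data 0, network 1, training 2, tuning 3, split 4), so a
stage can be re-run in isolation and still match the full run. Both 80/20
and 70/30 stratified split presets are first-class. Two identically-seeded
runs write byte-identical summary JSON.

Metric tables carry full precision internally; the two-decimal rendering is
presentation only. Zero-denominator conventions: F-score, MCC and G-mean
return 0. G-mean is √(sensitivity × specificity); per-class accuracy is the
one-vs-rest accuracy (TP+TN)/total — these are the definitions consistent
with every row of the published benchmark tables kept in
`osteosae.reference`, which is also why each class carries its own accuracy
value there.

Problem sizes in the test suite and acceptance script (e.g. 60 patches per
class at 128×128 for the end-to-end check, 10 seeds for optimizer medians,
three draws for the tuned-validation median) are chosen as the smallest
sizes at which each property is stable and meaningful on a single CPU.

## Known limitations

* No convolutional backpropagation: the feature network cannot be
  fine-tuned in-package, only its softmax head.
* Mini-batch SCG is a pragmatic approximation; the optimiser's convergence
  theory assumes full batches.
* The undocumented extra input-stage layer mentioned alongside the original
  classifier's description ("PZM layer") has no published definition and is
  not implemented.
* Fast O(1) bilateral approximations, denoising/variational autoencoder
  variants, GPU training and multi-objective WDO are out of scope.
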