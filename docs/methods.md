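# Methods

## The expressivity score

Expressivity of a layer for a scalar attribute is the estimated mutual
information (MI) between the layer's feature vectors `F ∈ R^{n×d}` and the
attribute `A ∈ R^n`, in nats. MI is the KL divergence between the joint
distribution of `(f, a)` and the product of its marginals; we estimate it
with the Donsker–Varadhan (DV) variational bound

    I(F; A) ≥ E_P(f,a)[T(f,a)] − log E_P(f)P(a)[e^{T(f,a)}],

tightened by gradient ascent over a neural critic `T` that scores matched
pairs high and mismatched pairs low (MINE). Both expectations are
mini-batch estimates of size `b`:

* **joint term** — the mean critic score over matched pairs `(f_i, a_i)`;
* **marginal term** — the log of the mean of `exp T` over mismatched pairs
  `(f_i, a_j)` with `i ≠ j`. The mismatch is a *derangement* (a cyclic
  shift of a shuffled batch order): exactly `b` pairs, no fixed points,
  every index used once on each side, so the empirical mismatch
  distribution is the product of the two within-batch marginals.

The training loss is the negative DV bound. The gradient of the
log-marginal term divides by the batch mean of `exp T`, a high-variance
quantity at small `b`; following standard MINE practice we replace that
denominator with an exponential moving average (decay 0.99) of the batch
means, kept in log space so large scores cannot overflow. The EMA enters
the gradient only — every *reported* bound uses the raw batch or full-data
term, so the score remains a pure DV estimate.

### Critic and optimizer

The critic is an MLP mapping the concatenated `(f, a)` vector (width
`d + 1`) to one scalar: hidden layers 256 → 64, ELU activations, Xavier
(Glorot-uniform) initialization, Adam at learning rate 1e-3, batch 100.
Two ablation variants are first-class configs: shallow (one 256 layer) and
deep (512 → 256 → 64). Features and continuous attributes are z-scored
before entering the critic (MI is invariant to invertible affine maps, so
the target quantity is unchanged; standardization only conditions the
optimization); binary attributes stay 0/1. Feature columns with
numerically zero variance are excluded before fitting.

### Held-out early stopping (and why)

A critic trained and evaluated on the same samples memorizes matched
pairs, and the DV bound computed on those samples drifts upward without
limit — on *independent* 16-dimensional features and n = 5000 we measured
spurious "MI" of 0.15–0.27 nats after 120+ epochs, while the bound on
held-out samples drifted symmetrically negative. The trainer therefore
holds out 20% of the samples from every gradient step, evaluates the DV
bound on that hold-out after each epoch, and stops when it has not
improved by at least 1e-3 nats for 20 consecutive epochs (cap: 200
epochs). The reported score is a fresh full-dataset evaluation (new
derangement over all n samples) at the best-held-out-bound parameters.
Under this rule the independence null is estimated at |MI| < 0.02 nats and
the Gaussian closed form is recovered within tolerance (below). When
fewer than two hold-out samples are available the trainer falls back to
stopping on the full-data bound.

### Multi-seed protocol

One expressivity value is the arithmetic mean of M = 10 independent fits
with seeds `seed₀ … seed₀+M−1`; the spread over seeds is reported as the
sample standard deviation. Every stochastic element — initialization,
epoch shuffling, derangements, the hold-out split — derives from the fit
seed, so results are exactly reproducible. Slightly negative estimates
(expected noise when the true MI is ~0) are reported raw with a warning
flag; clipping to zero would hide estimator failure.

## Validation oracles

* **Continuous Gaussian channel.** For jointly Gaussian `(F, A)` with
  correlation ρ, `MI = −½·ln(1−ρ²)` exactly. The estimator is required to
  match this within max(10% relative, 0.05 nats) at n = 5000, M = 10, for
  ρ ∈ {0.3, 0.6, 0.9}, and to stay within ±0.05 nats of zero for
  independent inputs (d = 16, both attribute kinds).
* **Binary channel.** For `A ~ Bernoulli(p)` injected into one feature
  coordinate with gain g and Gaussian noise, no closed form exists;
  `h(Y)` is computed by adaptive quadrature (scipy `quad`, interval ±10
  noise SDs around the component means) over the two-component mixture
  density, cross-checked in the tests against a 200k-sample Monte-Carlo
  entropy estimate.
* **Ordering.** Five attributes injected into separate coordinates at
  true MI {1.0, 0.6, 0.35, 0.2, 0.05} nats (sex on the binary channel,
  gain found by bisection of the quadrature MI) must be ranked correctly
  by the estimated means in ≥ 9 of 10 repetitions, and identically by the
  shallow/default/deep critic variants.

## Synthetic cohort and images

The cohort table emulates an echocardiography-annotated chest-radiograph
dataset: age ~ truncated normal (mean 62 y, SD 14 y, range 18–95); sex ~
Bernoulli(0.5); each left-ventricular dimension (cm) a linear model in age
and sex plus Gaussian noise (IVSDd intercept 0.85, slopes 0.004/y and
0.10 for male sex, noise SD 0.22; LVPWDd 0.82/0.004/0.08/0.20; LVIDd
4.80/−0.005/0.25/0.45); SLVH = 1 iff IVSDd or LVPWDd exceeds its
sex-specific threshold (IVSDd 1.35/1.45 cm for female/male, LVPWDd
1.30/1.40 cm). These values are synthetic conveniences chosen once for
physiological plausibility (dimensions in the echocardiographic normal
range, thresholds near upper reference limits, label prevalence ≈ 0.23);
they are estimates of no real cohort and live in one config file.

Rendered images place an annular "cardiac" structure in a noisy field.
The septal (upper) and posterior (lower) half-ring thicknesses track
z-scored IVSDd and LVPWDd separately — the label rule is an OR over the
two walls, so collapsing them into one pooled thickness would cap the
Bayes-achievable AUROC near 0.90; rendering them separately (also the
anatomically faithful choice) raises the measured ceiling to ≈ 0.98.
Inner radius tracks LVIDd, outer silhouette radius tracks age, and a
left/right brightness asymmetry encodes sex. Each image receives a
per-image exposure gain (SD 0.18) and brightness offset (SD 0.06) plus
pixel noise (SD 0.08). The exposure jitter is essential to the layer-depth
phenomenon: without it, global mean intensity alone encodes wall thickness
(ring area grows with thickness) and a single pooled convolution already
reads the attribute; with it, shallow intensity statistics are
uninformative and the attribute must be recovered from local geometry, as
in real radiographs where exposure varies per acquisition. Attribute
z-scores are clipped at ±3 before scaling so extreme draws cannot push
the geometry outside the frame.

What the generator does **not** model: real thoracic anatomy, projection
physics, inter-patient positioning variation, comorbidities, or any
correlation structure beyond the linear age/sex effects. Passing tests
therefore demonstrate estimator correctness and pipeline soundness on
controlled ground truth — not clinical performance on radiographs.

## Classifiers and feature taps

The desk-scale convolutional backbone is three stride-2 3×3 conv stages
(16/32/64 channels, ReLU), global average pooling, and a fully connected
head 128 → 64 → 1 with ReLU and dropout 0.3, trained end-to-end with
binary cross-entropy (Adam, weight decay 1e-5, batch 32, ≤ 10 epochs,
best-validation-AUROC checkpoint kept). The default learning rate is
1e-3: the desk-scale network trains from scratch, where 1e-4 (the
conventional choice when fine-tuning a large pretrained network) is
needlessly slow; a full-size fine-tuning run should set 1e-4 explicitly.
The transformer backbone is a frozen ViT-style encoder (8×8 patches,
embed 64, 4 pre-LN blocks, 4 heads, class token) with a trainable MLP
head on the [CLS] vector (warmup + cosine schedule); only the head
receives gradients, and an unfrozen transformer is deliberately
unsupported. A weights-path hook accepts externally pretrained encoders.

Feature taps: convolutional stages are reduced by global average pooling
(matching the network's own final pooling and keeping d modest for the
critic); transformer taps return the class-token vector after the block
(pooled patch tokens available as an option). Early/mid/final map to
stage 1 / stage 2 / stage 3 for the conv net and blocks ⌈L/6⌉ / ⌈L/2⌉ / L
for the transformer. Extraction always runs in evaluation mode, so
repeated calls are bit-identical.

## Evaluation machinery

AUROC is the Mann–Whitney statistic (ties get half credit); AUPRC is
step-wise average precision without interpolation (both via scikit-learn,
cross-checked in the tests against exhaustive pair enumeration and hand
step-integration). Confidence intervals are seeded nonparametric
percentile bootstraps over (score, label) pairs, 2000 resamples by
default; single-class resamples are redrawn with a bounded retry budget.
Balanced subsets keep the minority class whole and down-sample the
majority without replacement, independently per split; an optional
patient-grouping vector keeps all images of a patient in one split.

## Pipeline reproducibility

A single YAML config drives simulate → balance → train → extract →
expressivity → evaluate → report. Every stage seed is a SHA-256 hash of
the global seed and the stage name (reduced mod 2³¹), so one integer
reproduces the whole run byte-for-byte; a manifest records output hashes
and lets unchanged stages be skipped. Reports carry no timestamps, making
two runs of the same config byte-identical.

## Problem sizes used in the validation suite

Gaussian recovery and the independence null run at the stated n = 5000
with M = 10 seeds. The ordering experiment runs at n = 2000 with M = 2
seeds per attribute and a 120-epoch cap (patience 12): the injected MI
gaps (≥ 0.15 nats) are an order of magnitude above the seed spread at
this size, so additional seeds buy nothing. The end-to-end runs use 2000
rendered 64×64 images and ≤ 10 training epochs; the depth-trend check
repeats that full run over 10 training seeds with M = 2 critic seeds per
tap. These sizes are the package's desk-scale defaults; all are
overridable in config.

## Known limitations

* DV/MINE estimates are lower bounds with finite-sample bias; absolute
  values across attributes with very different marginal entropies are not
  directly comparable (binary attributes are capped at H(p) ≤ ln 2).
  Layer-to-layer and attribute-ranking comparisons are the intended use.
* The held-out stopping rule trades a small downward bias (it refuses to
  chase the overfitting regime) for null calibration; with very small n
  (< ~500 samples) the hold-out bound is noisy and estimates degrade.
* The toy renderer supports controlled validation only; no claim about
  real chest radiographs follows from it.
* Other MI estimators (KSG, InfoNCE, NWJ), conditional MI, and
  multivariate attributes are out of scope.
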