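# Methods

## Stimulus model

A trial's stimulus starts from a raw grayscale image p ∈ [0,1]^{32×32}
and is processed as

    x = clamp(2·μ·p − 1 + ε, −1, 1),   ε ~ N(0, σ²) i.i.d. per pixel,

i.e. contrast scaling by μ, normalization to [−1,1], additive Gaussian
pixel noise, and a hard-tanh threshold. σ is treated as the noise
*standard deviation* on the [−1,1] pixel scale; values like σ ∈ [1,2]
or σ = 3.75·μ only make sense as scale parameters there, but a
`sigma_is_variance` switch provides the variance reading. Superimposed
stimuli combine two contrast-scaled images by an element-wise maximum
*before* noise is added, so the compound stimulus receives one noise
field.

Training regimes sample per-trial (μ, σ): standard (μ ~ U[0.1,1],
σ ~ U[1,2]), fixed-μ (μ = 0.5), fixed-σ (σ = 1.5), fixed ratio
(σ = 3.75·μ), and the Gabor/RL regime (σ ~ U[0.5,1]). Gabor patches are
cosine gratings (0.3 cycles/px, phase zero at the image center,
orientation ±5° from vertical) in a centered Gaussian envelope
(sd 4 px), rescaled to [0,1]. Phase and orientation-sign conventions are
not externally constrained; the chosen ones make the two tilts exact
mirror images.

## Synthetic data

Because the pipeline must run without downloads, two generators supply
the data:

* **Image classes.** Two fixed prototypes (a shared Gaussian blob blended
  with class-specific oriented double-bar patterns; blend weight
  s/(s+2) for separation s) with per-sample random affine warps
  (rotation ±8°, translation ±2 px, scale 0.9–1.1) and amplitude jitter
  (N(1, 0.15), clipped). This mimics handwriting-like within-class
  variability: smooth shape deformations around a class template. It does
  *not* emulate natural-image texture, clutter, or multi-factor identity
  variation, so passing tests show that the *mechanisms* (calibration,
  bias, geometry) behave as designed, not that the effect sizes match any
  particular natural dataset.
* **Latent evidence.** Two rotated anisotropic Gaussians in 2-D with
  controllable per-class sd ratio, major-axis angles, and priors. The
  reference configuration (ratio 2.44, axes at 30° and 81.4°, i.e. 51.4°
  apart, class means on their own major axes) matches the latent
  statistics the VAE analysis targets, and is the regime in which optimal
  confidence departs from the balance-of-evidence rule.

## Networks and training

The encoder maps 1×32×32 → 100: three stride-2 3×3 convolutions
(32 channels, batch norm, leaky-ReLU slope 0.01), then fully connected
256 → 128 (batch norm + leaky ReLU) → 100 (linear). Supervised nets add a
classification head (sigmoid p(s2) for two-choice; softmax for
ten-choice) and a sigmoid confidence head trained toward 1 when the
current classification output is correct, 0 otherwise (targets are
recomputed every step from the live class head). Both cross-entropies are
summed; Adam, lr 5e-4, batch 32, 5 epochs by default. The RL variant
replaces the heads with a 3-way actor (LEFT/RIGHT/OPT-OUT) and a linear
critic; actions are sampled during training, rewards are 1/0 for
choices and r_opt-out for opting out, with
r_opt-out = min(accuracy of non-opt-out trials on the previous batch,
0.75), initialized at 0.5. The critic minimizes a Huber loss toward the
reward; the actor loss is −log p(a_t)·δ_t with δ_t = r_t − v_t (δ
treated as a constant). Adam, lr 1e-3, batch 32, 5000 iterations.

Since no deep-learning framework is assumed, the layers live in a small
numpy library with hand-derived backprop (im2col convolutions, transposed
convolutions as the conv adjoint, batch-norm train/eval modes), verified
against central finite differences to ~1e-9 relative error. Weights use
fan-in-scaled uniform initialization U(±1/√fan_in) so results are
reproducible from seeds alone. Evaluation uses running batch-norm
statistics and argmax decisions; for the RL net a trial counts as opt-out
when OPT-OUT is the argmax of all three actions, while the reported
decision is the forced choice over LEFT/RIGHT on every trial (accuracy
gates and calibration use this all-trials forced-choice accuracy; an
opt-out-excluded accuracy is available separately).

## VAE and ideal observer

The denoising VAE reuses the conv encoder trunk, ending in two 2-unit
linear heads for the posterior mean and log-variance; the decoder is
FC 2→128→256 (leaky ReLU) reshaped to 16×4×4 followed by three stride-2
kernel-4 transposed convolutions (32, 32, 1 channels) and tanh. The loss
is the per-image sum of squared errors against the *clean* target (the
contrast-scaled, clamped image before noise) plus the KL divergence of
q(z|x) from N(0, I), both averaged over the batch. Summing the
reconstruction term over pixels (rather than averaging) keeps the KL term
from collapsing the 2-D latent; this weighting is the package's choice.

Class-conditional bivariate Gaussians are fit to the posterior *means* of
labelled images (lower-variance than posterior samples; a switch enables
sampling). The ideal observer computes p(y = s1 | z) by Bayes' rule with
0.5 priors (log-density formulation for numerical stability), decides by
argmax (exact ties, a probability-zero event, go to s1), and reports
confidence = max posterior. Condition-level behavior is evaluated by
Monte Carlo over latent samples from the test condition because the
optimal decision boundary is non-quadratic for unequal covariances.
Geometry statistics treat each class's major axis as an undirected line:
the anisotropy ratio is sd(major)/sd(minor) and the axis separation is
folded into [0°, 90°], which is what makes the statistic invariant to
joint rotations of the latent space; isotropic covariances set a
degenerate flag with angle 0.

## Signal-detection metrics

d′ = z(HR) − z(FAR) with a log-linear correction (all four cells padded
by 0.5) whenever a cell is empty. meta-d′ is fit by maximum likelihood:
confidence is binned into 4 ratings at the record's own empirical
quantiles (already-discrete confidences keep their levels); the
equal-variance meta model places stimulus means at ±meta-d′/2, scales
the type-1 criterion to preserve the observed relative criterion
c/d′, and fits meta-d′ plus ordered type-2 criteria (log-increment
parameterization) to the rating counts conditional on stimulus and
response (Nelder-Mead). Response-specific variants maximize one
response's likelihood only. Forward simulations recover meta-d′ with
median absolute error well under 0.1 at n = 1e5. Late type-2 noise is
applied as logit → +N(0, ξ) → sigmoid with clipping at 1e-6 (ξ is a
variance).

Contrast calibration sweeps a grid, checks the accuracy/d′ curve for an
increasing trend, and linearly interpolates the first upward crossing of
the target; targets below the floor return the minimal contrast with a
warning and targets above the curve raise. Every PE comparison runs an
accuracy-balance gate before any confidence comparison: the mean paired
accuracy difference must be within max(1 percentage point, 2 SE of the
paired difference).

## Experiment battery and problem sizes

The full-scale design (100 replicates, 10,000-image test sets,
100×100 evidence grids) is scaled to desk size: cohorts of 2–3 networks,
synthetic pools of 500–1400 images, 300–3000 evaluation trials, and
12×12 grids in the drivers. These sizes were chosen as the smallest at
which the directional phenomena are stable across seeded replicates; the
dissociation experiment additionally rescales its five target d′ values
into the cohort's achievable range (a fixed span like 0.5–2.5 presumes
full-scale training). The five-condition paradigm keeps s1 at the
calibrated intermediate contrast throughout.

Two analysis-level choices deserve note. First, in the blindsight lesion
(first-layer activations × 0.01), eval-mode batch-norm running statistics
leave a constant offset on the decision output; at desk scale this pins
every trial to one side of the fixed 0.5 threshold, making d′
unmeasurable even though the graded signal is intact. The blindsight
runner therefore reads type-1 decisions from the condition's empirical
median of the decision output — d′ is criterion-free, and this mirrors
re-deriving confidence criteria from each condition's empirical
distribution, which the meta-d′ fit always does. Second, Eq.-16-style
normalized activity divides by the pooled dispersion computed as the mean
across neurons of per-neuron across-trial variances (sqrt of it in the
default "sd" mode, which is dimensionally consistent; a literal
"variance" mode is kept), because pooling the flattened matrix would
break per-neuron translation invariance.

## Known limitations

- Synthetic classes are far easier than natural images; absolute d′ and
  confidence levels are not comparable to full-scale numbers, only signs
  and orderings are.
- The meta-d′ fit assumes the equal-variance type-2 model; heavily
  non-Gaussian confidence distributions (e.g. post-lesion) can produce
  small negative estimates.
- The 55-layer residual encoder for color-image experiments is out of
  scope; only the architecture contract is documented here.
- Reports of statistical significance at 2–3 replicates are directional
  checks, not calibrated hypothesis tests.
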