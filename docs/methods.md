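# Methods

`latnet` implements a contextual-integration model of cortical lateral
connectivity and its use as a fixed, unsupervised augmentation of a small
convolutional classifier. This note records the model, the numerical
choices, and what the synthetic test corpus does and does not establish.

## Model

Each excitatory unit codes one feature `F_k` at one image location; its
steady-state rate is read as the probability that the feature is present,
with a linear probability-to-rate mapping. Classical-receptive-field
(CRF) responses come from a filter bank: the image is converted to
grayscale, scaled to maximum 1, locally mean-subtracted over each
filter's support, correlated with each filter, half-wave rectified, and
divisively normalized across features at every location so that

    sum_k c[k, n] = 1     for every location n.

This per-location normalization is the model's first, divisive form of
inhibition. Locations where every rectified response vanishes carry no
evidence and receive the uniform vector `1/K` (maximum entropy); an
all-zero mode is available for callers who prefer to drop them.

Lateral weights between units with non-overlapping receptive fields are
the above-chance relative co-occurrence of their features at a spatial
offset `d = (dy, dx)`:

    W[j, k, d] = <c_j(m) c_k(m + d)> / (<c_j> <c_k>) - 1,

with expectations pooled over all images and all valid positions
(translational invariance). `W = 0` for independent features, `-1` for
mutually exclusive ones. By construction `W[j, k, d] = W[k, j, -d]`
exactly; plain source/target symmetry at a fixed offset additionally
requires inversion-symmetric image statistics and is not assumed.

Surround integration takes two forms. The exact product form applies to
disjoint, RF-sized patches (the independence regime of its derivation):

    f_j(m) ∝ c_j(m) * prod_{n != m} (1 + sum_k W[j,k,n-m] c_k(n)),

renormalized per patch; its normalization constant is defined
operationally as the per-patch sum, so each patch remains a probability
vector. The linearized form, used on dense maps and inside the CNN,
keeps the first-order surround contribution

    f = c .* (1 + alpha * S),   S[j, m] = sum_k sum_{d != 0} W[j,k,d] c[k, m+d],

with a tunable surround strength `alpha >= 0`, zero padding at map
borders, and no renormalization. In both forms negative outputs are
floored at zero: weights reach below `-1` in aggregate, the model's rates
are probabilities, and the flooring is the minimal projection back onto
valid values. A single pass is computed — no recurrent iteration.

## Weight decomposition

Flattened to a matrix `G` (rows: target feature; columns: source feature
x offset, C-order), the weights are split as `G = L + S` by a weighted
principal component pursuit

    min ||L||_* + ||Lambda S||_1   s.t.  G = L + S,

solved with an inexact augmented Lagrangian: singular-value thresholding
at `1/mu` for `L`, columnwise soft thresholding at `Lambda_i / mu` for
`S`, dual update, `mu <- 1.5 mu` (initial `mu = 1.25 / ||G||_2`).
The column weight adapts every outer sweep as

    Lambda_ii = beta / (||S^(i)||_1 + gamma),

so columns that acquire l1 mass are penalized less, which concentrates
`S` on few source-feature/offset channels (column sparsity). The
literal product form `beta ||S^(i)||_1 + gamma` is selectable
(`adaptive_rule="literal"`) but penalizes active columns more and is not
the default. Convergence: relative residual `||G - L - S||_F / ||G||_F
<= tol` (default 1e-7), cap 500 sweeps, non-convergence returned with a
warning flag rather than raised.

Scaling of `beta`: for the image-statistics weight matrix the defaults
are `beta = 0.01`, `gamma = 1.0`; for generic unit-scale matrices the
natural operating point is the standard pursuit scale
`beta ≈ 1 / sqrt(max(m, n))` with `gamma` well below the typical column
l1 mass (sharper adaptation). The recovery tests use that scale.

`L` is truncated by SVD at the smallest rank retaining 99% of the
squared singular-value mass, then split per rank-1 term
`sigma u v^T` into `sigma (u+ v+^T + u- v-^T)` (positive part) and
`sigma (u+ v-^T + u- v+^T)` (negative part); the two sum back to the
truncated `L` and are entrywise single-signed. `S` splits entrywise.
The four components are labeled as circuit pathways — disynaptic
excitation (`W_LR+`), direct excitation (`W_S+`), and low-rank vs sparse
disynaptic inhibition (`W_LR-`, `W_S-`) attributed to distinct
interneuron populations; the labels are interpretive only, no interneuron
dynamics are simulated. Sparsity is reported both as the fraction of
nonzero entries and of nonzero columns (threshold 1e-12), since either
convention appears in practice.

## Filter bank

Defaults: 15x15 pixel grid at 1 deg/pixel (the grid scale is not
uniquely determined by the measurements the bank emulates; 1 deg/px makes
the 5-deg subfield separation and ~2.1-2.4 deg subfield sigmas fit the
grid, and it is configurable). Subfield sigma = 0.5 x average measured
subfield size: 2.1 deg (ON), 2.4 deg (OFF); two-subfield cells place the
stronger subfield (amplitude 1) at +2.5 deg and the weaker (amplitude
0.5, opposite sign) at -2.5 deg along one of eight axes 45 deg apart.
Subfields add on a zero background with no final normalization. The
preferred orientation is the axis orthogonal to the separation, mod 180
deg; single-subfield filters are unoriented (NaN) and excluded from
orientation-binned analyses.

The effective radius thresholds |intensity| at a fraction of each
filter's maximum (default 5%), counts suprathreshold pixels as area `A`,
and reports `sqrt(A / pi)` averaged over the bank. The literal
complementary reading (95% of maximum) yields a radius an order of
magnitude smaller than any plausible receptive-field extent for Gaussian
profiles and is exposed only through the same `threshold_frac` knob. At
the 5% default the 18-filter mean is 6.26 deg; published estimates for
this construction quote ≈7 deg, a discrepancy documented here rather
than absorbed by moving the threshold (7 deg would correspond to a
threshold near 2%).

## Analyses

Orientation dependence: ordered pairs of oriented filters are binned by
circular orientation difference (exactly {0, 45, 90} deg for this bank);
the mean of the positive part (or |negative part|) of the chosen
component is taken over all offsets and pairs in a bin, zeros included —
a sparse component is thereby compared on the same denominator as a dense
one. Distance dependence: the signed part is averaged over all feature
pairs per offset, then over square rings `max(|dy|, |dx|) = r`; the
profile is fit with `w(r) = wm exp(-r^2 / 2 sigma^2) + w0`
(initialization: `wm = max - min`, `w0 = min`, `sigma` = half the
r-range). A fitted amplitude below 1e-8 of the profile scale flags the
fit as degenerate (sigma unidentifiable). Sigma in degrees converts to
cortical distance via the 30 deg/mm magnification factor
(`sigma / 30 * 1000` microns).

## CNN experiment

The classifier is a minimal NumPy network: two valid 5x5 convolutions
(He-initialized), each followed by ReLU and 2x2 max pooling, then a ReLU
fully-connected layer and a softmax output, trained by minibatch SGD
with momentum 0.9 and cross-entropy loss. Everything is deterministic
given the seed (shuffling included), so two runs with one seed produce
bit-identical weights. Reference channel widths are 32/64 with a
128-unit hidden layer; the bundled experiments use 8/16 channels, a
64-unit hidden layer, 3 epochs and ~2000 training glyphs, sizes at which
the full 10-seed protocol completes in a couple of minutes while leaving
the qualitative ordering of the variants intact.

Lateral weights for a conv layer are learned from its post-ReLU,
pre-pool activations, divisively normalized across channels per location
(uniform at dead locations) exactly as image responses are; inference
then modulates the *raw* activations with the linear form before
pooling. Because raw activations are not probability-scaled, the
surround term can be large and useful `alpha` values are small; `alpha`
is chosen per trained model on held-out validation data by grid search
(default grid 0 to 1), ties toward the smaller value, under a
configurable noise mix, and a single value is shared by both layers and
reused across lateral variants. Offset extent defaults to a quarter of
the feature-map side.

Noise: AWGN adds `N(0, level^2)` per pixel and clips to [0, 1]; SPN
picks `round(level * n_pixels)` distinct pixels per image and sets each
to 0 or 1 with probability 1/2. Both are deterministic per seed.
Variants: `full` uses the learned tensors; `uniform-avg` replaces every
lateral connection with `1 / N_T`, `N_T` being the layer's total lateral
connection count (all channel pairs and nonzero offsets) — the control
for whether the *structure* of the weights matters; the two
inhibition-only variants keep both excitatory components and a single
inhibitory one, from the per-layer decompositions (`beta` 0.1 and 0.25
for layers 1 and 2, `gamma` 1.0). With `alpha = 0` or zero weights every
variant is bit-identical to the base network.

## Synthetic corpus

The generators provide statistically controlled stand-ins so the full
pipeline runs without external data: 1/f-amplitude pink noise (the
dominant second-order statistic of natural scenes), collinear oriented
contours (inducing the like-to-like co-occurrence the model predicts
connectivity from), a binary feature process with an exact closed-form
expected weight `P_jk/(q_j q_k) - 1` (the estimator's oracle), stroke
glyph "toy digits" with geometric jitter, and ideal oriented edges. All
are pure functions of their arguments, seed included.

What they do not emulate: higher-order natural-scene statistics
(occlusion, texture, phase structure), luminance distributions, and
handwriting variability. Consequently the *quantitative* outputs on this
corpus — fitted sigmas, sparsity fractions, retained ranks,
surround-term moments, absolute accuracies — characterize the corpus,
not natural images or handwritten digits; what the tests establish are
the estimator contracts (closed forms, symmetries, bounds), the solver's
recovery behavior, and the qualitative orderings (like-to-like weight
structure, noise-robustness benefit of learned over uniform lateral
connections). Runs on photographic corpora and MNIST IDX files are
supported through the same interfaces (`load_images`, `read_mnist_idx`)
for users with the data on disk; nothing downloads anything.

## Known limitations

- The exact product form is restricted to disjoint tilings; applying it
  to overlapping patches violates the independence its derivation needs.
- Single-pass modulation only; no recurrent settling, no feedback
  (top-down) pathways, no probabilistic sampling.
- The RPCA solver's adaptive rule makes the problem slightly
  non-convex across sweeps; determinism and the objective sanity checks
  stand in for global-optimality guarantees.
- `W` entries at offsets where receptive fields overlap are estimable
  but not meaningful under the model's assumptions; mask them
  (`mask_overlap`) before circuit-level interpretation.
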