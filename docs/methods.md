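# Methods

## The model

The package implements a digital-twin framework for arithmetic learning.
A recurrent convolutional network of the CORnet-S family — four stages
named V1, V2, V3 and IPS after the dorsal visual stream regions it
abstracts — is trained from random initialization to read a visually
presented addition or subtraction problem and emit one of the 19
possible results (0–18). Two ingredients turn it into a model of
excitation–inhibition imbalance:

1. **Neural gain.** Every rectification in the network computes
   `y = G · max(0, x)` with a single positive gain `G` shared across all
   units. `G` operationalizes neural excitability; the study grid is
   `G = 1 + 0.25 k`, `k = 0..16` (17 models from 1 to 5).
2. **Frozen normalization.** Batch normalization standardizes the input
   of every nonlinearity to mean 0, variance 1, and its affine
   parameters are permanently frozen at scale 1, shift 0, so response
   amplitude is controlled by the gain alone. Batch statistics are used
   during training, running statistics during evaluation (one of several
   conventions compatible with the description; chosen as the standard
   one).

Training uses cross-entropy over the 19 classes with Adam. One
iteration is one optimizer step on one mini-batch; the held-out test
split is evaluated at iteration 0 and on a fixed cadence.

### Architecture details

CORnet-S block structure is reproduced: a feedforward V1 stage
(7×7/stride-2 convolution, norm, gain-rectification, 3×3 max-pool, 3×3
convolution, norm, gain-rectification) followed by three recurrent
bottleneck blocks with convolution weights shared across time steps,
per-time-step normalization statistics, a stride-2 spatial reduction and
a 1×1 skip projection at the first step, and the previous step's output
as the residual afterwards. The third block is named V3 (a pure
renaming of CORnet-S's V4), the fourth IPS (of IT). Default recurrence
steps are (1, 2, 2, 2). The decoder is a global average pool over the
final-step IPS feature map followed by one affine map to 19 logits.
Channel widths scale with a single `width_scale` knob (1.0 reproduces
CORnet-S's 64/128/256/512; the bottleneck expansion factor is likewise
configurable).

Because no deep-learning framework is assumed, the package carries its
own reverse-mode autodiff engine (`pdnn.autodiff`): float32 tensors, an
im2col convolution with a pointwise fast path, batch normalization with
the frozen affine, max/average pooling and a fused softmax
cross-entropy. Gradients are verified against float64 finite
differences and scipy cross-correlation references in the test suite.
All computation is plain numpy, so a run is bit-reproducible given its
seeds.

## Stimuli

The task space is every `a + b` and `a − b` with operands and result in
0..18: 190 additions and 190 subtractions (the operand range includes 0;
this is forced by the 190+190 count). Each problem is rendered into a
five-slot 28×140 grayscale image — tens and units of the first operand,
operator, tens and units of the second — replicated across 3 channels;
blank tens slots are black.

Two glyph backends exist. The MNIST backend reads IDX files from disk
and never downloads anything. The default synthetic backend renders
digits from stroke skeletons with random affine jitter (rotation sd
≈ 4.6°, scale 0.85–1.05, shear, 2–4 px stroke width, additive pixel
noise), drawing each glyph from a pre-rendered per-digit pool. The
operator glyphs follow the construction used with MNIST: minus is a
digit "1" rotated 90°, plus the pixel-wise maximum of a vertical and a
rotated "1".

What the synthetic generator emulates: handwriting-like variability
within a digit class, glyph reuse across problems, and the compositional
slot layout. What it does not emulate: the full diversity of real
handwriting (MNIST has thousands of exemplars per digit; the synthetic
pool has tens), stroke topology errors, or scanner noise. Tests passing
on synthetic glyphs therefore demonstrate the machinery and the
direction of gain effects, not reading robustness on real handwriting.

For the paper-faithful profile each problem has 100 variants, half for
training (19000/19000 stimuli per split). With the MNIST backend the
train and test splits draw from the disjoint MNIST train/test glyph
pools; with the synthetic backend both splits share one glyph pool and
differ in glyph composition only — at reduced pool sizes, pool-level
disjointness makes the task a few-shot shape-recognition problem that
small networks cannot solve in a short horizon, which is a different
study than intended.

## Cohort matching

Model accuracies are normalized to [0, 1] against the min/max over the
entire sweep (all gains × all evaluated iterations); subject achievement
scores are normalized against the cohort min/max. The behavioral
distance is the L1 distance between the two normalized scalars; each
subject gets the distance-minimizing gain at every evaluated iteration
(ties towards the lower gain), and the reference iteration minimizes the
cohort-mean distance (ties towards the earlier iteration). A
permutation control re-draws uniformly random grid gains per subject.

The synthetic cohort generator stands in for the study's 45 children
(24 typically developing, 21 with mathematical learning disability,
NumOps threshold 90). True gains are drawn from grid-snapped truncated
normal priors (TD centred at 2.05, MLD at 3.77, sd 0.55 — the reported
group means); scores are the sweep's normalized accuracy at the drawn
gain plus Gaussian noise, mapped affinely onto a NumOps-like scale with
the threshold placed between the n_mld-th and (n_mld+1)-th lowest
scores, and groups assigned from the scores, so group sizes are exact
and the threshold invariant holds even when the priors overlap. The
generator records its exact affine scale on the cohort (`norm_bounds`)
so that matching is free of normalization distortion in recovery tests;
cohorts loaded from CSV use the plain min/max convention.

## Behavioral metrics

Per expected result r: mean response m_r and population standard
deviation s_r. Systematic error = mean_r |m_r − r| (trueness);
imprecision = mean_r s_r; effective response count = exp of the Shannon
entropy (natural log) of the marginal emitted-response distribution,
between 1 (one response used) and 19 (uniform). The entropy is computed
on the marginal distribution of answers, not per level. All metrics use
the test split.

## Representational similarity

For a layer, the mean activation of each unit over the test variants of
each problem gives a 380 × U matrix in canonical order (additions before
subtractions, then ascending result, then ascending first operand).
Pearson correlation across units between rows gives the 380 × 380 NRS
matrix. Block averages: add–sub over all cross pairs; add–add and
sub–sub over unordered distinct pairs, excluding the self-similarity
diagonal. Zero-variance rows are flagged as undefined and excluded from
block means. For the model-versus-brain comparison, empirical
similarity values provided on the Fisher-z scale are mapped back to
correlation units with tanh before the Pearson correlation with the
model values, with a shuffled-pairing null.

## Manifold geometry

The 380 problem means partition into 19 result manifolds of 20 points
each. Geometry follows the mean-field theory of linear classification
of manifolds: per manifold, the centroid is subtracted, an orthonormal
basis of the within-manifold subspace is built by SVD, coordinates are
scaled by the centroid norm and a unit center coordinate is appended.
For each Gaussian sample the anchor point is the projection of the
sample onto the feasible cone {v : ⟨v, s_i⟩ ≥ κ}; the projection is
solved exactly through its nonnegative dual — scipy NNLS at the default
margin κ = 0, projected coordinate descent otherwise. Capacity is the
inverse of the mean squared projection residual (manifold inverses
averaged); radius is the RMS in-subspace anchor norm (relative to the
center norm, hence scale-free); dimensionality is the mean squared
alignment between the Gaussian direction and the anchor. Degenerate
point manifolds are handled (radius 0, capacity → 2, the classical
perceptron limit). Center correlation is the mean absolute cosine
between globally centered centroids — a magnitude convention, since
alignment sign is arbitrary; note that global centering of K centroids
induces an O(1/K) floor. Ambient dimensions above a cap (default 5000)
are reduced by a seeded random projection.

An independent empirical oracle estimates capacity as P/N* where N* is
the ambient dimension at which half of the random balanced dichotomies
of the P manifolds are linearly separable (LP feasibility through
minimal hinge slack, no bias term), with the 50% crossing interpolated
on a dimension grid. The two estimators agree within a few percent on
synthetic ellipsoid manifolds and both reach the classical value 2 for
point manifolds.

## Scale profiles and what the reduced horizon shows

Two profiles are built in. The `paper` profile is the full study
condition: width_scale 1.0, bottleneck 4, 100 variants, batch 100,
learning rate 0.001, 3800 iterations, evaluation every 100. The `desk`
profile is sized for a single CPU: width_scale 1/16, bottleneck 2,
20 variants per problem, glyph pool 12, batch 50, evaluation every 50,
learning rate 0.003 (scaled up with the 16-fold width reduction so the
smaller model converges within its shorter horizon).

The automated test suite trains the full 17-gain grid for 300 iterations
per gain — about ten CPU-minutes — which is enough to reproduce, with
frozen seeds:

* chance-level (~5%) performance of untrained models;
* the strong negative correlation between gain and test accuracy at a
  fixed evaluation;
* the increase of IPS add–sub NRS with gain and its amplification along
  the layer hierarchy;
* the digital-twin matching machinery (self-matching at zero distance,
  higher matched gain for the low-achievement group, fitted distances
  far below the permutation null).

Training to the 95% mastery threshold, by contrast, takes a few thousand
iterations per gain even at desk scale (hours of CPU for the grid), so
properties that require mastery or a mature representation — iterations-
to-threshold correlations, high recovery rates from noisy synthetic
cohorts (which need a wide accuracy spread across gains), and the
mid-training manifold signatures — are not expected to emerge within the
suite horizon. The `pdnn sweep` command with a raised `max_iterations`
runs the full-length desk sweep for those analyses.

Known limitation: at 1/16 width (160 IPS units) the manifold capacity
and dimensionality trends versus gain track training progress rather
than the mature-representation signatures; the center-correlation trend
reverses toward the expected direction only after roughly a thousand
iterations. The estimators themselves validate exactly on synthetic
geometry, so this is a property of the reduced regime, not of the
machinery.

## Numerical choices

* float32 forward/backward; Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) as library-
  default moments, recorded in run manifests.
* Batch-norm ε 1e-5, running-stat momentum 0.1.
* Epoch-wise shuffling of the training split into sequential batches.
* Evaluation may sub-sample the test split (problem-stratified,
  deterministic) to bound per-checkpoint cost; accuracy on ≥380 items
  keeps binomial noise near one percentage point.
* NNLS projection is exact; coordinate descent runs to 1e-10 dual
  movement; degenerate/interior Gaussian samples contribute zero to the
  capacity inverse and are excluded from anchor statistics.
* Ties: matching ties break toward the lower gain, reference-iteration
  ties toward the earlier iteration, remediation target ties toward the
  earlier iteration.
* Welch's t-test for group contrasts, Cohen's d with pooled SD, Pearson
  r with the usual n−2 df transform; no multiple-testing correction is
  applied, matching the descriptive reporting style of the source
  analyses.
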