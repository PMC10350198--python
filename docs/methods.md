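# Methods

`lesionsubtype` re-implements, as a tested pipeline on synthetic cohorts, an
analysis that (i) predicts severe post-stroke aphasia from template-space
morphometry + lesion maps with a 3D CNN against class-weighted SVM baselines,
(ii) attributes the predictions to voxels with Grad-CAM++, baseline-referenced
path-gradient attribution and kernel SHAP, (iii) groups the attribution maps
into morphometry subtypes by consensus clustering under the eta-squared
distance, and (iv) decodes subtype exemplars against chi-square meta-analytic
topic maps. This note records the models, the defaults and why, the numerical
choices, and what the synthetic validation does and does not establish.

## Synthetic cohorts

Real cohorts of this kind consist of registered binary tissue segmentations
(CSF/GM/WM), a manually traced lesion mask, and a WAB-AQ score per subject.
The generator emulates exactly that interface on a mirror-symmetric
ellipsoidal phantom (CSF shell, GM ribbon, WM core; sagittal first axis), so
every downstream stage consumes the same objects it would for real data.

* **Lesions.** Grown from a fixed perisylvian-analog seed in the left
  hemisphere by Dijkstra ordering of the 6-connected voxel graph with
  per-subject randomized edge costs. Every prefix of the ordering is
  connected, so lesions are single blobs and volume is monotone in the size
  quantile. Quantiles are drawn from U(0.2, 0.9) of a maximum of 45% of the
  left-hemisphere volume: chronic left-MCA cohorts concentrate at moderate
  volumes; tiny lacunes and hemisphere-wiping infarcts are both uncommon.
* **Atrophy subtypes.** Subtype k is a mixture of 2-4 Gaussian foci
  (sigma = 0.10 of the grid per axis). The primary focus sits at a
  subtype-specific octant anchor on the GM ribbon; even-numbered subtypes add
  the sagittal mirror of their primary (bilateral patterns), odd-numbered
  subtypes add jittered satellites. Anchors are assigned so that every
  subtype keeps at least one right-hemisphere (contralesional) focus a large
  stroke cannot erase, and the first four subtypes have disjoint anchor sets.
  Atrophy converts GM voxels to CSF with probability `burden x pattern`
  (burden ~ U(0.5, 1.3)), and converts WM in the same territory at 0.7x the
  GM rate (tract degeneration accompanying cortical thinning).
* **Severity.** `wab_aq = 97.5 - lesion_effect*v - effect_k*b + N(0, 6)`,
  clipped to [0, 100], with `v` the lesion volume fraction and `b` the
  burden. The ceiling 97.5 is a near-maximum WAB-AQ for unimpaired speakers
  (any value in [95, 100] would do; it is configurable). Atrophy dominates
  severity by default (atrophy_effect 40 vs lesion_effect 60 applied to
  v <= 0.45, i.e. at most ~27 points): the phenomenon under study is that
  tissue integrity outside the lesion carries predictive signal beyond
  lesion size. Subtype k's atrophy effect is scaled linearly from 1.5x down
  to 0.5x of atrophy_effect across subtypes — different brain systems
  contribute differently to the behavioral score — while subtype membership,
  lesion size and burden are drawn independently, so subtype is not
  predictable from lesion volume. A common multiplier on both effects is
  calibrated by bisection so the realized fraction with `wab_aq <= 50` lands
  within +/-5 points of the 35% target (calibration is skipped when both
  effects are zero, and raises with the achievable range when the target is
  unreachable).
* **Reproducibility.** All randomness flows from the single cohort seed via
  named `numpy` substreams (one per subject and purpose).

What the phantom does **not** model: individual anatomical variability
(every subject shares one template), registration error, scanner noise,
partial-volume effects, or realistic gyral anatomy. Consequences for
interpretation are discussed under *Known limitations*.

## Preprocessing

Tissue masks and the lesion merge into a single ordinal map (background 0,
CSF 1, GM 2, WM 3, lesion 4; the lesion supersedes tissue). The ordinal
order CSF < GM < WM follows tissue density and is configurable through
`code_table`. Downsampling uses modal (majority) pooling per block — the
block analog of nearest-neighbor interpolation for label maps — with ties
broken toward the *highest* code so a lesion never disappears on a tie;
trailing partial blocks pool over the voxels they contain. The cohort is
cropped to the tightest box containing every nonzero voxel of every subject,
then codes are linearly rescaled to [-1, 1] (`c -> 2c/4 - 1`). Registration
is assumed done upstream; all inputs are treated as voxel-aligned. NIfTI
round trips are bit-exact.

## Cross-validation

One preallocated plan — 20 repeats of 6 outer x 8 inner stratified folds by
default — is shared by every model so paired comparisons across repeats see
byte-identical partitions. Stratification uses the granular WAB-R severity
categories (very severe [0,25], severe (25,50], moderate (50,76), mild
[76,100]; the printed 75/76 gap is closed by assigning (75,76) to moderate;
the binary severe label is `wab_aq <= 50`). Fold assignment shuffles within
stratum and deals round-robin with a pointer carried across strata, which
bounds both overall fold-size differences and per-fold stratum deviations by
one subject (231 subjects and 6 folds give test sets of 38,38,38,39,39,39).
Strata smaller than the fold count merge into the adjacent severity category.
The 70/30 train/validation split inside an outer-train set sizes validation
as `round(0.3 n)` by the largest-remainder method (192 -> 134/58). Plans
serialize to JSON bit-exactly.

## The CNN

A VGG-style single-channel 3D CNN: blocks of shape-preserving 3x3x3
convolutions + ReLU, each block closed by a 2x max pool (ceil mode; an axis
already at size 1 is skipped, since a small 8-mm grid cannot survive five
strict halvings), then three fully connected layers — FC1 at twice the last
convolutional channel count with batch normalization and dropout, FC2 at the
last-conv channel count (the latent layer exposed downstream), FC3 at the
class count. Four complexity presets span the tuned ranges (blocks 4-5,
convolutions per block 1-4, channels 8-128):

| level | convs/block | channels |
|---|---|---|
| 1 | 1,1,1,1 | 8,16,32,64 |
| 2 | 2,2,2,2 | 16,32,64,128 |
| 3 | 2,2,2,2,2 | 8,16,32,64,128 |
| 4 | 2,2,3,3,4 | 8,16,32,64,128 |

Training minimizes cross entropy weighted by inverse class frequencies
(weight_c = n / count_c) under plain SGD with a cosine-annealing warm-restart
schedule: cycle i spans `50 * 2^i` epochs (restarts at cumulative epochs 50,
150, 350, 750 over the 800-epoch budget) and within a cycle of length T the
rate decays from the base rate to the 1e-10 floor at the cycle's *last*
epoch (denominator T-1, so the floor is actually reached before each
restart). L2 decay applies to weights only, not biases or batch-norm
parameters. Early stopping watches validation loss with patience 100 and
min-delta 1e-4 and restores the best weights. Batch size 128 with ~135
training subjects means roughly one batch per epoch; shuffling is per epoch.
Hyperparameters (complexity x dropout {0.6,0.7,0.8} x L2 {0.001,0.01} x
learning rate {1e-5, 8e-5, 1e-4}) are grid-searched by smallest mean
inner-fold loss, never accuracy, and the winner is refit on the whole outer
train with the 70/30 split.

The network runs on a small dependency-free numpy engine written for this
package (float32; explicit forward/backward passes; convolutions as 27
shifted channel-mixing contractions). The engine exposes the last
convolution's activations and gradients and the gradient at the input, which
the attribution methods consume directly. Analytic gradients are verified
against finite differences in the test suite. Training is deterministic
given the seed.

## SVM baselines, fusion, evaluation

SVMs (linear and radial kernels as separate models; the kernel is never
tuned) minimize hinge loss with inverse-class-frequency weighting on the
flattened scaled maps. Cost and kernel scale are tuned by random search over
300 logarithmically spaced bins ([1e-3, 2e4] and [1e-3, 1e3]), drawing 60
candidates per fold by default (the draw count is a package choice; only the
bin construction is prescribed). Optional PCA or PCA-then-ICA reduction
(1-75 components, tuned; ICA runs on the retained PCA scores, i.e. on the
tuned component count) is fit on training data only and reused on held-out
subjects — a leakage audit records the fit indices. Decision values map to
probabilities through a logistic (Platt-style) link because fusion consumes
probabilities.

Fusion: (i) weighted probability averaging over a 101-point weight grid
(step 0.01; weight 1 = CNN only); (ii) a linear-discriminant meta-learner on
the 2-D probability space, fit per outer fold on inner-fold out-of-sample
predictions (prevents optimistic stacking), with a ridge-regularized
fallback for singular covariances; (iii) linear SVMs trained on CNN-derived
features — latent activations or saliency maps — generated for each subject
by the fold model under which that subject was held out.

Evaluation pools predictions across a repeat's outer folds and scores once
(pooled-then-scored). Severe is the positive class, so recall equals the
severe-class accuracy and balanced accuracy is the mean of the two class
accuracies; divisions by zero yield 0 with a flag. Label-permutation tests
rebuild the model per permutation and use the add-one estimator
`p = (1 + #{null >= observed}) / (1 + n_permutations)`. Paired model
comparisons across repeats use the two-sided paired t with df = repeats - 1
and Cohen's d on the differences; zero-variance differences raise rather
than report an infinite statistic.

## Saliency

* **Grad-CAM++** on the last convolution's ReLU output, with
  `alpha = g^2 / (2 g^2 + sum(A g^3) + 1e-8)` (the standard gradient-power
  surrogate for the higher derivatives, exact for an exponential-activated
  score), channel weights `w_k = sum alpha * relu(g)`, map
  `relu(sum_k w_k A_k)` trilinearly upsampled to the input grid. All-zero
  gradients produce an all-zero map with a warning, never NaNs.
* **Path-gradient attribution** (the deep-SHAP stand-in): the class-score
  gradient averaged along the straight line from baseline to input, times
  (input - baseline), averaged over baselines. Because the network is
  piecewise linear, a segment's midpoint gradient is exact unless the
  segment straddles a ReLU kink; segments whose directional-derivative
  estimate disagrees with the actual score change are bisected until the
  summed attribution matches the score difference within 1% (default;
  capped at 1024 segments; a fixed-step mode exists for speed). This
  preserves the completeness property the map comparisons rely on; DeepLIFT
  multiplier propagation is out of scope.
* **Kernel SHAP** for the SVM: Shapley-kernel weighted least squares with
  the efficiency constraint enforced exactly; absent features imputed from
  the instance's k nearest background neighbors (k = 10% of the background);
  exhaustive (and exactly Shapley) whenever all proper coalitions fit the
  budget, Monte-Carlo otherwise.
* **ROIs**: lesion, perilesional (1-voxel dilation ring inside the left
  brain by default), extralesional, and their sagittal-mirror homologues
  intersected with the brain; per-ROI means of sum-1-normalized maps are
  contrasted between predicted classes with Welch two-sample t-tests.

## Subtyping

Maps are compared with the pointwise eta-squared coefficient
(`eta^2 = 1 - SS_within / SS_total`, pair means vs the grand mean of both
maps): 1 for identical maps, sensitive to both scale and offset, unlike
Pearson correlation. k-means uses k-means++ seeding under the distance
`1 - eta^2`, arithmetic-mean centroid updates (relaxed k-means; a medoid
update is available behind a flag), empty clusters reseeded at distinct
farthest points, best of 250 replicates by total distance. Consensus
matrices subsample 60% of voxels 1000 times by default; every run clusters
*all* subjects, so the co-clustering denominator is simply the run count and
the diagonal is 1.

Model-order selection over k = 3..30: candidates whose off-diagonal
consensus values are consistent with unimodality under Hartigan's dip test
(p > 0.05 against a uniform bootstrap null; the null is cached per sample
size) are excluded; among survivors the largest k with PAC <= 0.1 wins
(PAC = fraction of consensus values strictly inside (0.1, 0.9); interval and
threshold configurable); if nothing passes, the smallest-PAC candidate is
returned with a warning. The dip statistic is computed by the iterative
greatest-convex-minorant / least-concave-majorant refinement and is verified
in the tests against an independent linear-programming oracle (exact minimax
unimodal-CDF fit on a fine grid) and against the analytic values 1/(2n) for
equally spaced data and 1/4 for two equal point masses. Exemplars come from
affinity propagation on the consensus matrix (damping 0.9, max 2000
iterations, 100-iteration convergence window), with the preference tuned by
bisection until the emergent cluster count matches the selected k (nearest
achievable otherwise, flagged).

By default the pipeline clusters raw, unmasked Grad-CAM++ maps; sum-1
normalization and per-subject lesion masking are available toggles.

## Decoding

A synthetic study corpus (400 studies, 200 topics, 5% baseline activation
rate, 15% topic-membership rate by default) records binary per-voxel
activation and per-topic membership; planted topics activate a chosen region
at odds 8x baseline. Each topic's meta-map is the signed square root of the
per-voxel chi-square statistic (2x2 activity-by-membership table, no
continuity correction; zero-margin voxels score 0; sign follows the
direction of association — the signed-root form keeps direction, which
Pearson decoding needs). Exemplar maps are decoded by Pearson correlation
against every topic map over non-lesion brain voxels; retained topics need
r > 0.2 *and* a Bonferroni-corrected p < 1e-4 (the threshold applies to the
corrected p, i.e. raw p times the topic count, capped at 1).

## Pipeline scales

`scale: full` is the complete protocol (231 subjects, 20 repeats of
6x8 folds, the full hyperparameter grid, 800 epochs, 500 permutations,
consensus with 1000 runs x 250 replicates) and is cluster-scale compute.
`scale: smoke` is the desk preset (60 subjects, 2 repeats of 2x2 folds, one
CNN configuration, 50 epochs, consensus 60 x 8). The test suite exercises
the full pipeline at a micro scale (24 subjects, 6 epochs) and the
end-to-end scientific checks at 60-64 subjects with 30-50 epochs and
reduced consensus settings; these problem sizes are the package's choices
for routine verification and are all overridable.

## Known limitations

* With a shared template anatomy and desk-scale grids, the Grad-CAM++ maps
  of trained classifiers are dominated by a per-class template: the first
  principal component of the normalized maps tracks the predicted class, and
  within-class individual structure is weak. Planted subtype structure that
  is perfectly decodable from the *inputs* does not survive into the
  Grad-CAM++ maps, because (i) severity prediction only requires global
  atrophy totals, leaving class gradients spatially diffuse, and (ii) after
  4-5 max-pool stages the last convolution retains 1-3 voxels per axis with
  near-global receptive fields. End-to-end subtype recovery through
  CNN -> Grad-CAM++ -> consensus clustering therefore fails at this scale
  even though the consensus machinery recovers planted map-level structure
  exactly; the corresponding end-to-end checks in the acceptance suite
  document this honestly rather than substituting a different pipeline.
  Conditions that plausibly change the picture — individually varying
  anatomy, larger grids relative to the network's receptive fields, and
  features trained on hundreds of subjects — are exactly what the real-data
  setting provides and the phantom does not.
* The severity model is linear with Gaussian noise and clipping: the
  simplest generator consistent with severity driven jointly by lesion size
  and extralesional atrophy. No floor/ceiling psychometrics beyond clipping.
* The dip-test p-value uses a uniform reference null, the conventional and
  conservative calibration for consensus distributions.
* Kernel SHAP at full voxel dimension is Monte-Carlo only; exactness is
  established on low-dimensional problems where brute-force Shapley values
  are computable.
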