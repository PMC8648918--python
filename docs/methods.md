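# Methods

## Model

mGMDH-AFS classifies a binary outcome (drug target = 1) from a mixed
binary/categorical/continuous feature table.  The classifier is a Group
Method of Data Handling (GMDH) network: a sequence of layers, each holding at
most `top_k` (default 10) *neurons*, where a neuron takes exactly two inputs
and outputs

    response(u, v) = logistic( Σ_k c_k · φ_k(u, v) ),

with the basis φ drawn from {1, u, v, uv, u², v², sin u, sin v,
e^clamp(u), e^clamp(v), log(1+|u|), log(1+|v|)} (exponent arguments clamped
to ±20; the logistic argument to ±30 so the output stays strictly inside
(0,1) in float64).  Layer-1 neurons read original features; deeper neurons
read previous-layer neuron outputs or original features (both are legal
inputs for a layer ≥ 2 neuron; pairing survivors with the strongest original
features lets evidence missed by layer 1 enter later, instead of being lost
irreversibly to the greedy first cut).

Because the basis is non-convex, coefficients are estimated by canonical
global-best particle swarm optimization (swarm 30, 100 iterations, inertia
0.72, c₁ = c₂ = 1.49, box [−10, 10]) maximizing the Matthews correlation
coefficient of the thresholded response (≥ 0.5) on the estimation set.  MCC
is used precisely because the data are heavily imbalanced: the all-majority
classifier scores 0.  Two refinements that leave this fitness untouched:

* one swarm particle is warm-started at the ridge-IRLS logistic solution
  over the linear terms (1, u, v), so every neuron is at least as good as a
  linear-logistic combiner of its inputs;
* the fitted coefficient vector is rescaled post hoc (unit norm × the 1-D
  likelihood-optimal scale).  The thresholded-MCC fitness is invariant to
  positive rescaling, so the scale is a free parameter; choosing it by
  maximum likelihood makes the graded output approximate P(y | u, v), which
  is what downstream layers and the final ROC consume.

## Training pipeline

Constructed from the *training partition only* (the model object owns its
data; nothing from a held-out set can reach any fitting step):

1. **Categorical encoding.**  Each categorical feature is one-hot expanded
   and a univariate logistic regression fitted by IRLS; every category maps
   to its fitted positive-class probability (the saturated MLE equals the
   empirical proportion), clipped to [1e−6, 1−1e−6].  Unseen categories map
   to the fitting-set prevalence.  Continuous features are z-scored on
   fitting-set statistics; binary features enter as 0/1.
2. **I-RELIEF feature weighting.**  Iterated expectation form: under the
   current weighted L1 distance, each sample's kernel-weighted (width 1.0)
   expected nearest-miss minus nearest-hit margin is accumulated per
   feature; negatives truncated to zero; renormalized onto the simplex;
   iterate to a fixed point (tolerance 1e−4, ≤ 50 iterations).  Features
   with weight ≥ 1/(2·n_features) are selected.  Each iteration is
   O(n² · n_features), so the expectation runs over a class-stratified
   subsample capped at 600 rows; at that size weight estimates are stable
   (the benchmark's 12 informative features are recovered at caps 600,
   1,000 and uncapped alike).
3. **Oversampling.**  Minority rows duplicated by seeded sampling with
   replacement to a 1:1 ratio.  Duplication (not interpolation) keeps binary
   features valid; an interpolating variant would fabricate impossible
   annotation vectors.
4. **Estimation/validation split.**  The oversampled training set is split
   60/40 (stratified) into the estimation set (neuron fitting) and
   validation set (neuron ranking, early stopping).  The split is
   group-aware: all copies of one original row land on the same side —
   otherwise duplicated minority rows appear on both sides and the
   validation set cannot serve its anti-overfitting purpose.  The 60/40
   ratio (rather than 70/30) keeps enough *distinct* minority prototypes on
   the validation side for the ranking signal to be usable at this scale.
5. **Layer growth.**  Layer 1 enumerates unordered feature pairs (if more
   than 25 features survive selection, the 300 pairs with the largest
   Relief-weight sums).  Deeper layers enumerate survivor–survivor pairs
   plus each survivor × the top-15 features by Relief weight.  Neurons are
   ranked by the mean of estimation and validation MCC (the validation side
   alone carries few distinct minority prototypes; the mean halves the
   selection noise), ties broken by higher estimation MCC then lower input
   indices.  Growth stops when the best validation MCC of a new layer fails
   to exceed the previous best (strict early stopping), or at 10 layers.
6. **Output and cutoff.**  The network output is the top-ranked neuron of
   the last accepted layer.  The decision cutoff maximizes Youden's
   J = TPR − FPR on the ROC of the validation-subset scores — validation is
   part of the training set but not used to fit neuron coefficients, so its
   score distribution is the least biased one available before the held-out
   set; estimation-row scores are optimistic for the fitted minority
   prototypes and would push the cutoff too high.  `closest-to-(0,1)` is
   available as an alternative criterion, and the cutoff can instead be
   estimated on all training rows (`cutoff_set="train"`); on the benchmark
   the three choices are indistinguishable.

Everything above is deterministic given the single training seed; component
seeds are spawned from it by name, so train → predict is a pure function of
(data, config, seed), and a serialized model reproduces scores bit-exactly.

## Baselines

* Logistic regression: hand-rolled IRLS with an L2 ridge (λ = 1e−6) on
  z-scored features — the ridge keeps coefficients finite under complete
  separation.  Optional exclusion of features with |standardized
  coefficient| below a threshold (refit once).
* Poisson-link GLM: the 0/1 label regressed as a count with a log link
  (statsmodels IRLS); predictions are rates thresholded at 0.5.  Applying a
  Poisson link to binary outcomes is unusual but implemented as specified;
  rates may exceed 1.
* RBF-SVM: libsvm SMO; (C, γ) by internal stratified 3-fold CV maximizing
  MCC over C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1, 10}.  Grid search with
  internal CV stands in for more elaborate kernel-width heuristics, keeping
  the tuning transparent.
* RBF network: K-means prototypes (K = 10 default), shared width = median
  inter-center distance, linear two-node output layer by least squares,
  argmax decision.
* Sequential forward selection: greedy wrapper adding the feature that most
  improves internal 3-fold CV MCC; stops on no improvement.  Available for
  any trainer; the packaged benchmark runs SVM/RBFN on all features by
  default (`use_sfs` flag) because the greedy wrapper multiplies cost by
  features × folds without changing the qualitative comparison.

None of the baselines oversample: the comparison deliberately contrasts the
imbalance-aware pipeline against standard practice at p ≥ 0.5.

## Validation harness

Stratified 70/30 hold-out (per class: floor of the fraction, leftover to the
training side), stratified k-fold (default 4), and a permutation control in
which labels are shuffled uniformly (class ratio preserved exactly) and the
*entire* pipeline rerun per shuffle; empirical p = (1 + #{permuted ≥ real}) /
(n + 1), so p is never zero.  Classifier comparison: Cochran's Q over the
shared test set, then pairwise McNemar of mGMDH-AFS against each baseline
(exact two-sided binomial below 25 discordant pairs, continuity-corrected
chi-square above), Bonferroni-adjusted with m = number of pairwise tests.
Degenerate cases are flagged, not raised: MCC → 0 on a zero denominator,
DOR/DP undefined when FP·FN = 0 (a Haldane +0.5 variant is available).

## Synthetic benchmark

`generate_dt_benchmark` emulates the statistical structure of a real
drug-target table: 150 vs 1,943 samples (a realistic 1:12.95 drug-target class ratio at ~1/13
scale), 65 "biochemical" features (60 binary + 5 four-level categorical) and
23 continuous "topology" features.  Twelve features are weakly informative —
seven binary flags with sparse base rates (0.02–0.05) and minority rate
differences 0.12–0.25, five continuous scores with 0.50–0.80 sd mean
shifts — and the rest are noise, identically distributed in both classes.
Features are class-conditionally independent, so the Bayes rule is available
in closed form; the balanced likelihood-ratio rule achieves sensitivity
≈ 0.86 and specificity ≈ 0.89 (Monte-Carlo, 20k per class), i.e. the
benchmark is learnable but far from separable.  Note that at prevalence
0.072 even this Bayes rule has MCC only ≈ 0.43–0.50: on minority-heavy
problems a balanced operating point necessarily costs precision, and MCC
values well above that are not reachable by any classifier at this
imbalance and effect size.

What the generator does *not* emulate: feature correlations (real annotation
flags co-occur), interaction effects (the generative law is additive, so the
GMDH's interaction modelling earns no advantage here by construction),
missing data, and the long-tailed degree distributions of real
interactomes.  Passing benchmarks therefore demonstrates imbalance handling
and pipeline correctness, not superiority on real proteome tables.

## Problem sizes and numerical choices

The packaged experiments run at desk scale: the benchmark is 2,093 × 88, the
permutation control uses 10 shuffles, comparisons use five independent
draws.  With only 45 positives in a 30% test partition, per-draw sensitivity
estimates carry a binomial standard error of ≈ 0.06; medians over five draws
inherit roughly half of that.  Seed-to-seed spread of the full pipeline is
correspondingly wide (test AUC 0.75–0.95 across draws), which is the main
limitation at this scale — the network's greedy layer selection must make do
with ~60 distinct minority prototypes for fitting and ~40 for ranking.

Ties: top-k selection and feature selection break ties toward lower indices;
the optimal cutoff takes the smallest threshold on a Youden plateau, clipped
strictly inside (0,1).  Degenerate inputs: constant feature pairs yield a
flagged zero-MCC neuron; all-constant feature sets raise; Relief returns
uniform weights (with a warning) when every margin is non-positive.
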