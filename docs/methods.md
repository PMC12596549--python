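# Methods

This note documents the modelling choices, the synthetic data-generating
process, numerical conventions, and the places where the design was
genuinely open.

## The classifier

**Sequence view of a tabular record.** The data are cross-sectional, but the
encoder is recurrent, so a record must become a sequence. We use the minimal
reading: the d = 25 encoded columns, in fixed schema order, become a
length-T = 25 sequence of scalar tokens (token dimension 1). The mapping is
a bijection isolated in one function (`network.tabular_to_sequence`) so that
alternative sequence constructions can be swapped without touching the rest
of the model.

**Encoder.** A bidirectional LSTM with hidden size H (default 128, the
tuned value; the harnesses below use smaller H, see *Problem sizes*). Per
step the forward and backward hidden states are concatenated:
h_t = [hf(t); hb(t)] ∈ R^{2H}. The forward pass reads t = 1..T, the
backward pass t = T..1.

**Residual feature track.** XF(t+1) = f_a(W_i x(t) + W_r XF(t)) +
λ(XF(t) − f_a(·)), algebraically (1−λ)·f_a(·) + λ·XF(t). f_a defaults to the
sigmoid; λ is a *fixed* hyperparameter (default 0.5), not learned — it is
described as a coefficient and never appears in the tuning grid. XF(1) = 0.
W_r here is a separate refinement matrix, distinct from the LSTM's own
recurrent weights; the track runs post-encoder.

**Attention mask.** The mask construction is not prescribed by the
formulation we implement, which only uses M(t) inside
H(t+1) = (1+M(t)) ⊙ XF(t) + Residual(t). We construct it as a learned
sigmoid gate M(t) = σ(W_m H(t) + b_m) (entries in (0,1)), matching the
soft-amplification semantics of (1+M); H(1) = 0. Residual(t) is the BiLSTM
output h_t — a skip connection from the nearest upstream representation,
consistent with the role residual connections play against vanishing
gradients.

**Summary state and head.** ŷ = σ(W_o H(T) + b_o), with H(T) the last
attention-updated state by default. Whether the final state or a pooled
summary should feed the head was open; we default to the last state and
expose mean pooling behind `pool="mean"`. (Empirically, on separable
synthetic cohorts the last state trains better here; note that its backward
half hb(T) has read a single token, so the information mostly flows through
the attention track and hf(T).) The decision threshold is 0.5. Disabling
residual attention (the ablation arm) removes the XF track and mask
entirely, leaving exactly a plain BiLSTM + head.

**Initialization.** Seeded uniform fan-in: U(−k, k) with k = 1/√H for all
LSTM tensors (the standard recurrent convention — using each tensor's
literal first dimension would give the scalar-token input weights a bound
of 1, an order of magnitude larger than the recurrent weights, which
saturates the gates early and slows convergence measurably), and
k = 1/√(2H) for the residual, attention and head tensors.

**Training.** Minibatch gradient descent on an in-repo reverse-mode autodiff
engine (gradient-checked against central finite differences). The loss is
the demographically reweighted cross-entropy; the per-batch objective is the
mean (the summed form only rescales the learning rate with batch size), and
probabilities are clamped to [1e−7, 1−1e−7]. Optimizers: Adam (default;
β = 0.9/0.999, ε = 1e−8), RMSProp (ρ = 0.9), plain SGD. Tuned defaults:
128 units, learning rate 0.001, batch 32, 100 epochs, Adam. Non-finite loss
aborts with a learning-rate diagnostic.

**Transfer learning.** A checkpoint (single `.npz` archive: named float64
arrays + JSON metadata with a schema fingerprint of feature names, d, T and
H) trained on the synthetic source corpus initializes the recurrent,
residual and attention tensors; the output head is always re-initialized
fresh (seeded). Strict mode requires an exact fingerprint match and errors
naming the offending tensors; non-strict copies only shape-matching tensors.

## Demographic reweighting and fairness reporting

Groups are sex × the age-50 split (the two axes available in this schema).
w(g) = 1/p(g) with p(g) computed on each *training fold* only, then rescaled
so the mean per-sample weight is 1 (Σw_i = n): the raw inverse-frequency sum
would grow with imbalance and act as a hidden learning-rate change,
confounding the fairness effect with an optimization effect.

Per cross-validation fold, subgroup F1 and error rate ((FP+FN)/n) are
computed on the test fold; the per-axis gap is the absolute subgroup
difference; the reported ΔF1 / Δerror is the mean of the per-fold gaps.
Gaps are in percentage points of whatever scale the metrics carry. A fold
in which one side of an axis has no test records is excluded from that
axis's mean and logged.

## Fuzzy multiple imputation

Donor similarity is a Gaussian kernel exp(−d²/2σ²) of the normalized
Euclidean distance over co-observed features — min-max-scaled numerics
(squared differences) and simple-matching categoricals (0/1 mismatch),
divided by the number of co-observed features. Defaults chosen once:
bandwidth σ = 0.5 on the normalized distance, m = 5 draws, donor pool
k = 20. Each draw samples min(k, #donors) donors without replacement;
numeric cells take the mean over draws of the membership-weighted subset
mean, categorical cells the category with the largest total membership
across draws (ties to the smaller code). Imputed values therefore always
lie in the observed value set of the field; observed cells are never
touched; a field with no complete donors raises an error listing the
affected rows. With k ≥ #donors every draw is the full pool, which makes
the bandwidth → ∞ limit exactly the donor mean (the property the tests
check). Within cross-validation the imputer is fitted on the training fold
only and applied unchanged to the test fold.

The stability report compares observed-cases statistics with the completed
data: per-numeric Δmean and Δvariance, and the maximum absolute change in
pairwise numeric correlations (pairwise-complete before vs complete after).

## Preprocessing

Min–max scaling is fitted on the training partition only; transform-time
values outside the fitted range are clipped to [0,1]; a constant training
column maps to 0. One-hot blocks expand each multi-level categorical over
its full declared domain in schema order (cp 4, restecg 3, slope 3, ca 4,
thal 3), binary fields pass through, giving 25 columns in a deterministic
order — checkpoints and attributions depend on it. Original outcome codes
1–4 (disease severity) are binarized to 1 on read. Stratification of the
k folds uses the binary outcome only; demographic balance is the
reweighting's job, not the splitter's.

## Shapley attribution

The coalition value v(S) is the model's mean output over a background
sample with the features in S set to the explained record's values
(background-marginal replacement; the background is 100 seeded training
rows, or all if fewer). One-hot blocks move as one coalition member, so
contributions land on the 13 original clinical features. Exact mode
enumerates all 2^k coalitions (k ≤ 12) with the factorial Shapley weights;
sampled mode averages marginal contributions over uniformly random
permutations — each permutation telescopes, so additivity
(φ0 + Σφ = prediction) holds to float precision in both modes, while
per-feature values converge to the exact ones with the number of
permutations. Coalition values are memoized per explained record.

## Synthetic cohorts

The generator emulates the 14-field schema: group (sex × age bin) drawn
from `group_mix`, age from a truncated normal within the bin, continuous
vitals from clipped normals (e.g. chol ~ N(246, 51)), categoricals from
fixed marginals roughly matching published summaries of the Cleveland
subset. The outcome is logistic in severity scores s_j ∈ [0,1] (numerics
scaled by nominal ranges, ordinal categoricals spread over [0,1],
thalassemia ordered normal < fixed < reversible defect) with default
log-odds coefficients emphasizing cp (2.6), oldpeak (2.2), thal (2.0),
thalach (−1.8, protective) and age (1.2) — so attribution methods have a
known ranking to recover.

The intercept is calibrated *per demographic group* (bisection) so every
group hits the requested prevalence; `bias_shift` then adds per-group
log-odds on top. This keeps subgroup prevalences equal at zero bias even
though age carries risk within each group, making the injected unfairness
the only between-group signal. Missingness is MCAR, by default confined to
`thal` (2/303) and `ca` (4/303). The separable preset scales all
coefficients fourfold and draws labels deterministically as 1{p > 0.5}
(with Bernoulli labels the scale-4 cohort has a Bayes accuracy of only
0.916, i.e. it is not actually separable).

What the generator does **not** emulate: the real joint dependence
structure of the Cleveland data (features are conditionally independent
given the group), measurement error, informative missingness, or temporal
structure. Passing tests therefore certify the machinery — contracts,
leakage safety, fairness arithmetic, attribution axioms — not clinical
performance on real cohorts. The "Cleveland-shaped stand-in" used by the
replication checks is such a synthetic cohort with n = 303 and exactly
2 + 4 cells masked; it matches the real file's shape and missingness
pattern only.

## Problem sizes used by the harnesses

Chosen once as the package's own scaled-down study conditions:

- **Separability sanity**: n = 400 separable cohort, tuned default
  configuration (128 units, lr 0.001, batch 32, Adam), 100 epochs, at a
  fixed cohort/training seed. 100 epochs sits on the shoulder of the
  learning curve, so training accuracy varies by several points across
  seeds (e.g. 0.97 vs 0.88); the documented condition is deterministic.
- **Reweighting efficacy**: per seed, train on a full n = 300 biased cohort
  (group mix 40/40/10/10, −1.0 log-odds on both female groups, coefficients
  ×3 so the signal is learnable at this budget; H = 24, 50 epochs), score
  both arms on one independently drawn n = 1500 cohort — subgroup F1 on a
  ~75-record fold is dominated by counting noise, a large fresh test set is
  not. 10–12 seeds.
- **Cross-validation demonstration**: k = 10 on the n = 303 stand-in with
  H = 32, 40 epochs.
- **Ablation grid in tests**: n = 90 cohort, H = 6, 2 epochs — it checks
  bookkeeping contracts (identical folds, variant flags, reduction of the
  no-TL/no-RA arm to the plain pipeline), not metric ordering.

## Known limitations

- The sequence view of a static record is a modelling convention; nothing
  temporal is actually measured.
- The scalar-token sequence with a last-state readout is **recency-biased**:
  columns late in the schema order (slope, ca, thal) influence the final
  state more than early ones (age, cp, oldpeak), and trained-model Shapley
  rankings reflect that — e.g. on the separable cohort the converged model
  ranks thal > cp > ca, recovering cp but not oldpeak among the generator's
  dominant effects. Alternative sequence constructions can be swapped in at
  `tabular_to_sequence`.
- The fairness comparison is an aggregate group-gap criterion; no
  equalized-odds or causal analysis is attempted.
- Exact Shapley enumeration is limited to 12 features; the 13-feature
  schema uses permutation sampling in practice.
- Headline accuracy/F1/AUC numbers on synthetic cohorts depend on the
  generator's Bayes rate and the scaled-down training budgets; they are
  demonstrations of the harness, not clinical claims.
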