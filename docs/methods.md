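# Methods

## Model and procedure

The package aggregates global feature-importance outputs from an ensemble
of N models trained on the same tabular dataset.  The pipeline is:

1. **Per-model normalization.**  Each model's raw importances are reduced
   to magnitudes (signed metrics such as linear coefficients lose their
   sign; sign/direction tracking is a non-goal) and normalized *within
   that model only*: either rank-transformed to 1..p (1 = most important,
   ties get the average of the ranks they span) or scaled to shares
   summing to 1.  Normalization is strictly column-wise so that models
   with incommensurable importance scales never contaminate each other.
2. **Model weights.**  Equal weights 1/N by default.  Optionally a softmax
   over held-out performance, w_j ∝ exp(perf_j / T): performances must be
   higher-is-better and come from validation folds, never the training
   fit, or the weighting rewards overfitting.  The temperature T (default
   1, the plain exp-performance softmax) exists because a 0.01 accuracy
   gap and a 0.3 R² gap should not be forced through the same exponential;
   the choice is the practitioner's and is explicit.  The softmax is
   computed shift-invariantly (max subtracted), so only performance
   *differences* matter.
3. **WIS** = Σ_j w_j R_j(f): with equal weights and rank normalization
   this is exactly the mean rank.  The orientation (lower-is-better for
   ranks, higher-is-better for shares) travels with the scores as a typed
   value; mixing orientations silently is an error by construction.
4. **FC** counts models whose rank of f is ≤ k.  It is deliberately
   unweighted — FC is the consistency axis and every model gets one vote —
   and k defaults to 10.  A k-sweep helper reports FC across several k,
   since genuinely robust features keep high FC over a range of k.
5. **Derived outputs.**  Composite C(f) = WIS·FC/N, defined only on the
   higher-is-better WIS scale (rank-based WIS must pass through the
   inversion p + 1 − WIS first; otherwise the product would *reward*
   inconsistency).  Joint selection: FC fraction ≥ 0.5 and WIS in the top
   quartile (nearest-rank quantile, boundary inclusive).  Categories:
   crossing high/low WIS (same quantile rule) with high/low FC gives
   robust / model-specific / consistently-moderate / low-signal.  Final
   ranking: WIS first, higher FC breaks ties, lexicographic feature name
   breaks exact ties so the order is a reproducible total order.

### Missing features

When models report different feature sets, the matrix is built over the
union.  Default fill: worst rank p (or share 0) — a model that never
surfaces a feature is treated as evidence against it, consistent with
non-appearance in a top-k being a non-vote.  The alternative `EXCLUDE`
policy leaves the cell empty and renormalizes the model weights per
feature over the models that did report it; use it when models genuinely
saw different candidate pools rather than merely disagreeing.

### Default k

The two-feature worked example annotates its FC values as "top-3", but
those values (1.0 and 0.8 over ranks [1,2,4,1,3] and [1,8,2,15,1]) are
only consistent with thresholds between 8 and 14 — rank 4 must count, rank
15 must not.  The package therefore uses the general default k = 10, which
reproduces the printed FC values, and does not attempt to guess the
annotation's intent.

## Model harness

The diverse suite is: logistic regression / linear regression
(standardized, |coefficients| as importance), decision tree (depth 5 — a
deliberately simple, interpretable baseline), random forest and gradient
boosting (impurity importance; the gradient booster is scikit-learn's
generic implementation), and an RBF-kernel SVM with permutation
importance as its model-agnostic attribution.  Performance is the mean
over repeated, seeded CV folds (accuracy for classification, R² for
regression by default); importances come from a refit on the full data.
Permutation importance computes the baseline once and averages the
metric drop over seeded column shuffles (default 5 repeats).  No
hyperparameter tuning is performed; tuning is the caller's concern.

## Synthetic cohort generator

`generate_cohort` emulates the small-clinical-cohort regime: n = 300
rows, p = 20 standard-Gaussian predictors, s = 5 informative ones with
effect magnitudes spaced linearly over [0.5, 1.5] and alternating signs,
outcome drawn through a logistic link (binary, default) or as the linear
signal plus N(0, 1) noise (continuous).  Optional equicorrelated blocks
(consecutive blocks of 5, within-block correlation rho, off by default)
model redundant predictor groups.  `disagreement_rankings` skips data
generation entirely and perturbs a shared ground-truth importance order
with Gaussian rank noise — a direct simulation of explainer disagreement.

What the generator does **not** emulate: non-Gaussian marginals, mixed
categorical/continuous predictors, missingness, interactions,
non-linear effects, class imbalance, or the covariate structure of any
real registry.  Passing recovery tests therefore demonstrates that the
aggregation machinery behaves correctly under a known linear-logistic
truth, not that it recovers risk factors in real clinical data.

Because the generator's truth *is* linear-logistic, the linear ensemble
member is the correctly specified model for it.  One measurable
consequence (seen in the bootstrap stability experiment): the linear
model's own top-5 can be slightly more stable than the consensus, which
averages in deliberately volatile members such as the shallow tree.  The
consensus is still far more stable than the volatile members and within a
few hundredths of the best single model — but strict dominance over a
correctly specified oracle is not a property this benchmark can
demonstrate, and the corresponding directional test documents that
honestly by failing under these conditions.

## Stability evaluation

B = 20 bootstrap resamples of the rows (bootstrap rather than CV folds:
it resamples the same experiment rather than partitioning it); every
method — each single model's magnitude-ordered top-k and the consensus
top-k — is evaluated on the identical resample sequence.  The metric is
the mean pairwise Jaccard index of the B top-k sets.  Problem sizes
(B = 20, k = 5, 3-fold CV inside each resample) keep a full experiment
around a minute on one CPU.

## Numerical choices

- Weights validated to sum to 1 within 1e-12; sum-scaling is idempotent
  and sums to 1 within 1e-12.
- Nearest-rank quantile with inclusive boundary for all "top quartile"
  cuts: with 4 features and q = 0.25, exactly the best feature qualifies.
- Sorting uses a stable mergesort so tie behaviour is reproducible.
- Degenerate inputs fail loudly: all-zero importance vectors, single-class
  outcomes, empty feature sets, orientation mismatches and misaligned
  weight vectors are all errors, not silent coercions.

## Known limitations

- Correlated predictors split votes: two redundant features can each end
  up with moderate WIS and reduced FC even when their shared signal is
  strong.  Interpret feature groups collectively; clustering before
  aggregation is out of scope.
- FC is gameable in isolation (a feature sitting at rank k in every model
  scores FC = N); that is why WIS and FC are reported together.
- No confidence intervals on WIS/FC and no hypothesis test on stability
  differences; both are deliberate non-goals.
- Aggregation of local (per-instance) explanations is not supported.
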