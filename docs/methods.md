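# Methods

This note records the modeling choices, the defaults and why they were
chosen, what the synthetic benchmarks do and do not show, and the numerical
conventions used throughout.

## The cascade

One binary classifier per task per layer, all random forests with a shared
configuration: `n_estimators = 500`, `max_features = ⌊log₂(w)⌋` where w is
the width of the *current* layer's training matrix (so 10 for a 1024-bit
layer 1 and still 10 for a 1072-wide stacked layer), `random_state = 8`.
These are the reference settings of the method; they are deliberately not
tuned per task.

Layer 1 consumes the raw fingerprints and is bit-identical to independently
trained single-task forests (this equivalence is asserted in the test
suite). Layer k ≥ 2 consumes the original fingerprints concatenated with
**only the immediately previous** layer's T score columns — widths are
m + T, not cumulative. The task's own previous-layer score is included by
default; `include_own_score=False` removes it (an ablation switch — the
own-score contribution is small but positive).

Score features for a task's own training chemicals are direct predictions
from the previous layer (whose model saw those chemicals in training); no
out-of-fold scheme is used. This matches the method's published procedure
and keeps the layer recursion identical at train and predict time; the
memorization it introduces is visible to the validation-based layer
selection, which is what guards against it.

**Splits.** 70/10/20 train/validation/test per task, stratified by label
with largest-remainder rounding (realized counts match the fractions to
within one chemical per class). Stratification is a deliberate choice:
heavily imbalanced tasks (≤ 10% minority) would otherwise frequently draw
single-class 10% validation splits. Each task is split independently; the
per-task seed is derived from the master seed and a CRC32 of the task name
so adding or removing a task never reshuffles the others.

**Stopping and selection.** Layers are added while the mean validation AUC
strictly improves (patience 1); the first non-improving layer is retained
for inspection but the selected layer is the argmax, so a non-improving
layer is never selected and the selected layer's mean validation AUC is
≥ layer 1's by construction. Ties (no strict improvement) stop growth —
the earlier layer wins, favoring the cheaper model.

**Undefined AUCs.** A task whose validation (or test) split contains one
class gets AUC = NaN, is excluded from the layer mean, and triggers a
warning. No imputation is attempted.

**AUC** is the rank-based (Mann–Whitney) statistic with midrank ties:
P(score⁺ > score⁻) + ½ P(tie). It equals brute-force pair enumeration to
1e-12 (asserted against that oracle).

**Persistence.** A model directory holds a JSON manifest (format version,
task order, forest parameters, per-layer validation AUCs, selected layer,
feature length) plus one joblib file per (layer, task) classifier; see
`FORMAT.md`. `load(save(model))` reproduces predictions bit-identically
(asserted).

## Chemical-space diagnostics

- *Common-chemical percentage* between two dataset groups: for each of the
  n × m subset pairs, 100·|common ids| / |union of ids| (the union — "unique
  chemicals in both subsets" — is the denominator); the maximum over subset
  pairs is reported.
- *Average similarity*: each subset pair contributes the mean Tanimoto over
  all its cross-pairs of chemicals; the unweighted mean of the n × m
  subset-pair means is reported (not one pooled mean over all chemical
  pairs — the average is over subset-pair values). A chemical present in
  both subsets contributes its self-similarity of 1; this matches the
  observed behavior of heavily overlapping dataset pairs reporting
  near-100% similarity.
- *Task label correlations*: Pearson |r| over chemicals labeled in both
  tasks, binned low (< 0.3), medium [0.3, 0.5), high [0.5, 0.7), very high
  (≥ 0.7). Pairs with fewer than `min_shared = 3` shared chemicals, or zero
  label variance on the shared set, are uncategorized — two shared points
  always give |r| = 1 and are uninformative, hence the floor of 3.
  Correlations are computed on the binary labels.
- *PCA* treats bits as reals, mean-centers, and does no further scaling
  (standard practice for fingerprint PCA). The full SVD solver is used for
  determinism; explained-variance fractions are checked against a dense
  eigendecomposition oracle.

Structure handling: ECFP "diameter 6" is Morgan **radius 3** (toolkits
parameterize by radius). Deduplication keys on canonical SMILES, not raw
text. Multi-fragment entries are rejected as mixtures rather than desalted
— no desalting protocol is assumed, so the conservative choice is to reject
and report. Threshold comparisons follow the printed operators exactly
(≤/≥ inclusive, > strict); missing endpoint values propagate as missing
labels and exclude the chemical per-task, not globally.

## EZ Metric

A weighted sum of binary endpoint calls (4 endpoints at 24 hpf, 17 at
120 hpf in the reference roster). Weight values are **configuration, not
code**: the published weights live in supplementary material of the source
study and may be revised, so the module takes a YAML mapping
endpoint → {weight, group}; `examples/ez_weights_uniform.yaml` is a
clearly-labeled uniform placeholder. Missing calls are skipped by default
(`missing_policy="skip"`), mirroring the standard treatment of endpoints
that were never measured; `"error"` is available for strict pipelines.
The score is monotone in any 0→1 call flip and bounded by [0, Σ weights]
(property-tested).

## Downstream ZF augmentation

`augment` appends the cascade's best-layer binary calls (threshold 0.5 —
the method itself publishes no threshold, so the conventional one is used)
to an external task's fingerprint matrix; 1024 + 48 = 1072 columns in the
reference configuration. Feature selection operates over the T ZF columns
with the fingerprint block held fixed (the ZF block is where redundancy is
expected; a flag allows selecting over everything). The search is
sequential backward elimination with conditional inclusion (floating):
remove the candidate whose removal maximizes stratified k-fold CV AUC;
after each removal, re-admit an excluded candidate when that strictly beats
the best score recorded at the resulting size; return the best subset seen
anywhere (ties → smaller set, then lexicographically first — the tie rule
is this implementation's convention). The best-seen rule guarantees the
selected set's CV AUC is never below the full candidate set's. Subset
scores are memoized; CV folds are stratified; the same forest configuration
is used for subset scoring and the final model.

Repeated evaluation draws R stratified 80/20 splits with per-run seeds
derived from the master seed via `SeedSequence([master, run])` (documented
counter scheme, always < 2³¹); selection and fitting see only the training
split of each run (leakage is tested for).

## Synthetic benchmarks

The generator emulates a multi-source toxicity compilation:

- **Pools.** Each pool has a prototype bit pattern (density 0.10); a
  chemical is the prototype with per-bit flips (probability 0.15). Pool
  structure: `shared` (all tasks, one pool), `disjoint` (tasks partitioned
  over pools; zero chemical overlap across pools), `mixed` (tunable overlap
  with a shared pool). Tasks in one pool use identical chemicals —
  mirroring real compilations where one lab's chemical list serves several
  endpoints.
- **Labels.** 16 latent dimensions × 4 signal bits each; signal bits are
  fair coins for every chemical so the latent vector z (standardized group
  sums) is comparable across pools. Task t thresholds
  w_t·z + ε, with w_t = ρ·w_shared + (1−ρ)·w_private (unit norm),
  ε ~ N(0, 0.25), then flips labels with probability `label_noise`. The
  threshold τ_t is the empirical quantile chosen so the *post-flip*
  positive fraction hits the target; targets unreachable under the noise
  level raise an error. Realized positive fractions land within ±0.05 of
  target for ≥ 200 chemicals per task (tested).
- **Why labels come from a latent, not from bits directly:** cross-task
  signal must survive disjoint bit-space pools — z is a global function of
  the bits, so one task's model scores another pool's chemicals
  meaningfully. That is precisely the transfer channel the cascade needs.

**Transfer benchmark** (`transfer_benchmark_config`): 8 tasks × 400
chemicals, 4 disjoint pools, latent dim 16, label noise 0.1, positive
fraction 0.3, ρ = 0.9. The fingerprint length is 256 bits and benchmark
forests use 150 trees: at the log₂ max-features rule this keeps the
per-split chance of drawing signal bits high enough for forests to learn at
this scale, and keeps the 10-replicate study fast on a single CPU (the
500-tree reference configuration is exercised separately by the layer-1
equivalence check, where it matters). Under these conditions the selected
layer beats layer 1 on test data in 10/10 replicate seeds with a mean gap
≈ 0.12, converging at layers 3–5; at ρ = 0 the mean gap is ≈ 0 (the
selection rule usually returns layer 1).

**Downstream benchmark** (`zf_downstream_benchmark`): a cascade is fitted
on the transfer benchmark; 4 × 75 = 300 *fresh* chemicals (never seen by
any model) are drawn from the same pools — the scale of a typical
downstream developmental-toxicity set — and labeled by a consensus rule:
toxic when many of the benchmark's task labeling rules fire. That is a
signal the cascade's binary predictions encode directly, while a
fingerprint-only forest must rediscover a sum of thresholded latent
projections from a few hundred compounds. Over 20 paired 80/20 splits the
augmented model's mean test AUC is consistently higher; its across-run
variance is smaller at the canonical benchmark seed, but the variance
comparison is intrinsically noisy at 20 runs (the sampling variance of a
variance is large) and the reduction is not significant at every seed —
a known limitation of the benchmark, not of the augmentation code path.

**What these benchmarks do not show.** Synthetic chemicals are prototype
bit patterns, not molecules: there is no structure-activity landscape, no
scaffold clustering, no assay noise heteroscedasticity, and the latent
label model is linear before thresholding. Passing benchmarks demonstrates
that the machinery transfers signal when relatedness exists and abstains
when it does not — they say nothing about the AUC attainable on any real
compilation.

## Degenerate inputs and numerical conventions

- Tanimoto of two all-zero vectors is defined as 0.
- AUC and Pearson raise on single-class / zero-variance inputs rather than
  returning a default.
- Forests run with `n_jobs = 1`; all results are deterministic given seeds,
  across runs and platforms, up to the forest library's floating-point
  reproducibility.
- Empty prediction inputs return empty score matrices, not errors.
- Stratified splitting requires ≥ 2 chemicals per class; it raises a
  SplitError naming the task otherwise.
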