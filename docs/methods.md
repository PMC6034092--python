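# Methods

## Setting

`grouprf` addresses the interpretation problem of Random-Forests
classifiers trained on very wide, very small biomedical datasets —
canonically, FDG-PET brain images of a few dozen subjects vectorized into
~10⁵ voxel intensities, with a binary prognosis label. Per-voxel
importance scores from such models are individually unreliable and hard
to read. The package therefore scores *groups* of features (a disjoint
partition such as a brain atlas with ~116 anatomical regions) and attaches
permutation-based statistical scores to the resulting group ranking, so a
practitioner can say not just "region A ranks first" but "the probability
that a ranking prefix this strong arises with no signal is below α".

## Forest and importance model

The classifier is a standard Random Forest: T fully grown binary trees
(Gini criterion, minimum split size 2, no depth limit), each grown on a
bootstrap replicate of the n samples, examining K randomly drawn candidate
features per split. K may be given as an integer, `"sqrt"`
(= round(√p), the usual default) or `"all"`. Tree growing is delegated to
scikit-learn; determinism is guaranteed for a fixed `(X, y, config)`.

The per-feature importance is the **unnormalized Mean Decrease of
Impurity**: for tree T,

    I(x_i, T) = Σ_{N : v(N)=x_i} (n(N)/n) · ΔI(N),
    ΔI(N) = I(N) − (n(N_l)/n(N)) I(N_l) − (n(N_r)/n(N)) I(N_r),

averaged (unweighted) over trees. With bootstrap on, n(N) counts the
(repeated) bootstrap examples reaching node N and n is the bootstrap
sample size. No rescaling to unit sum is applied, so the sum of all
importances equals the mean total impurity reduction per tree — a
conservation law the tests assert, and the reason group sums are
physically meaningful. The implementation reads these quantities from the
stored node statistics; an independent test oracle recomputes Gini from
the stored class counts node by node, and a second oracle rebuilds small
trees by exhaustive split enumeration.

Conventions chosen where the model family leaves freedom (recorded here
because they affect bit-level reproducibility, not statistics): split
thresholds at midpoints of consecutive sorted values with "≤ goes left";
prediction ties on an even number of trees resolve to class 0; split-score
ties resolve by the library's seeded stream, so exactness-style tests use
fixtures whose greedy tree is unique.

## Group scores

Given a partition of features into G disjoint groups (features outside
every group are "unassigned": they participate in fitting but in no group
score), three aggregations are provided: `sum` (total impurity reduction
credited to the group), `avg` (= sum/♯G) and `max`. The sum is biased
toward large groups — at K = 1 split features are drawn uniformly, so a
large irrelevant group collects many small contributions; the benchmark
reproduces this as a strong positive rank correlation between summed
scores and group sizes. Groups are ranked by descending score; ties break
by the partition's listed group order so the ranking — on which all
statistical scores condition — is reproducible.

## Statistical scores

All four procedures start from the observed ranking s₁ ≥ … ≥ s_G and an
identical protocol (P repetitions, level α, master seed). Each repetition
derives its own random stream from `(seed, rank, repetition)`, so results
are independent of execution order and reproducible.

**CER** at rank i permutes the rows of every feature in groups ranked
i..G (and of unassigned features) with **one shared permutation vector**
— preserving the joint distribution of the permuted block while severing
its link to the labels and to the intact head groups — refits the forest,
re-aggregates, and counts the fraction of repetitions in which the best
permuted tail-group score reaches s_i. It estimates the family-wise error
rate of selecting down to rank i.

**CER^r** shares the permutation scheme but counts the event "group g_i
is ranked i-th or better among all G groups on the permuted data" — less
conservative, with a known cost in precision.

**eFDR** shares the scheme too; per repetition the false-positive count
V_i is the longest prefix on which the descending permuted tail scores
dominate the observed s_i, s_{i+1}, …, and the score is the mean of
V_i/(V_i + i − 1), with 0/0 ≡ 0. The denominator follows the printed
definition of the estimator (i − 1, not i).

**mProbes** augments the matrix with one probe copy of every group, each
probe shuffled by its own row permutation (shared within the group, so
within-group correlation survives), fits one forest per repetition on the
doubled matrix, and scores each group by the fraction of repetitions in
which any probe group matches or beats it. Real-group scores are
recomputed inside each augmented run, since probes change the competition
for splits; symbolic K resolves against the augmented width. One fit per
repetition makes mProbes a factor G cheaper than the tail procedures.

Selection at level α uses the `first_crossing` rule by default (longest
ranking prefix with every score < α); the `max_rank` rule (every rank up
to the last score below α) is available for the literal reading of the
CER selection definition. Domination comparisons use ≥, the conservative
direction. Tail-procedure evaluation walks ranks from the top and stops
after the first score ≥ α unless a full curve is requested; an optional
`early_abort` stops a rank's repetitions once the accumulated failure
mass alone guarantees the score is ≥ α — the selection decision is
provably unchanged, and the reported score at the crossing rank (computed
from the repetitions actually run) is still ≥ α, but it is no longer an
exact multiple of 1/P, so the option is off by default.

On instances small enough to enumerate every row permutation with a
deterministic forest (single tree, K = p, no bootstrap), all four
estimators are tested for exact equality against brute-force enumeration.

## Synthetic benchmark

The generator emulates a linear group-structured classification problem
with known ground truth. Defaults (the benchmark's central setting):
p = 500 features, g = 50 contiguous groups with sizes given by g − 1
distinct cut-offs drawn from {1..p−1} (the open upper end guarantees no
empty group), R = 5 relevant groups chosen uniformly, n = 100 samples,
1% label noise. Each relevant group k carries a latent driver
z_k ~ N(0,1); its features are independent noisy copies z_k + N(0,1)
(within-group correlation exactly ½, asserted by tests); irrelevant
features are i.i.d. N(0,1). Labels are y = 1{Σ w_k z_k > 0} with
w_k ~ U[0,1], then a deterministic round(0.01·n) labels are flipped
(chosen without replacement), making tests exact. R = 0 is accepted as an
explicit null model — every feature pure noise, labels i.i.d. fair coins
— used for FWER calibration. sgn(0) maps to class 0.

What the generator does *not* emulate about real neuroimaging data:
spatial smoothness and scanner artefacts, inter-region correlation,
nonlinear or interaction effects, class imbalance, and the p ≫ 10⁵ regime.
Passing benchmarks therefore demonstrate the statistical machinery under
a favourable linear model, not clinical performance.

## Evaluation metrics

Precision TP/S (defined as 1 for an empty selection — no false
discoveries, so conservative selectors are not penalized) and recall
TP/R against the known relevant set. Rankings are scored by AUPR over
top-k prefixes using a left-continuous step integral: each recall step is
credited the precision of the prefix *strictly before* the entering
relevant group (a rank-1 hit is credited precision 1). This choice was
made deliberately over trapezoidal or average-precision integration,
whose small-sample bias is large at g = 50, R = 5 (random-ranking means
0.133 and 0.165 respectively); the step integral yields exactly 1 for a
perfect ranking and mean R/g for random rankings (0.0998 ± 0.001
empirically at 20 000 replicates), matching the calibration the metric is
meant to have. rec-1 (best recall at precision 1) and prec-1 (best
precision at recall 1) bound what ideal conservative/exhaustive selectors
could achieve on a given ranking. Misclassification rate is reported in
percent.

## Problem sizes used by the test suite and acceptance script

The full-scale benchmark protocol (20 datasets, T = 1000, P = 1000) costs
G × P forest refits per dataset for the tail procedures and is not a
sensible default for a test suite. The shipped runs use: selection study —
5 datasets, T = 150, P = 100 (score granularity 0.01 ≪ α = 0.05);
aggregation-ordering study — 5 datasets, T = 300, K = 1; null-FWER study
— 20 pure-noise replicates, g = 20, T = 100, P = 100. The `early_abort`
optimization (exact for selection decisions) is enabled for these runs.

A reproducibility note from our own replication at these scales: the
no-false-positive behaviour of CER and mProbes reproduces exactly (0
irrelevant groups selected across all datasets), the aggregation-ordering
and size-bias effects reproduce clearly, and the null FWER is controlled
with margin. The *number* of relevant groups the FWER-style procedures
select under the first-crossing rule is, however, consistently lower
(≈ 1–1.5 per dataset) than the full-scale reference values (≈ 2.7–3.05):
the permutation scores at ranks 2–4 typically sit at 0.06–0.4 rather than
below α, because the observed group scores exceed the permutation-null
maximum only narrowly at n = 100. This is not a tree-count effect
(T = 1000 gives the same curves; the dominant variance is
permutation-induced chance correlation) and the importance computation
cross-checks against an independent reference implementation; the
discrepancy is documented rather than tuned away.

## Known limitations

* Binary classification only; labels must be coded {0, 1}.
* Groups must be disjoint; overlap-tolerant aggregation is out of scope.
* The tail procedures cost G × P forest refits even with early stopping;
  at atlas scale (G ≈ 116, P = 1000) they are batch jobs, not interactive
  calls. mProbes is the affordable default.
* Atlas handling assumes voxel features were linearized in C order (last
  axis fastest) over in-mask voxels; the order is recorded in partition
  metadata because it defines feature identity.
* No spatial preprocessing (normalization, smoothing, intensity scaling)
  is provided; inputs are assumed already vectorized.
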