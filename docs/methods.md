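# Methods

## Problem setting and model

Given *m* known drugs with a symmetric binary interaction matrix
**A** (zero diagonal, every drug having at least one partner) and a
symmetric similarity matrix **S** with entries in [0, 1] and unit
diagonal, the task is to score how likely a *new* drug *x* — described
only by its similarity vector **s**ₓ to the known drugs — interacts with
each known drug.

The local classification model (LCM) decomposes this into *m*
independent binary tasks.  Task *j* labels every other known drug by
column *j* of **A** and trains a classifier on the restricted similarity
matrix; drug *j* itself is excluded from its own training instances (a
self-pair is undefined in **A**).  Each task therefore handles *m − 1*
instances, never the ~*m*²/2 drug pairs a global pair classifier would,
which is what makes the approach fast and lets the engine scale linearly
in the number of tasks.

### Member classifiers

All members consume the similarity matrix directly and emit a decision
profile [p₊, p₋], p₊ + p₋ = 1.

**MLKNN.**  Distances are 1 − similarity, so the K nearest neighbors are
the K most similar training drugs; ties at the K-th position break by
ascending drug index (deterministic and seed-free).  The posterior is
Bayes' rule over the count of positively labeled neighbors, with prior
Pr[y=1] = (1+c)/(M+2) (c positives among M instances) and add-one
smoothed count tables over the K+1 possible neighbor counts; both tables
sum to one by construction.  Neighbor counts of training instances are
computed leave-self-out.  Default K = 5; tasks smaller than K+1
instances clamp K to M − 1.

**RLS.**  The dual solution w = (**S** + αI)⁻¹**y** with α = 0.5; the
query score is **s**ₓ·w.  Since the targets are 0/1, the raw score is
clipped to [0, 1] to form the profile.  Similarity matrices need not be
positive semidefinite, so the system is solved by LU factorization; a
ridge δI (δ doubling from 1e-8) is added only if the system is
genuinely singular.

**SVM.**  A C-SVC on the precomputed similarity kernel (box constraint
C = 1, solver tolerance 1e-7), through scikit-learn's libsvm binding.
The signed decision value is mapped to a probability by a Platt sigmoid
1/(1+exp(a·s+b)) fitted on the training decision values with
prior-smoothed targets (t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2)); the
smoothing regularizes the fit enough that resubstitution scores can be
used directly, which keeps every task cheap.  The sigmoid slope is
constrained to be non-positive so calibration is monotone in the score.
The calibration method is overridable (identity / clip / platt).

**Degenerate tasks.**  A target drug whose training labels are
single-class (no positive, or no negative) cannot train a discriminative
model; the engine then emits the smoothed empirical prior (1+c)/(M+2)
for every query and logs the fallback.  This keeps the score matrix
total and conservative.

### Dempster–Shafer fusion

Fusion operates on the frame Θ = {+, −}.  Per member *n*, reference
profiles R_k^n are the class-wise means of the member's decision
profiles on its own training instances (resubstitution — the literal
reading of "training instances belonging to class k"; no internal CV).
The likelihood s_k blends the member's posterior with the L2 proximity
of its profile to the class reference (see README for the formula);
likelihoods are clamped to [1e-9, 1−1e-9] so the Dempster normalizer
stays positive even for degenerate profiles.  Combining the two simple
support functions (focus {k} with degree s_k; focus {not-k} with the
joint opposing degree) under Dempster's rule gives the closed-form
per-member evidence e_k = s_k(1−s_j)/(1−s_k s_j); the test suite checks
this closed form against the generic BBA combination on a dense grid,
to 1e-12.

The fused class evidence is the product over members of w_k(n)·e_k(n),
normalized over the two classes (the normalizer is read as
*class-wise*; normalizing over members instead would only rescale both
classes equally and change nothing after normalization over classes —
so the two readings coincide here).  The weight
w_k(n) = |r_k(k) − r_j(k)|·|r_k(k) − r_k(j)| multiplies a between-class
and a within-class specificity of the references; weights are floored
at 1e-6 rather than renormalized, so an uninformative member is damped
but never hard-vetoes a class.  Note that because the normalizer
absorbs any common scale, only the ratio w₊(n)/w₋(n) affects the
result — the weight factor acts like a per-member class prior.

**Ablation variants** substitute the neutral element of one factor:
`no_posterior` replaces y(k) by 1/2 in the likelihood, `no_proximity`
replaces the exp(−distance) factor by 1, `no_weight` sets all weights
to 1.

**Baselines.**  The four unsupervised rules combine the members'
positive-class posteriors arithmetically.  The decision-template rule
scores e_k = 1 − (1/N)Σₙ‖yₙ − DT_k‖² with per-member class templates
(identical to the reference profiles); these values can be negative and
are used raw for ranking, so score matrices of this rule are not
probabilities.

## Evaluation protocols

**Hold-out CV (new-drug setting).**  Per repetition, a seeded fraction
of drugs is withheld with all their interactions; models train on the
remaining network and score each withheld drug against every training
drug.  All withheld pairs of a repetition are pooled into one
precision–recall curve summarized by step-wise average precision
(no linear interpolation; tied scores form one threshold group) — AUPR
penalizes highly scored false positives under the strong per-task class
imbalance, unlike ROC AUC.  A per-drug-mean mode is available behind a
flag.  Repetition seeds default to 1..R and are echoed in every report,
making reports bit-reproducible.  Repetitions whose withheld truth is
single-class are skipped with a warning.

**LOOCV degree bias.**  Each drug in turn is withheld; the method's
score vector over the remaining drugs is Spearman-correlated with those
drugs' degrees.  Both the signed mean and the mean of absolute values
are reported, since rank-vs-score sign conventions differ between
analyses; constant score vectors make the correlation undefined and are
excluded with a warning.  The NS baseline scores a target by the sum of
query similarities to the target's partners — directly proportional to
degree — while LP propagates each target's label column through the
row-normalized similarity graph with restart weight β (default 0.5; the
query node is appended with its similarity row).  Both are simplified
stand-ins shaped after the published descriptions, present to exercise
the bias analysis, not faithful reimplementations of the original
methods.

## Synthetic data

The generator plants the assumption the model relies on: drugs in the
same similarity cluster share interaction partners.  Groups get random
binary prototype profiles (p = 64 bits); drugs flip each prototype bit
independently with probability 0.1; similarities are Jaccard of the
noisy profiles.  Half of the cross-group pairs (rounded up, taken in
ascending group-distance order so every group participates) interact
with probability 0.8, all other pairs with background probability 0.05.
Defaults (m = 60, 4 groups) give pair density ≈ 0.33, matching the
density regime of curated dense DDI networks.  `degree_skew` makes
group sizes proportional to rank^−skew, producing the degree
heterogeneity the bias probe needs.  Isolated drugs are wired to one
random member of an interacting group so every drug has degree ≥ 1.
All randomness flows through one seeded generator; identical seeds give
bit-identical datasets.

What the generator does **not** emulate: real fingerprint sparsity and
bit correlations, transitive similarity structure between clusters,
heavy-tailed degree distributions, and any pharmacological mechanism.
Passing benchmarks on it show the pipeline recovers planted
cluster-interaction structure well above prevalence; they do not certify
performance on real pharmacovigilance data.

## Benchmark scale and numerical choices

The canonical desk-scale benchmark (`lcmds.benchmarks`) uses 20
independent datasets × 50 hold-out repetitions at 25% ratio.  Fifty
repetitions per dataset follow the standard protocol for this
evaluation; 25% hold-out keeps 45 training drugs so the K = 5
neighborhoods and both classes remain well-populated in almost every
local task (at 85% hold-out on 60 drugs, tasks shrink to 8 instances
and MLKNN degenerates to its smoothed prior).  The degree-bias probe
uses one dataset with degree_skew = 1.5 under full LOOCV.

On this benchmark all three members land within ~0.005 AUPR of each
other, close to the ceiling imposed by the 0.8/0.05 interaction
sampling noise.  Fusion therefore has little headroom: LCM-DS matches
or slightly exceeds its best member, removing the posterior factor
causes the largest (still small) drop and removing proximity a smaller
one, while the weight factor is neutral-to-marginally-harmful here —
with near-equally strong members, a per-member class-prior tilt cannot
help.  Heterogeneous member quality, as arises on real data, is where
the weight factor earns its place.

Other numerical choices: profile components are validated to sum to 1
within 1e-9; BBA masses within 1e-12; Jaccard of two all-zero profiles
is defined as 0 with a warning (similarity 0 is the conservative
choice); similarity diagonals are forced to 1 on load; matrices are
dense throughout (intended scale: up to a few thousand drugs).
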