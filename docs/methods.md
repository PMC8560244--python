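# Methods

This note records the models the package implements, the choices made where
the design was genuinely open, and what the synthetic benchmarks can and
cannot show.

## Information measures and the TAM approximation

All entropies are in bits with the convention 0·log 0 = 0. A split
candidate is invalid (never selected, never an exception) when its split
information is below 1e−12 — i.e. all records fall into one branch — or
when a continuous attribute has fewer than two distinct values.

The TAM criterion replaces ln x on (0, 1] by its third-order expansion
about 1, u − u²/2 + u³/3 with u = x − 1. Substituting x = a/b into p·ln p
and clearing denominators gives the closed rational form
a(a−b)(2a²−7ab+11b²)/(6b⁴), which the test suite verifies exhaustively
against the direct product for all 0 < a ≤ b ≤ 50. The approximation is
applied to all three terms of the gain ratio — parent entropy, conditional
entropy and split information — so the whole per-candidate scoring path is
free of transcendental calls; an instrumented counter around the module's
only `log2` wrapper enforces this. The 1/ln 2 prefactor is kept so the
approximated quantities remain in bits; since it multiplies numerator and
denominator alike it provably cancels in the ratio.

The cubic surrogate is accurate near balanced proportions and degrades fast
toward the extremes: the relative entropy error is ≈3.8% at a 50/50 split,
≈4.7% at 40/60, but ≈12.8% at 20/80 and unbounded as a proportion
approaches zero. What rescues attribute *selection* is that the distortion
is shared across candidates scored at the same node: on random two-class
selection problems with class and branch proportions in [0.2, 0.8], the
exact and approximated criteria pick the same best attribute in ≈95–97% of
draws (the `gain_ratio_rank_agreement` experiment). Trees grown in the two
modes can still diverge structurally, because near-tie decisions at a top
node cascade; on the default benchmark their test predictions agree on
roughly 90% of records while their accuracies differ by well under two
points.

## Continuous-attribute discretization

Candidate thresholds are the N interior equal-division points
A_i = MIN + i·(MAX−MIN)/(N+1), i = 1…N (default N = 10), each inducing the
binary partition [MIN, A_i] vs (A_i, MAX], membership closed on the left.
All N candidates are evaluated; ties go to the smaller threshold. The
classic alternative — midpoints between consecutive distinct sorted values —
is available behind `midpoint_candidates=True` but is off by default, since
the equal-division rule is what makes the candidate count independent of
the node size. Both children of an interior threshold are necessarily
non-empty, so recursion always shrinks node sizes.

## Tree induction

At each node every available attribute is scored (categorical: multiway by
level; continuous: best discretized threshold). Candidates with gain below
1e−12 are dropped — splitting on them cannot improve purity — then the
"at least the mean gain ratio" filter is applied over the valid candidates
and the largest survivor wins, ties broken by attribute name then
threshold, so builds are bit-reproducible. Categorical attributes are
consumed along a path; continuous attributes may recur with new thresholds.
A level absent at a node becomes a leaf child carrying the parent's class
distribution, which is also what prediction returns when it meets an
unseen level. There is no pruning; `max_depth` (25) and
`min_samples_split` (2) are the only regularizers, so trees deliberately
overfit noisy data exactly as an unpruned C4.5 would.

## Network training

One hidden layer of sigmoid units by default. Weights start
Glorot-uniform, biases at zero, deterministic per seed. The
cross-entropy/softmax head trains by full-batch gradient descent; the loss
is summed (not averaged) over records, so step sizes comparable across
sample counts require a learning rate ∝ 1/m — the comparison harness uses
0.3/m. The optional L2 term is (λ/(2m))·Σθ² over weights only.

The LM trainer works on the sigmoid-output head and E = ½Σ(d−y)², the form
a residual-based method needs. The Jacobian is assembled from per-sample,
per-output reverse-mode passes; (JᵀJ + µI)Δ = −Jᵀe is solved as a linear
system, never by explicit inversion. µ starts at 1e−3 and multiplies or
divides by 10 on rejection/acceptance (floored at 1e−12; a numerically
singular solve counts as a rejection); only strictly improving steps are
accepted, so the accepted-loss trace is strictly decreasing. Training stops
at the iteration cap, when the loss change falls below `tol`, when the
gradient vanishes, or when µ exceeds 1e12 without an acceptable step —
the last indicating a local minimum, which on the classic XOR task happens
for a minority of random starts (both trainers fail on those starts; the
2-2-2 XOR landscape is the textbook example).

Because LM reaches sharp minima in tens of iterations, on noisy data it
memorizes label noise that slow gradient descent never gets to. The model
wrapper therefore supports the standard remedy from classic LM
backpropagation practice: `validation_fraction` holds out a slice of the
training data and the fitted model is the iterate with the best validation
accuracy. The comparison harness applies the same protocol to both
trainers so neither gets an unfair early-stopping advantage.

## Joint model and evaluation

The two members are combined by convex probability averaging — the simplest
rule that strictly generalizes both members. With `validation_grid` the
members are trained on four fifths of the training data and w_tree is
picked from {0, 0.1, …, 1} on the held-out fifth (ties to the smaller
weight); the members are not refit afterwards, keeping the weight an
honestly held-out choice.

MAE/MSE/RMSE/MAPE are defined with absolute values as usual. Applied to a
classifier they compare the predicted probability of the true class with
1.0, which keeps them bounded, well-defined (T_i = 1 never vanishes) and
sensitive to calibration. MAPE is reported as undefined when any truth is
zero; the other metrics are still computed. Recall is per class, macro
averaged over classes present in the test set.

## Synthetic data

The generator emulates screening corpora: a latent risk class (default
three: low/moderate/high), Likert items drawn from class-conditional
multinomials over five levels whose mode shifts with the class and whose
sharpness is 0.5·separation per level of distance, and continuous activity
features from unit-variance Gaussians whose means sit at regular-simplex
vertices with side `separation` — so `separation` is the between-class
distance in within-class standard deviations and a single dial controls
both feature families (at 0 the data carry no signal at all and any
model's accuracy collapses to the largest class weight). Labels flip to a
random other class with probability `label_noise`. Likert items are typed
categorical to exercise multiway splits even though semantically ordered.

The default benchmark is 2000 records, uniform classes, 6 Likert items, 4
activity features, separation 2.5, 5% label noise, cut into 10 near-equal
shuffled folds of which 6 train and 4 test (1200/800). These sizes keep a
full five-model comparison around a few seconds so that ten-seed protocols
remain routine on a single CPU. What passing tests on this generator shows
is that the implementations are correct and behave monotonically in signal
and noise; it does not show that any accuracy transfers to real screening
data, whose feature dependencies, ordinal structure and temporal
organization the generator deliberately omits.

## Numerical conventions

Softmax subtracts the row maximum before exponentiation; predicted
probabilities are clipped to [1e−12, 1−1e−12] inside the cross-entropy.
Sigmoid is evaluated in its numerically stable two-branch form. Argmax
tie-breaks take the lowest class index. Serialization rounds tree
distributions to 12 significant digits, which round-trips predictions
exactly at double precision for the comparisons made here.

## Known limitations

- No pruning and no missing-value handling; records with absent values are
  rejected at load.
- The TAM criterion's error explodes for proportions near 0/1; it is a
  speed-for-accuracy trade whose safe regime is interior proportions, and
  nodes deep in an unpruned tree routinely leave that regime.
- LM is a batch method: memory scales with samples × outputs × parameters,
  which is fine at questionnaire scale and wrong for millions of records.
- The joint rule is a fixed convex vote; no stacking or per-record gating.
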