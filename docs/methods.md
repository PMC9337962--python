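# Methods

## Scoring and discretization

Each indicator is scored by a sex-specific piecewise-linear table mapping
the raw measurement (kg/m², mL, cm, s, repetitions) to [0, 100]; values
outside the table clip to the end scores, and tables must be monotone in
the indicator's better direction (lower is better for BMI, the 50 m sprint
and the endurance run). The shipped tables are editable JSON configuration
in the spirit of national student fitness-test standards, not a
transcription of any official document; swap in official breakpoints via
`physfit export-config` / `--config`.

Scores discretize into four grades with left-closed bands: `[85, 100] →
excellent`, `[75, 85) → good`, `[60, 75) → medium`, `[0, 60) → poor`. The
published band descriptions overlap at 85 and 75; the left-closed reading
is adopted because it is the only convention consistent with "less than 60
is poor", and it makes `discretize` total and monotone on [0, 100].

Missing measurements are either dropped row-wise or filled with the
sex-stratified attribute mean (every indicator in the battery has
sex-specific norms, so pooling sexes would bias fills). Attribute
reduction removes attributes whose normalized mutual information with the
class label (MI / class entropy) falls below a threshold, default 0.01;
the most relevant attribute is always retained.

## Classic ID3

Standard greedy induction: expected information `I = −Σ pᵢ log₂ pᵢ`,
size-weighted split information `E(A)`, gain `G(A) = I − E(A)`, multiway
split on the argmax-gain attribute, recursion per subset. All logarithms
are base 2. Stopping: pure subset; exhausted or uniform attributes
(majority leaf); empty branch (parent-majority leaf). Numerical choices:

* gain ties break by candidate-list order (stable and reproducible);
* majority ties prefer the better grade, then the lexicographically
  smaller label;
* gains are compared with a 1e-12 slack so floating-point noise cannot
  flip an argmax.

Every internal node caches its training majority so that attribute values
unseen during training fall through to a deterministic label at
classification time.

The windowed trainer seeds a random window (default half the data, forced
to contain every class at least once when possible), builds a tree, adds
all misclassified out-of-window rows, and rebuilds, for at most
`max_rounds` (default 10) rounds. It is deterministic given its seed.

## Binary-simplified ID3

The two-class node information
`H = −(p/(p+n))log₂(p/(p+n)) − (n/(p+n))log₂(n/(p+n))` admits a
second-order Maclaurin surrogate: writing the minority fraction as x and
expanding `ln(1+x) ≈ x − x²/2` collapses the size-weighted sum of child
entropies, up to the constant `2/ln 2` and the parent-size normalization,
to

```
G′(F) = Σⱼ pⱼnⱼ/(pⱼ + nⱼ).
```

Because `G′` approximates the weighted **post-split** impurity rather than
the gain, the gain-maximizing split *minimizes* it; the implementation
minimizes, treating the published "gain value" label as an erratum. The
diagnostic `approximation_error(p, n)` reports the exact-vs-surrogate gap
for one node: ≈ 0.279 bits at balance, decaying monotonically (though only
like −q·log q) as the minority fraction q → 0, which is why the surrogate
ranks near-pure candidate splits reliably.

Candidate tests are one-vs-rest on (attribute, value) pairs — this honors
the strictly binary tree form with Y/N branches; an alternative
per-attribute reading (summing `G′` over an attribute's multiway
partition) is exposed as `attribute_simplified_gain` for analysis but not
used in construction. For more than two classes the criterion becomes the
Gini-style impurity `Σⱼ |Sⱼ|(1 − Σᵢ qᵢⱼ²)/2`, which the identity
`pn/(p+n) = |S|(1 − q₊² − q₋²)/2` makes exactly equal to `G′` in the
two-class case; alternatively, grades can be dichotomized
(positive = {excellent, good}) via `to_labeled_dataset(..., dichotomy=...)`
to run the algorithm in its native two-class form. A tested pair is never
retested on its own yes-path, and a depth cap (default 25) guarantees
termination on label-inconsistent data.

Empirically (and checked in the acceptance suite), the simplified
criterion selects a split of maximal exact information gain in ≳95% of
random two-class instances, and always in the near-pure regime where both
children's minority proportions are below 0.15 — the regime the expansion
is taken in.

## AHP weighting

Judgment matrices must be positive, unit-diagonal and reciprocal
(`m_ij·m_ji = 1` within 1e-9); reciprocity is enforced rather than the
looser symmetry sometimes quoted, since the Saaty scale and the
consistency machinery both presuppose it. Weights use the normalized
column-sum scheme — `t_ij = m_ij/Σᵢ m_ij`, `vᵢ = Σⱼ t_ij`,
`wᵢ = vᵢ/Σ vᵢ` — which is exact for consistent matrices
(`m_ij = wᵢ/wⱼ`); a full eigen-decomposition serves as an independent
oracle in the tests only. `λ_max = (1/n)Σᵢ(Mw)ᵢ/wᵢ`,
`CI = (λ_max − n)/(n − 1)`, `CR = CI/RI` with Saaty's canonical random
indices (0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45 for orders 1–9,
shipped as an editable table); CR < 0.1 passes, and orders 1–2 pass by
construction with CR defined as 0. For any positive weight vector on a
reciprocal matrix, `Σᵢ(Mw)ᵢ/wᵢ ≥ n²` by AM–GM on reciprocal pairs, so the
reported λ_max never falls below n.

The shipped hierarchy places the seven scored indicators under five
primaries (body composition, cardiorespiratory, flexibility, speed,
strength); its 5×5 judgment matrix ranks cardiorespiratory fitness
highest and flexibility lowest and has CR ≈ 0.015.

## Hierarchical evaluation, planted rule and recommendation

Composite scores are AHP-weighted means: secondaries → primary, primaries
→ overall. The categorical cascade mirrors this: per-primary trees read
secondary grades, the overall tree reads primary grades.

The synthetic ground truth (the *planted rule*) works on grade values, not
raw scores: each grade maps to its band midpoint (excellent 92.5, good 80,
medium 67.5, poor 30), primaries take the weighted mean of child grade
values and discretize, the overall grade repeats this over primary grade
values. Operating on grade values makes the label a deterministic function
of the secondary grades, so with zero noise both tree algorithms can (and
do) reproduce it exactly on training data — the consistency property the
test suite leans on.

Recommendation is a first-match rule table over the grade profile. The
default table fires on the weakest primary indicator (lowest grade, ties
broken by profile order, only when below excellent) and maps it to a mode
list (cardiorespiratory → aerobic running program; strength → resistance
circuit; flexibility → stretching/yoga; speed → sprint intervals; body
composition → mixed aerobic + dietary guidance), with a mandatory
always-matching maintenance rule. Totality is verified by enumerating all
4^(p+1) grade profiles at load time.

## Comparison metrics

Neither comparison metric has a standard closed definition in this
setting, so operational ones are used:

* **entropy ratio** — for each tree, sum `(|subset|/s)·H(subset)` over
  every node's routed training subset; report 100 × (improved sum /
  classic sum). Identical trees give exactly 100%.
* **information loss rate** — `100 × (1 − I(Y; Ŷ)/H(Y))` from the
  prediction/label contingency table: the share of label information the
  classifier fails to transmit. 0% for a perfect classifier, 100% for a
  constant one.
* **accuracy** — agreement with ground-truth labels on held-out rows. (In
  the original human study "accuracy" meant mean student-satisfaction
  scores on a 0–100 scale — a protocol requiring human subjects that is
  documented here but deliberately not imitated.)
* **relative time** — wall-clock training time, reported but never
  asserted: it is hardware-dependent.

One observation worth flagging: because the binary tree typically has many
more nodes than the multiway tree, its node-entropy sum is usually the
*larger* one on rich datasets (ratio > 100%), although on small groups the
two algorithms often produce structurally identical trees and the ratio is
exactly 100%. The ratio direction is therefore a property of tree shape
under this operational definition, not an asserted advantage of either
algorithm.

`compare` splits each group in half (seeded), trains both algorithms on
the training half, computes the entropy ratio there and the loss
rates/accuracies on the held-out half (falling back to the full group if
the held-out labels are single-class), and averages across groups. All
non-timing fields are reproducible under a fixed seed.

## Synthetic cohorts

`generate_cohort` draws each indicator from a sex-specific truncated
normal (scipy's `truncnorm` under a seeded generator), labels via the
planted rule, then applies label noise (flip to a uniformly chosen
different grade) and missingness (blank cells), in that order, so ground
truth always reflects the complete measurements. Defaults: n = 300, equal
sex ratio, zero noise and missingness.

The default distribution parameters model a relatively homogeneous student
cohort: locations sit in the medium/good score bands and spreads are tight
enough that each indicator's grades concentrate on one or two bands. This
is deliberate — it keeps the joint grade space compact enough that a
150-row training half covers the label function's support, which is what
makes ≥95% held-out accuracy at the 150/150 design achievable; it is also
the regime real test batteries are calibrated for (most students pass in
the middle bands). What the generator does **not** emulate: correlations
between indicators within a student (draws are independent given sex),
heavy-tailed or skewed measurement distributions, age structure, and any
real national norm. Passing tests therefore demonstrate the algorithms'
correctness and internal consistency on data with the assumed structure,
not performance on real cohorts.

Group layouts: `generate_grouped_cohort(5, 30)` mirrors the five-group
comparison design; the 300-subject cohort with a 150/150 split is the
accuracy design. Both are configurable — the two designs' sample
arithmetic is independent here.

## Problem sizes and runtime choices

The test and acceptance workloads use 1,000 random datasets (≤ 60 rows)
for oracle-agreement checks, 100 matrices per AHP property, cohorts of
150–300 for tree induction, 10,000 subjects for distributional
convergence, and 5 × 30 for the group comparison; the whole suite runs in
well under a minute on one core. These sizes were chosen to make every
statistical check stable at fixed seeds while keeping the package quick to
iterate on.

## Known limitations

* The simplified criterion is a two-class approximation; its multiclass
  generalization is Gini-style and can disagree with exact gain away from
  purity (by design — this is the trade the original simplification makes).
* The windowed trainer assumes the classic windowing loop; termination on
  inconsistent data relies on the round cap rather than a convergence
  proof.
* Scoring tables and recommendation mode lists are illustrative defaults,
  meant to be replaced by institution-specific configuration.
* AHP weights use the row-sum approximation, which deviates from the
  eigenvector method for strongly inconsistent matrices (exactly the
  matrices the CR test rejects).
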