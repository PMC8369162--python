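# Methods

## The model

The package treats AOP identification as binary classification of a protein
from its evolutionary profile. For a query of length L, a profile HMM's
match-state emission block is an L × 20 grid of scaled negative
log-frequencies; the normalization f(x) = 2^(−x/1000) (0 for the `*`
token) maps each cell into [0, 1], giving the frequency matrix
H = [h₍ᵢⱼ₎]. Columns are canonicalized to the alphabetical residue order
A..Y regardless of the order in the source file, so feature names are
stable across inputs and a feature-index subset chosen on one dataset is
portable to another.

Three descriptor families operate on an L × 20 position matrix, which may
be either H or the sequence's one-hot matrix B (so each descriptor has a
sequence-only and a profile-based variant):

* **AAC** (20): column means. On B this is exactly the residue frequency
  of the sequence.
* **DPC** (400): yᵢⱼ = 1/(L−1) Σₖ m₍ₖᵢ₎ m₍ₖ₊₁ⱼ₎, averaging
  adjacent-position products. On B this counts adjacent residue pairs. The
  profile variant is deliberately *not* renormalized to sum to 1; its raw
  scale carries information about per-position concentration.
* **ACC** (400·G): the lagged covariance z₍ⱼₖ₎(g) between columns j and k
  at lag g = 1..G, with the mean taken over the **full** column for both
  factors (one h̄ⱼ per column, not a per-window mean). The full 20×20×G
  tensor is kept — auto terms j = k and both directed cross terms — and
  flattened lag-slowest, then j, then k. The flattening order is arbitrary
  for the classifier; it is fixed and recorded in the component registry so
  selected index sets are reproducible. Mean-centering makes ACC invariant
  to per-column shifts: it sees only sequence-order structure, which is
  what makes it complementary to AAC/DPC.

Valid inputs use the 20 standard amino acids only; records containing
ambiguous codes (X/Z/B, also J/U/O) are rejected by default, or skipped
with a warning on request. G must satisfy 1 ≤ G ≤ L−1 for every sequence
encoded, i.e. G is bounded by the shortest protein in the dataset.

## Selection, balancing, classification

**ANOVA ranking.** Each feature's two-group F statistic is the ratio of
between-group to within-group mean squares. Degenerate cases: zero
within-group and zero between-group variance → F = 0; zero within-group
variance with distinct group means → an infinite sentinel that ranks above
all finite scores (ties among sentinels, and all other ties, break by
ascending feature index, so rankings are deterministic). A tolerance of
1e−12 × (per-feature squared magnitude) guards the zero-variance tests
against floating-point cancellation. The subset size is chosen by a
stepwise incremental sweep (default step 5, arbitrary size lists
supported, the full size always included), scoring each prefix of the
ranking by stratified k-fold CV accuracy with a fixed-hyperparameter
classifier; the smallest size attaining the maximum wins (parsimony
tie-break).

**SMOTE.** Minority samples are visited in seeded round-robin order (every
sample contributes once per pass before any repeats); for each, one of its
k = 5 nearest minority neighbours (Euclidean distance in the feature space
as given, post-selection and pre-scaling) is drawn uniformly and a
synthetic point X′ = X + u·(N − X), u ~ U(0,1), is added until the classes
are balanced. k defaults to 5 and is clamped (with a warning) to
minority−1 when the minority class is small. Synthetic rows are flagged by
id; originals pass through bit-identically.

**Classifier.** Standardization (zero mean/unit variance per feature,
fitted on training data; zero-variance features get unit scale) followed
by an RBF-kernel SVM. The hyperparameter grid is the 10 × 10 set of odd
powers of two, C ∈ 2^{−3..15}, γ ∈ 2^{−15..3}, scored by mean stratified
CV accuracy with ties resolved to smaller C then smaller γ. ROC scores are
raw margin decision values, not calibrated probabilities.

**Protocols.** Stratified k-fold (seeded), jackknife (leave-one-out), and
independent train/test. Every training-time computation — ANOVA selection,
SMOTE, scaling, grid search — is refitted inside each fold on the training
partition only; the per-fold fitted state (selected names, synthetic-row
count, scaler moments) is recorded in the report, which is what the
leakage-canary test inspects. Metrics pool confusion counts across folds
(each sample scored exactly once) and AUC pools the decision scores; this
pooled convention is the only one compatible with jackknife, where each
"fold" holds one sample. Undefined Sen/Spe (empty class in the evaluated
set) is reported as 0 with an explicit flag; a zero MCC denominator gives
MCC = 0 by convention. AUC is trapezoidal over the threshold-swept ROC and
equals the tie-corrected Mann–Whitney rank statistic (asserted in tests).

Whole-dataset oversampling before the CV split is supported only behind a
`resample_before_split` compatibility flag that emits a prominent leakage
warning: interpolated copies of test points then appear in training folds
and every metric is optimistically biased. The leakage-free fold-internal
protocol is the default, and near-ceiling CV numbers reported elsewhere
for this family of pipelines are typically only approachable under the
leaky ordering.

## The synthetic fixtures

Generated profiles draw each cell independently from
N(baseline = 0.25, noise = 0.08), clipped to [0, 1]; rows are not
constrained to sum to 1, as real normalized emission rows need not be.
Lengths are uniform on 50–70, comfortably above the G = 10 lag bound.
Class signal is planted two ways: raised baselines on chosen columns in
the positive class (a composition signal, invisible to ACC), and lagged
couplings m₍ᵢ₊g,ₖ₎ ← (1−ρ)·m₍ᵢ₊g,ₖ₎ + ρ·m₍ᵢⱼ₎ on chosen column pairs (an
order signal, visible only to the ACC component (j, k, g)).

Three named conditions are used throughout the tests:

* **standard planted** — 29/171 samples (1:6 imbalance, n = 200), six
  coupled pairs at lag 3 with ρ = 0.5 plus a 0.03 composition shift. The
  coupling is spread over several residue pairs because a realistic class
  difference touches many profile columns; a single informative component
  among thousands of noise components would be drowned in the RBF
  distance, which is a property of the fixture, not of the method.
* **weak/overlap** — same pairs at ρ = 0.15, no shift. Classes overlap, so
  the 1:6 imbalance actually biases the classifier; this is the regime in
  which fold-internal SMOTE measurably raises sensitivity. With the
  strongly separable standard fixture both balanced and unbalanced
  training saturate and the comparison is uninformative.
* **null** — no signal, balanced 100/100. The chance band for CV accuracy
  is then centred on 0.5; an imbalanced null would put the trivial
  majority-vote baseline at 0.86 and make "chance" ill-defined.

What passing on fixtures does and does not show: it verifies the
machinery — encoding identities, ranking, leakage-free protocol plumbing,
signal recovery at a planted effect size — but fixture profiles are
independent Gaussians with none of the positional autocorrelation,
gap/indel structure, or homology-driven column dependence of real HHblits
profiles, and the planted effect is not a claim about real antioxidant
biology. Performance numbers on fixtures say nothing quantitative about
performance on curated AOP benchmarks.

## Numerical and design choices

* Profile `.hhm` parsing consumes only the 20 emission columns of each
  match-state line; transition and diversity columns are ignored.
  Insertion states do not appear in emission blocks, so rows map 1:1 to
  match states. The fixture writer emits scores round(−1000·log₂ f), so
  parse → normalize recovers frequencies within the ±0.5-integer rounding
  bound f·(2^0.0005 − 1), which the round-trip test asserts.
* Fold seeds derive from the user seed as (seed·1009 + fold) mod (2³¹−1);
  all stochastic steps (fold shuffling, SMOTE, grid-search CV) consume
  seeds derived this way, making every report reproducible bit-for-bit.
* The default no-grid hyperparameters are C = 1 and γ = 1/d on
  standardized features (the usual 1/(d·Var) width heuristic, which
  reduces to 1/d after standardization).
* Problem sizes in tests and the acceptance script (n = 200 fixtures,
  G ≤ 10, 10×10 grid with 3 inner folds) were chosen so a full run
  completes in about a minute on one CPU while keeping the planted-signal
  recovery comfortably away from its thresholds.
* The experiment drivers report the sweep/ablation tables with the exact
  configuration snapshot attached, and the lag sweep asserts the
  substantive property — accuracy jumps when G first reaches the planted
  lag — rather than strict monotonicity between two pure-noise lags, which
  would be a coin flip.

## Known limitations

* No bundled real datasets or profile database; real-data use requires an
  external HHsuite installation via the `run_hhblits` hook.
* Only the two-class problem is implemented; the ANOVA ranking is written
  for two groups.
* Platt-scaled probabilities are not exposed; ROC uses margin scores.
* Jackknife on large tables is O(n) model fits and is intended for small
  datasets; use k-fold CV otherwise.
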