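# Methods

`golgicsp` classifies Golgi-resident proteins into the two terminal
cisternae — *cis*-Golgi (positive class) and *trans*-Golgi (negative
class) — from two inputs per protein: its amino-acid sequence and a
position-specific scoring matrix (PSSM) produced by iterative homology
search (PSI-BLAST `-out_ascii_pssm`; running the search itself is outside
the package — only the ASCII output is parsed). This note records the
model, the defaults and the numerical choices, and what the synthetic
test bed does and does not demonstrate.

## Feature extraction

**g-gap dipeptide composition.** For a sequence of length L, the
frequency of each ordered residue pair (a, b) separated by g intervening
positions is n_ab / (L − g − 1), giving a 400-vector indexed
alphabetically, first residue major (AA, AC, …, YY). The pipeline default
is g = 3 (correlations at a 3-residue interval track hydrogen-bonding
periodicity in secondary structure); g is exposed over 0–8. Dipeptides
touching a non-standard letter (B, J, O, U, X, Z) are not counted but the
denominator stays L − g − 1, so a fully standard sequence sums to exactly
1 and a sequence with ambiguity codes degrades gracefully rather than
being rejected.

**PSSM descriptors.** The L×20 score matrix E (columns in alphabetical
amino-acid order; the parser converts from PSI-BLAST's native column
order) is condensed into three 20×20 descriptors:

- *PSSM-DC*: entry (a, b) = Σ over positions whose query residue is a of
  E[i, b], divided by L. The summation rule "amino acid type a changed to
  type b" is read as grouping rows by the query residue; the alternative
  reading (consecutive-position products) would duplicate the bi-gram
  descriptor and is rejected. Positions with non-standard query residues
  contribute to no row but still count in L.
- *Bi-gram*: B[m, n] = Σ_{i=1..L−1} E[i, m]·E[i+1, n].
- *ED* (evolutionary difference): e[m, n] = Σ_{i=2..L−1}
  (E[i−1, m] − E[i+1, n])² / (L − 2); non-negative by construction, needs
  L ≥ 3.

Raw log-odds scores are used by default. Whether the original protocol
used the log-odds or percentage block of the ASCII file is ambiguous, so
a `pssm_scale: raw | sigmoid` switch exists (sigmoid: 1/(1+e^(−x)));
defaults were fixed before any evaluation and are not data-tuned.

## CSP projection

Each descriptor E is summarised by its normalised covariance
R = EE′/trace(EE′) (unit trace makes proteins comparable regardless of
score magnitude). With class means R̄₁, R̄₂ and composite Rc = R̄₁ + R̄₂:

1. eigendecompose Rc = Uc λc Uc′ and whiten with **P = λc^(−1/2) Uc′**,
   so P Rc P′ = I. (The −1/2 exponent is forced by the stated contract
   that all eigenvalues of P Rc P′ equal one; a −1 exponent would not
   whiten.)
2. S₁ = P R̄₁ P′ and S₂ = P R̄₂ P′ share eigenvectors B and their
   eigenvalues are complementary, λ₁ + λ₂ = I; directions where one class
   carries maximal variance carry minimal variance for the other.
3. W = (B′P)′, Z = W·E, and the features are the normalised log variances
   f_j = log(var(Z_j)/Σᵢ var(Zᵢ)) over the 20 columns of Z.

Numerical choices: eigenvalues of Rc below 1e−10 times the largest are
clipped to that floor before inversion (a non-positive eigenvalue raises
a degenerate-input error with a condition-number diagnostic); the
variance ratio is floored at 1e−300 before the log; population variance
(divide by 20) is used — the estimator choice cancels in the ratio.
Eigenvector columns of B are sign-fixed (first non-zero entry positive)
so serialized models are reproducible; eigenvalues of S₁ are sorted
descending so feature order is stable. The log-variance ratio is
invariant to global rescaling of E.

**Orientation.** The printed form takes column variances of Z = W·E with
W = (B′P)′; the conventional CSP readout takes row variances of
Z = (B′P)·E. These are not equivalent: the row form puts the most
discriminative filter output in f₁/f₂₀, while the column form mixes the
filters through each descriptor column, spreading the class signal over
all 20 features — and for a class difference confined purely to a row
subspace the column readout can miss it entirely. Both are implemented
(`csp_orientation: paper | standard`), the literal column form is the
default, and the synthetic end-to-end runs confirm the default detects
covariance-structured class differences when all 20 features are given to
the classifier. Single-feature threshold analyses should use the
`standard` orientation.

## Class balancing (SMOTE)

The real benchmark shape is 87 cis vs 217 trans. SMOTE equalises the
classes by generating minority points x + u·(x_nn − x), u ~ U[0,1], with
x_nn one of the k = 5 nearest minority neighbours (Euclidean distance on
unscaled features). Oversampling is exactly to parity; base points are
cycled round-robin, with the non-integer remainder (87 → 217 needs 130
synthetics) assigned by a seeded shuffle. Synthetic rows are flagged
`synthetic-SMOTE` in the table's provenance column. A minority class of
one cannot be oversampled (error); k larger than minority−1 is clamped
with a warning.

## Feature selection (RF-RFE)

One random forest per iteration; the feature with the lowest importance
is removed and appended to the back of the rank list, for N iterations on
N features. The default importance is out-of-bag permutation importance:
per tree, accuracy on the tree's out-of-bag samples is compared against
the accuracy after permuting one column, and drops are averaged over
trees (an `impurity` switch uses Gini importances instead; whether the
original "accuracy" criterion meant OOB permutation or retrain deltas is
not recoverable, so the standard Breiman reading is the default).
Importance ties remove the feature with the larger original column index,
making rankings deterministic under a fixed seed. The prefix search then
evaluates the top-k features for every k with the *same* stratified fold
partition (paired comparison, lower variance) and keeps the smallest k
among accuracy ties; by construction the chosen prefix is at least as
accurate as the full set on those folds.

## Classifier and evaluation

Random forest of unpruned trees on bootstrap samples, m_try features per
split. Defaults n_trees = 100, m_try = ⌊√d⌋; a `weka_compat` preset
(10 trees, ⌊log₂ d⌋ + 1) mirrors the historical WEKA defaults the
original protocol relied on. The positive-class score is the literal
fraction of trees voting positive (computed per tree, not averaged leaf
probabilities); label calls threshold the score at 0.5.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/n,
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)); a zero
denominator reports the metric as 0 with a flag in the report. The ROC
curve is the threshold sweep of (1−Sp, Sn) over distinct scores with
trapezoidal AUC, which equals the Mann–Whitney concordance probability
(ties counted half).

Cross-validation uses stratified random folds (stratification protects
the 87:217 imbalance; a non-stratified switch exists); folds = n gives
the jackknife. Held-out predictions are pooled before the confusion table
is formed (canonical); a per-fold AUC mean is reported alongside when
folds are large enough. If a training portion ends up single-class the
partition is re-drawn up to 10 times before erroring.

**Leakage protocol.** By default every data-dependent stage — CSP fit,
SMOTE, feature selection — is refit inside each training fold. Because
published protocols of this kind often fit such stages on the full
dataset first, a `paper_mode` flag reproduces that optimistic variant
(CSP fitted and SMOTE applied once, before splitting). Accuracies from
`paper_mode` are expected to be higher; the default is the honest
protocol.

## Synthetic data

The generator emulates the *shape* of the real benchmark (two unequal
classes, default 87 vs 217; lengths uniform in a configurable range,
default 60–120) with one class-difference dial s:

- **Sequences**: class-conditional first-order Markov chains over the 20
  standard residues. A fixed template (internal seed, independent of the
  dataset seed so s means the same thing everywhere) nudges the base
  chain's log-probabilities in opposite directions per class:
  ±0.5·s·(0.7·residue-usage bias + 0.3·transition perturbation). The
  usage-bias component shifts the stationary distribution, so dipeptide
  features at any gap distance respond to s; at s = 0 the classes are
  identical.
- **Profiles**: score rows drawn as Gaussians with a class-specific
  20×20 column covariance: a common geometric spectrum (6 → 0.3) carried
  by bases rotated apart by angle 0.1·s, with the second class's spectrum
  blended toward its reversal with weight s/(4+s), plus iid noise of
  scale σ (default 1). These coefficients were fixed at design time so
  that cross-validated accuracy rises smoothly across s ∈ [0, 2] rather
  than saturating immediately. Scores are scaled by 2.5, rounded to
  integers in [−10, 10] (ASCII PSSM convention), and every profile passes
  through the ASCII writer/parser round trip on generation.

What this does *not* emulate: homology structure, alignment-depth
dependence of PSSM sharpness, length–composition correlations, or any
biophysical realism. Passing the synthetic suite therefore demonstrates
that the implementation recovers class structure that is genuinely
present in the stated form (covariance or composition differences), not
that the published accuracies on the real 304-protein benchmark are
reproduced — those depend on Swiss-Prot-scale homology searches and are
out of scope here.

## Problem sizes used in the automated runs

The test suite and the acceptance script run the end-to-end sweep at 50
proteins per class, lengths 40–80, 50 trees and 10-fold CV with 10 seeds
per separation level s ∈ {0, 0.5, 1, 2}; the fusion comparison uses the
same sizes at s = 0.5 (a moderate separation where the sequence block
alone is mid-range, leaving headroom for the evolutionary blocks to
add signal); RF-RFE recovery uses 60×10 tables over 50 seeds. These
sizes are the package's chosen defaults for its own verification runs.

## Known limitations

- The default column-variance CSP orientation can be blind to purely row-subspace
  covariance differences (see Orientation above).
- Per-fold RF-RFE inside cross-validation is faithful but expensive at
  460 features; the pipeline defaults to selection off, and the artifact
  rank list is computed once on the full balanced table for inspection.
- OOB permutation importance reconstructs each tree's bootstrap sample
  from its stored random state; this matches scikit-learn's sampling
  scheme and is covered by the test suite, but is tied to that scheme.
- The jackknife path re-trains n forests and is quadratic-ish in n; use
  it only for small benchmarks.
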