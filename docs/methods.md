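# Methods

## Model

kmerForest is a two-stage pipeline. Stage 1 is a binary classifier of
chromatin state from sequence alone: each interval is featurized as a
sparse vector of k-mer counts over the 4^k possible words (base-4
encoding A=0, C=1, G=2, T=3; feature order is therefore lexicographic),
and a bagged ensemble of decision trees is fit to separate accessible
(label 1) from inaccessible (label 0) intervals. Stage 2 converts the
fitted model into per-k-mer importance scores via out-of-bag permutation
(mean decrease accuracy, MDA), and scores a single-nucleotide variant by
the accumulated MDA change over the ≤ k windows the variant alters.

Assumptions worth making explicit:

- **Additive window model.** A variant's effect is the sum of per-window
  importance changes; spatial interactions between k-mers, and between
  nearby variants, are ignored. Indels are out of scope: an
  insertion/deletion shifts every downstream window and the neighbouring
  k-mer accounting no longer holds, so the VCF reader accepts SNVs only.
- **Strand handling.** The feature space is strand-specific by default
  (dimension exactly 4^k). Peaks are strandless, so a
  `rc_collapse` flag is provided that folds each k-mer with its reverse
  complement into one canonical feature (dimension 4^k/2 + 4^(k/2)/2 for
  even k, 4^k/2 for odd k; the representative is the lexicographically
  smaller member). Under collapsing, variant scores are symmetric under
  reverse-complementing the sequence and alleles, which is verified as a
  property test.
- **Windows containing non-ACGT characters are skipped entirely** (no
  partial credit), keeping Σcounts = number of valid windows
  interpretable. In variant scoring, a window whose REF version contains
  an ambiguous base is dropped on both the ref and alt side to avoid
  phantom asymmetric contributions.

## Forest and MDA

Trees are scikit-learn `DecisionTreeClassifier`s (Gini, unbounded depth,
no pruning); the bagging loop, bootstrap/OOB bookkeeping, voting, and
the MDA computation are implemented here. Per tree, a bootstrap multiset
of size N is drawn with replacement (a sample may appear more than
once); the complementary OOB set is recorded. For a size-N bootstrap the
expected OOB fraction is (1−1/N)^N → 1/e ≈ 0.368, which the tests check
against binomial tolerance. Prediction is majority vote; an exact 50/50
tie maps to label 0 (arbitrary but fixed). Features are subsampled at
every split, `floor(sqrt(n))` by default.

MDA follows the classical OOB permutation formulation: for tree *b* with
baseline OOB accuracy acc_b, feature *j*'s values are permuted among the
OOB samples, the tree re-predicts, and MDA_j = (1/B) Σ_b (acc_b −
acc_{b,j}), raw accuracy decrease with no standard-deviation
normalization. Exactness shortcuts: a tree contributes 0 for any feature
it never splits on (permuting an unused feature cannot change its
predictions), so only split features are permuted; features unused by
every tree and features constant across the matrix score exactly 0. A
tree whose OOB set is empty (possible at tiny N) contributes 0, with a
NaN recorded as its baseline. One permutation per (tree, feature) by
default; `n_repeats` averages several for variance reduction.

Determinism contract: all bootstrap indices and tree seeds are drawn
from one generator seeded by the training seed *before* any fitting, and
each permutation RNG is seeded by the tuple (permutation seed, tree
index, feature index). Results are therefore bit-identical regardless of
thread count or execution order; threading (joblib) changes wall time
only. MDA scores may be slightly negative (permutation noise); they are
used as-is by default so the brute-force oracle equivalence is exact,
with an optional clamp at zero in variant scoring.

## Variant score

For an SNV at 0-based position p, the affected windows start at offsets
−(k−1) … 0; each yields a (ref k-mer, alt k-mer) pair differing at
exactly one position. Three aggregates of Δ = MDA(alt) − MDA(ref) are
computed: `score_abs` = Σ|Δ| (default ranking key — disruption
regardless of direction), `score_signed` = ΣΔ (direction of effect), and
`score_mean_abs` = Σ|Δ| / #windows (an average per affected word). The
absolute form is the default because "impact" semantics should not let a
destroyed word cancel against a created one; the signed form is retained
for effect-direction analysis. Which aggregate a given study should use
is a genuine modelling choice, not a mathematical one; all three are in
every output.

## Conservation weighting

The conservation-weighted feature of k-mer *i* is
x_i^{s*} = (1/k) Σ_{j=1}^{x_i^s} Σ_{q=1}^{k} fre_{q,j}, i.e. each
occurrence contributes the mean per-base conservation frequency of the k
positions it covers instead of 1. The implementation computes window
means with a cumulative sum, so the all-ones case reproduces plain
counts exactly (integer arithmetic in float). Uncovered track positions
default to fre = 1.0, deliberately: missing conservation data reduces
the weighted model to the plain one rather than silently down-weighting.
Track values outside [0,1] are clipped with a warning. How fre should be
defined at alignment gaps or ambiguous reference bases is left to the
producer of the track; the reader treats the track as authoritative.

## Synthetic benchmark

The generator emulates the *shape* of an accessibility study at desk
scale, not its biology:

- Background genome: i.i.d. uniform ACGT (configurable composition),
  default 200 kb.
- Positives: 300 non-overlapping intervals of 150–300 bp; each receives
  each motif word (default the single exact word `GATAAG`, a
  pioneer-factor-like binding word) with probability 0.9 at a uniform
  offset. Exact words rather than PWMs keep ground truth crisp.
- Negatives: 300 intervals length-matched by resampling from the
  positive length distribution, rejected on positive overlap and on
  >10% N content. Negatives are also sampled mutually disjoint: on a
  real genome two random draws essentially never coincide, and on a
  small genome overlapping negatives would leak near-duplicate sequences
  across cross-validation folds and bias the null away from AUC 0.5.
  No GC matching (the background is compositionally homogeneous here; a
  flag is the natural extension for real genomes).
- Conservation: fre ~ N(0.95, 0.05²) inside planted motifs, N(0.55,
  0.05²) elsewhere, clipped to [0,1] — a strong but not degenerate
  conservation signal.
- SNV panels: 200 "pathogenic-like" variants uniform over planted motif
  positions, 200 "normal-like" variants at background positions ≥ k from
  any motif occurrence (planted or incidental); ALT uniform over the
  three non-REF bases.
- Chance occurrences of the motif in background are recorded as
  "incidental" in the truth record, not scrubbed — they mirror real-data
  ambiguity.

What passing tests on this generator show: the pipeline recovers a
planted discriminative word, ranks it first among 4096 features, and
separates motif-hitting from background variants. What they do not show:
performance on real DNase-seq peaks, where signal is carried by degenerate
PWMs, GC and repeat structure confound, and accessibility is cell-type
specific. The generator is a correctness instrument, not a biological
claim.

## Problem sizes and numerics

Default study conditions (and the sizes used by `scripts/acceptance.py`
and the end-to-end tests): 200 kb genome, 300+300 intervals, k = 6
(4096 features; k is configurable in [2,10], with 4–10 the practical
range for DNA and >10 entering the dimensionality curse), 100 trees,
5-fold stratified cross-validation, 200+200 SNVs. Production-scale runs
would use the `n_trees=500` default and larger corpora; the statistical
behaviour checked here does not depend on those sizes.

Numerical/tie-break choices: ranking ties broken by ascending feature
index (lexicographic k-mer order); prediction ties to label 0; auPR by
step-wise summation Σ (R_i − R_{i−1})·P_i with no interpolation (linear
PR interpolation overestimates); ROC-AUC by trapezoid over the threshold
sweep, which the tests verify equals the pairwise rank formulation with
ties counted ½ to 1e-12. Cross-validation derives a distinct training
seed per fold from the base seed. The monotone-scaling invariance of
tree ensembles (multiplying all features by c > 0 rescales split
thresholds without changing structure) holds exactly in exact
arithmetic; the test uses a power-of-two constant so floating-point
rounding cannot flip near-tie splits.

## Known limitations

- SNVs only; no indels, no multi-variant interactions.
- One exact-word motif model in the benchmark; no PWM sampling yet.
- The MDA table is cell-type specific in real use (one model per
  DNase-seq experiment); the package trains one model per invocation and
  leaves multi-experiment aggregation to the caller.
- `score_variant` consults only the MDA table, not the forest itself, so
  variants in k-mers the forest never used score 0 even if they would
  perturb predictions jointly with others.
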