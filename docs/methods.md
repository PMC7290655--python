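# Methods

This note records what the package computes, the assumptions behind it,
and the choices made where the design was genuinely open. Empirical
statements here are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Peptide windows and benchmarks

A candidate binding phosphosite is the window PBP(m, n): the central
S/T/Y plus m upstream and n downstream residues (defaults m = n = 10,
window length K = 21), padded with `*` where the window overruns a
terminus. Coordinates are 1-based, following UniProt site conventions.
Non-standard residues (U, B, Z, X, …) also map to `*`, which keeps the
alphabet at exactly 21 symbols — the count the 231-pair encoding depends
on — at the cost of `*` occasionally appearing in a window interior.

Benchmarks pair the annotated positive windows of a hierarchy node with
the remaining S/T/Y windows of the *same* proteins as negatives
(minimizing compositional confounding), de-duplicated at the
peptide-string level with first occurrence kept (determinism), and with
any negative identical to a positive dropped. pS/pT benchmarks mix S and
T centers; pY benchmarks are Y-only. Whether family/cluster negatives
should instead be pooled across the whole group is exposed as a choice to
the caller (`build_benchmark` takes the node), not decided silently.

## Group-based scoring

`S = (1/N) Σ_j (Σ_i M(A_j, P_ij)) · W_j` with M = BLOSUM62 extended by
its conventional `*` row/column (+1 diagonal, −4 off-diagonal); the
matrix is injectable for experimentation. Scoring reduces to the
per-position residue-count profile of the positive set, so cost is
independent of N. A query belonging to the positive set is *not* excluded
when scored; leave-one-out handling belongs to the evaluator, which
removes the held-out item from the training profile.

## Position weight determination

Weights are per-position multipliers of the mean substitution score.
The procedure is staged:

1. **LASSO logistic regression** of the label on the K per-position
   similarity features. The penalty is picked from the grid
   {0.1, 1, 10, 50} as the *strongest* penalty whose cross-validated AUC
   is within 0.005 of the grid best (a one-standard-error-style rule,
   preferring sparse solutions). Zero-variance feature columns (e.g. the
   center position of a single-class node, which is constant) are
   excluded from the penalized fit and reported as weight 0: a constant
   column is an intercept in disguise and would otherwise absorb a
   spurious, never-correctable weight. Coefficients are rescaled so the
   largest magnitude is 1 — the AUC objective is scale-invariant, and
   this keeps the hill climb's literal ±1 steps commensurate with the
   starting point.
2. **Hill climb**: iterations alternate a random ±1 mutation of one
   weight with random zeroing of one weight. The objective is the
   cross-validated AUC of the linear score with folds fixed per run
   (drawn once from the seed), so AUC changes reflect weight changes
   only; below 10 positives the objective switches to leave-one-out and
   flags this in the returned state. The run stops when the best AUC has
   improved by less than 1e-5 over the last 50 iterations, with a hard
   iteration cap (default 5000) guaranteeing termination.

Two numerical safeguards matter in practice. Scores are rounded to 1e-9
before ranking so that float-level near-ties are tied consistently — a
weight move with no real effect (a constant shift of every score) cannot
nudge the AUC through tie-breaking. And an accepted step must improve the
CV AUC by more than `min_improvement` (default 1e-3, configurable down to
0 for the strict rule). The strict "any increase" rule ratchets on
partition-level noise: single-coordinate moves with no generative signal
routinely gain 1e-4–1e-3 of empirical AUC — an order of magnitude below
the ≈0.015 sampling error of the estimate at a thousand items — and the
accumulated noise weights measurably degrade the downstream encoding.
With the threshold, a single fully conserved anchor position is recovered
as the top-|weight| position in essentially every seeded run, and the
full pipeline's cross-validated AUC is stable across fold schemes.

## Pair-similarity encoding

Each unordered symbol pair {a, b} of the alphabetically ordered 21-symbol
alphabet (231 pairs, laid out (A,A), (A,C), …, (\*,\*)) receives

    S_ab = Σ_j D_j · M(a,b) · W_j / Σ_j D_j,

where D_j counts, at position j, the pairings between the query residue
and the positive-set residues realizing {a, b}. The denominator is
pair-specific — the only reading under which S_ab is a weighted average
of M(a,b) over the positions where the pair occurs; pairs never realized
encode as 0 (the natural "no evidence" value). Pairing is query-versus-
positives only, not positive-versus-positive. Note an algebraic
consequence: with all weights equal, every realized pair encodes
c·M(a,b) regardless of the peptide, so the encoding is informative only
through position-weight variation — weight optimization is not a
refinement but a prerequisite of this representation. The implementation
aggregates over the positive-set profile, making encoding O(K·21) per
query; a brute-force pair-enumeration oracle in the tests pins the
semantics.

## Classifier and transfer learning

Seven layers: input (231), five fully connected ReLU hidden layers
(defaults 128/64/32/16/8), and an output layer of two independent sigmoid
units trained against one-hot targets with binary cross-entropy; the
reported score is the positive-class unit (a single-unit variant is
selectable). Training is SGD with momentum and L2 weight decay, mini-batch
shuffled per epoch, fully reproducible from the seed; dropout acts on the
hidden activations during training only.

Numerical choices: inputs are standardized by the training-set mean and
standard deviation, stored on the model so inference sees the same scale
(raw encoded features span roughly ±30 and destabilize plain SGD);
gradients are clipped at global norm 5; probabilities are clamped away
from exact 0/1. Early stopping on a validation slice is available
(`patience > 0`) but off by default: at the benchmark sizes this package
targets (~10² positives), epoch selection on a 10% slice is dominated by
noise and measurably hurts cross-validated accuracy — dropout is the
default anti-overfitting device. Hyperparameter search maximizes mean
10-fold CV AUC, breaking ties toward fewer parameters, then grid order.

Transfer learning initializes a child model from its parent's parameters
and fine-tunes at a 10-fold reduced learning rate; a zero-epoch fine-tune
is exactly the parent. The parent chain (cluster → family → group) is
recorded on the model. Clusters qualify for their own model from 3 known
sites upward.

## Evaluation

Ac, Sn, Sp, PPV, NPV and MCC from the confusion table, with undefined
ratios reported as nulls, never silently zero. ROC points are (1−Sp, Sn);
the AUC equals the Mann–Whitney probability with ties at half credit.
Nodes with ≥ 30 positives use stratified 4/6/8/10-fold cross-validation
(fold assignment seeded and recorded); smaller nodes use leave-one-out.
The full pipeline — weights, encoding, network — is refit inside every
training fold; held-out scores are pooled into a single ROC. All
negatives are kept (no per-fold subsampling).

## Threshold calibration

Cutoffs are empirical background quantiles: the smallest score c with
fraction(background ≥ c) ≤ target, which is conservative and
deterministic under ties; a target of 0 places the cutoff strictly above
the background maximum. Defaults follow the group convention —
high/medium/low at 2/6/10% FPR for pS/pT predictors, 4/9/15% for pY —
estimated on 20 seeded draws of 10,000 windows and averaged. The
background is any user-supplied proteome (tests use the synthetic one);
excluding known positives from the background is optional and off by
default, since the background is a near-negative set by construction.
Thresholds nest: high ⊆ medium ⊆ low ⊆ All.

## DRP association and enrichment

The permutation test fixes the PPBD assignments and re-draws the kinase
family's n_L sites uniformly without replacement from the universe each
round (10,000 rounds by default), recording the overlap x′. Re-drawing
the set is equivalent under this null to permuting a paired vector and is
directly checkable against the exact null, Hypergeometric(T, m_K, n_L).
The empirical p-value is add-one smoothed ((#{x′ ≥ x}+1)/(rounds+1)), so
it is never 0 and is the default; the Gaussian fit to the x′ sample is
optional and warns when |skewness| ≥ 0.5. Grid-wide association uses
Bonferroni control by default; a raw cutoff is available for comparison
with threshold-style analyses. Enrichment is the upper-tail
hypergeometric test on user-supplied term↦id tables with fold enrichment
reported; no annotation sourcing is built in.

## Synthetic data

The generator emulates the structure of curated binding-site benchmarks:
positives sample each constrained offset from its consensus residue set
with adherence probability q (background otherwise; defaults uniform over
the 20 residues so analytic expectations are exact), negatives are pure
background with the same center class, imbalance is set by a
negative:positive ratio (real benchmarks span roughly 4–200), and
de-duplication may leave slightly fewer positives than requested — counts
are reported rather than resampled, keeping draws pure functions of the
seed. Hierarchies refine a group motif by adding constraints per family
and cluster. Proteomes are background-composition sequences with motif
windows planted at recorded interior positions.

What this does *not* emulate: real flanking-sequence correlations,
disorder preference, proteome-level residue frequencies (available as a
preset but not default), homology between sites, or annotation noise.
Passing tests therefore demonstrate correctness and internal consistency
of the algorithms under controlled conditions, not field accuracy on
curated data.

## Study conditions used by the reference experiments

- Family benchmark: 100 positives, 10:1 negatives, 14-3-3-like motif
  (R at −3 and P at +2 at q = 0.9; R at −5 and S at −2 at q = 0.54).
- Weight recovery: one fully conserved anchor (R at −3, q = 1) in a
  PBP(5, 5) window, 300 positives, 10:1; rank uses competition ranking.
- Transfer: group model from 200 positives; per replicate a 10-positive
  cluster benchmark (cluster motif = group motif + extra constraints,
  q = 0.75), encoded with the group predictor, 4-fold CV, fine-tuning
  (40 epochs at reduced rate) against from-scratch training on identical
  folds.
- Calibration: backgrounds of 700 proteins × mean length 500 (~35,000
  candidate S/T windows); 20 draws of 10,000 windows; the fresh-background
  check uses an independently generated proteome.

These sizes were chosen to represent a mid-sized domain family; all are
parameters, not constants.

## Known limitations

- The hill climb optimizes an empirical CV-AUC; on small benchmarks the
  result is seed-dependent even with the acceptance threshold, and
  magnitude rank of weights is only meaningful up to the ±1 step size.
- The pair-average encoding discards pair frequency (only the weighted
  position average survives), which caps its discriminative power
  relative to the raw linear score on some data; the network cannot
  recover information the encoding removed.
- LOO evaluation refits the network per round but, in the default fast
  mode, optimizes position weights once per benchmark; exact per-round
  weight refitting is available through the trainer configuration at
  proportionate cost.
- The permutation null treats kinase site sets as exchangeable across the
  universe; per-site multi-family structure is not preserved.
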