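# Methods

## Problem and model

`hbpkit` is a binary sequence classifier: given a protein's primary sequence
over the 20 standard amino acids, predict whether it is a hormone-binding
protein (positive class) or not. The model has three stages — deterministic
feature encoding, a boosted shallow-tree ensemble, and a metric/protocol
layer — each documented below together with the design choices that were
genuinely open and how they were resolved.

## Curation filters

The benchmark regime assumes curated input: sequences of at least 50
residues, standard alphabet only. `apply_benchmark_filters` removes shorter
sequences (reason `length<50`) and any sequence containing characters
outside `ACDEFGHIKLMNPQRSTVWY` — this covers the ambiguous letters B, J, O,
U, X, Z as well as whitespace and special characters (reason
`nonstandard letter`). Lowercase input is uppercased before validation.
Filtering is idempotent and total: it never raises, and
|survivors| + |rejections| = |input|.

Two curation steps are deliberately *not* reimplemented: homology reduction
(CD-HIT clustering at the 60% identity threshold is an external published
tool; the package documents the threshold and accepts pre-clustered input)
and annotation-based exclusion of "fragment"/"by similarity" entries, which
requires database metadata absent from FASTA. A keyword blacklist on the
FASTA description line is available as an opt-in approximation of the
latter, off by default.

## Encoding

Residues are coded alphabetically, A=1 … Y=20. Any fixed bijection works;
the alphabetical one is reproducible without a lookup file, and the choice
is frozen into the feature version tag stored with every trained model.

**Sequence matrix.** Codes are laid out row-major into an m×m grid,
m = ⌈√n⌉, with the m²−n trailing cells zero — 0 is the padding value,
distinct from every residue code. Positions in the incidence descriptors
are 1-based; matrix indices in the moment engines are 0-based.

**PRIM.** The position-relative incidence matrix is defined here as

    PRIM[a, b] = Σ_{p : Z_p = b} (p − firstpos(a)),   a occurring in X,

with all-zero rows for absent residues; negative contributions (occurrences
of `b` upstream of `a`'s first occurrence) are kept. "Position relative
incidence" admits more than one reading (first-occurrence anchoring vs
all-pairs averaging); this package pins the first-occurrence form, states it
exactly so tests can be exact, and isolates it in one function
(`compute_prim`) so the definition can be swapped without touching anything
else. The implementation uses the closed form
`PRIM[a, b] = AAPIV[b] − FDV[b] · firstpos(a)`; the test suite checks it
against an independent nested-loop enumeration.

**AAPIV / FDV.** AAPIV[a] is the sum of 1-based positions of residue `a`
(so ΣAAPIV = n(n+1)/2 always); FDV holds raw occurrence counts, not
frequencies — tree ensembles are scale-invariant, and counts keep the
conservation law ΣFDV = n exact. Reversed variants (RPRIM, RAAPIV) are the
same operators applied to the reversed sequence.

## Statistical moments

For each 2-D matrix (sequence matrix, PRIM, RPRIM) three families are
computed for all orders p + q ≤ D:

- **Raw**: M(p,q) = Σᵢ Σⱼ iᵖ jᑫ a(i,j), 0-based, 0⁰ = 1.
- **Central**: the same sums about the mass centroid
  μx = M(1,0)/M(0,0), μy = M(0,1)/M(0,0). A zero-mass matrix has no
  centroid: `central_moments` raises a typed error. Inside batch
  featurization the one matrix that can reach zero total mass by
  cancellation — PRIM, whose entries may be negative — gets a zero central
  block plus a logged warning instead, keeping featurization total.
- **Hahn**: projections H′(p,q) = Σᵢ Σⱼ h_p(i) h_q(j) a(i,j) onto discrete
  Hahn polynomials evaluated on the support {0..N−1}, computed by the
  three-term recurrence in the degree, multiplied by the square root of the
  Hahn weight and scaled to unit Euclidean norm. The orthonormal scaling
  prevents the overflow that bare Hahn polynomials suffer for N ≳ 20 and
  makes correctness directly testable: the Gram matrix is the identity to
  ~1e−15 for N up to 128 at D = 3, and the full-order transform (D = N−1,
  full coefficient grid) reconstructs any matrix to round-off.

Open parameters and their resolutions: the moment order budget is D = 3
(10 moments per family — compact, and consistent with how
statistical-moment feature sets of this kind are typically sized); the Hahn
parameters default to α = β = 0 (the symmetric case, where the weight is
uniform and the polynomials reduce to the discrete Chebyshev family), both
exposed in `FeatureConfig`/`hahn_basis`; the 2-D weight function is taken as
the separable product of 1-D Hahn weights. Although the Hahn projection is
printed in continuous-integral form in parts of the literature, inputs here
are finite matrices, so the discrete double sum is the implemented (and
standard) form.

## Feature vector

Block order is fixed and versioned: [seq raw | central | Hahn; PRIM raw |
central | Hahn; RPRIM raw | central | Hahn; AAPIV; RAAPIV; FDV] — 150
values at D = 3. Moments are computed on the three matrix structures only;
the three length-20 vectors enter raw (no 1-D moments): the matrices carry
the positional structure the moments are meant to summarize, and the
vectors are already fixed-length descriptors. The total dimensionality is a
documented default, switchable via D.

The feature version tag (a hash of the names, order and residue coding) is
stored in the table metadata and inside every saved model; a model refuses
tables with a different tag or column set. Names follow
`<block>_<family>_<p>_<q>` and `<block>_<residue>`.

Featurization requires the sequence-matrix side m = ⌈√n⌉ > D; at the
benchmark minimum n = 50, m = 8, so this never binds in the intended
regime (it rejects only toy sequences shorter than (D+1)² = 16 residues).

## Classifier

A discrete adaptive-boosting loop whose weak learners are randomized
depth-limited decision trees (scikit-learn `DecisionTreeClassifier`).
Per round, with sample weights w (initially uniform):

1. draw a bootstrap sample of size n from w (the "selectively sampled"
   training set); fit a tree with `max_depth=2`, entropy splits,
   `min_samples_leaf=min_samples_split=2`, and a random √F-sized feature
   subset considered per split;
2. compute the weighted 0/1 error ε on the full training set; if ε ≥ 0.5
   the learner is discarded and the weights reset to uniform (classic
   safeguard), otherwise its weight is α = ½·ln((1−ε)/ε);
3. multiply the weights of misclassified samples by e^α and the rest by
   e^−α, renormalize.

Prediction aggregates the learners by weighted vote; the reported
probability is the α-weighted fraction of trees voting positive, which is
in [0, 1] by construction. Classification threshold 0.5 with ≥ tie-break
toward the positive class. Defaults are the grid-searched operating point
(125 trees, depth 2, entropy, min samples 2); whether the original ensemble
boosted single randomized trees or whole forests is ambiguous, so the
composition is configurable: `per_tree_randomization=False` with
`n_estimators=1` reduces the model exactly to a single depth-2 tree, and
the randomized-tree default expresses the boosted-forest reading. All
randomness (bootstrap draws, feature subsets, tree seeds) flows from one
integer seed; two runs with the same seed are bit-identical. A degenerate
bootstrap draw containing one class falls back to a weight-fitted tree for
that round.

## Metrics and protocols

Scalar metrics use the standard confusion-matrix formulas (ACC, Pre,
Rec = SN, SP, F1, MCC). Zero-denominator cases return NaN as an explicit
"undefined" marker — never an exception, and never a silent 0, which would
corrupt comparisons. ROC and PR curves place one threshold per distinct
score (ties grouped at one threshold, yielding a step curve), and both
areas use the trapezoidal rule; the ROC is anchored at (0,0) and ends at
(1,1), and the PR curve is anchored at recall 0 with the first threshold's
precision. The trapezoidal AUC equals the tie-corrected normalized
Mann–Whitney statistic exactly, which the tests exploit as an independent
oracle (alongside scikit-learn's `roc_auc_score`).

Cross-validation is stratified K-fold (default K = 5, seeded shuffle),
every sample tested exactly once. Headline CV metrics pool the confusion
counts (and out-of-fold scores, for the curves) across folds; per-fold
reports with mean ± sd are attached as the alternative aggregation, since
pooled and fold-averaged numbers can legitimately differ. Self-consistency
trains and evaluates on the identical dataset (an upper-bound diagnostic,
not a generalization estimate). The independent test refuses any id shared
between training and test tables (leakage guard).

## Synthetic data generator

The generator emulates a balanced two-class benchmark of 50–600-residue
sequences (defaults: 358 per class, mirroring a benchmark split of that
size; lengths uniform on [50, 600]). Negatives draw residues i.i.d. from
the uniform composition; positives from
(1 − e)·uniform + e·(biased profile), where the biased profile puts weight
proportional to 1..20 on the alphabetically ordered residues and e ∈ [0,1]
is the effect size (default 0.5 — a clearly learnable but imperfect
signal). At e = 0 the classes are identical in distribution, giving a null
dataset for calibration; at e = 1 composition alone separates them. An
optional motif planted at 25% (positives) vs 75% (negatives) of the
sequence length creates a purely positional signal, invisible to FDV but
visible to PRIM/AAPIV, so the descriptor blocks can be probed
independently.

What the generator does **not** emulate: real HBP residue statistics,
homology/family structure, length–class correlation, or annotation noise.
Passing the recovery and null tests therefore demonstrates that the
pipeline is implemented correctly and detects compositional/positional
signal at realistic sample sizes — not that it attains any particular
accuracy on curated biological benchmarks.

## Problem sizes and numerical tolerances

The recovery experiment uses 400 sequences per class at e = 1 (pooled CV
accuracy ≥ 0.95 expected); null calibration uses 20 independent datasets of
100 per class at e = 0 with 50-tree ensembles, asserting mean CV accuracy
within 0.5 ± 0.08. Moment-engine agreement with brute-force oracles is
checked at relative error 1e−10 (with an absolute floor scaled to the
matrix's moment magnitude, since first central moments are analytically
zero); Hahn orthonormality at 1e−8; full-order reconstruction at 1e−6.

## Known limitations

- The PRIM definition is one defensible reading of "position-relative
  incidence"; a different anchoring would change feature values (not the
  pipeline).
- Hahn moments of the sequence matrix use a support size m that varies
  with sequence length, so a given (p,q) coefficient is comparable across
  sequences only in the sense of being the same-order projection, not the
  same basis vector.
- The classifier's probability is a vote fraction, not a calibrated
  posterior.
- Feature vectors are not scaled; this is irrelevant for trees but the
  tables are not directly suitable for margin-based learners.
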