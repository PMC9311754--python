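# Methods

This note documents the models and procedures implemented in `ppiforest`,
the choices made where the construction was genuinely open, and what the
synthetic benchmark does and does not establish.

## Problem setting

Interaction prediction is cast as binary classification of ordered protein
pairs.  The only per-protein input is an evolutionary profile: the N×20
position-specific scoring matrix (PSSM) produced by PSI-BLAST, whose entry
(i, j) is the log-odds score of residue type j at sequence position i.
Columns are indexed in the PSI-BLAST ASCII header order
`A R N D C Q E G H I L K M F P S T W Y V` throughout.  Only the log-odds
block of the ASCII file is used; the weighted-percentage block is parsed
for validation and discarded.  Dataset-construction conventions from this
literature (dropping chains under 50 residues) are available as a filter
utility; sequence-identity clustering is out of scope and must be done
upstream.

## Composition descriptor

LPP needs one fixed-length vector per protein.  Each PSSM score x is
squashed to s = 1/(1+e^(−x)), and the squashed matrix S (N×20) is condensed
to C = (1/N)·SᵀS, flattened row-major to 400 values.  This descriptor

- is invariant to row order and to duplicating all rows (it depends on the
  rows only through a normalized sum of outer products), so proteins of
  different lengths are directly comparable;
- keeps cross-column second-order statistics, which carry more profile
  information than the 20 column means alone (a `plain-mean` 20-d variant
  is available for ablation);
- stays bounded in (0, 1), so downstream Euclidean distances are
  well-scaled.

The squashing makes the descriptor most informative when scores lie in the
logistic's responsive range (roughly |x| ≤ 4), which is where PSI-BLAST
log-odds concentrate.

## Locality Preserving Projections

Given descriptors x₁…x_n (rows of X), LPP builds a symmetrized
k-nearest-neighbor graph (i and j are linked iff either is among the
other's k nearest by Euclidean distance; default k = 5), weights links by
the heat kernel Pᵢⱼ = exp(−‖xᵢ−xⱼ‖²/t), and minimizes Σᵢⱼ (yᵢ−yⱼ)²Pᵢⱼ
subject to wᵀX D Xᵀw = 1, i.e. solves

    X L Xᵀ w = λ X D Xᵀ w,   L = D − P,   D = diag(Σⱼ Pᵢⱼ),

keeping the l eigenvectors of smallest eigenvalue (ascending).  Embeddings
of new samples are y = Wᵀ(x − x̄) with the training column means x̄.

Numerical choices:

- **Heat scale** t defaults to the mean squared linked distance ("auto"),
  making the weights scale-free; a fixed t is accepted and satisfies exact
  scale equivariance (X → cX with t → c²t leaves P unchanged).
- **Centering**: columns are mean-centered before the eigenproblem; this
  removes the trivial constant direction and makes the transform of the
  training mean exactly zero.
- **Regularization**: X D Xᵀ is singular whenever n ≤ m (400-d descriptors,
  modest protein counts), so eps·I is added to the right-hand side,
  eps = 1e-6·trace(X D Xᵀ)/m by default.
- **Span restriction**: the regularized full-space pencil also has
  spurious λ = 0 eigenvectors orthogonal to the data span — directions
  with zero embedding variance that would crowd out every informative one
  when n ≤ m.  The solver therefore works in span(Xcᵀ) (via SVD); for
  w in that span every term of the pencil stays in the span, so the
  restricted eigenpairs are exact eigenpairs of the full regularized
  problem, with the spurious ones excluded by construction.  Requested
  dimensions beyond the data rank are zero-padded (degenerate inputs such
  as all-identical rows then yield a constant embedding rather than an
  error).
- **Determinism**: each eigenvector's largest-magnitude entry is made
  positive; neighbor ties are broken by sample index; eigenvalues are
  returned ascending.  Each column is rescaled to wᵀX D Xᵀw = 1 where that
  form is nondegenerate.

LPP is fitted on the collection of per-protein descriptors (one sample per
protein), which is the only reading that yields one fixed vector per
protein for pairing.  The embedding dimension quoted throughout is
per-protein (pair vectors have twice that length); a `dim_means=per_pair`
switch supports the other accounting.

## Rotation Forest

Binary-only, from scratch.  For each of the L trees:

1. the m feature indices are randomly partitioned into K disjoint subsets
   (random permutation cut into contiguous chunks; the first m mod K
   subsets get one extra index);
2. for each subset, ⌈0.75·n⌉ training rows are drawn **with replacement**
   (a without-replacement subsample is available) and full-rank PCA is run
   on those rows restricted to the subset's columns — all components are
   kept, so the block is orthonormal and the assembled m×m matrix F is
   orthogonal (a rotation, not a reduction).  A bootstrap block with
   numerically zero variance falls back to an identity block (logged);
3. an unpruned CART tree (Gini) is fitted on S·F with the full labels.

Prediction averages the trees' class posteriors on their rotated inputs;
the label is the arg-max with exact-0.5 ties resolved to the negative
class (conservative for interaction calls).  The classical variant's
random class-subset selection before PCA is not part of this procedure; a
`classic_class_subsets`-style deviation was considered and rejected to
keep the rotation construction exactly as described above.  Defaults
K = 5, L = 5.  All randomness flows from one seed through spawned child
streams; refitting with the same seed is bit-exact.

## Evaluation

Confusion metrics use the positive class "interacting" (label 1):
accuracy (TP+TN)/total, sensitivity TP/(TP+FN), and MCC
(TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TN+FN)(TP+FP)).  **Precision has two
dialects**: benchmark tables in this literature often print "precision"
computed as TN/(TN+FP) — specificity — so `as_printed` (default for
table-style output) reproduces that convention and `standard` uses
TP/(TP+FP).  Zero denominators yield 0 with an explicit flag.  The ROC is
a threshold sweep over unique posterior values with TPR = TP/(TP+FN) and
FPR = FP/(FP+TN) — the standard false-positive rate; any other denominator
does not produce a ROC — and AUC is the trapezoid area, which equals the
concordance (pair-counting) statistic exactly.

Cross-validation is stratified on the pair label (per-fold class ratios
within one pair of the global ratio) and seeded.  Within each fold the LPP
embedding is fitted on the training fold's proteins only, then all
proteins are embedded and the forest is trained on the training pairs —
no information flows from held-out pairs into the fit.  A
`transductive_lpp` switch fits the embedding on all proteins instead, for
comparison with protocols that do not separate this step.  Proteins may
appear in both training and test pairs (pair-level CV, the protocol of the
benchmark tables this package mirrors); protein-level cold-start splits
are a non-goal.  The independent protocol fits LPP and the forest on one
dataset and scores another, embedding test proteins with the fitted
projection; the two id spaces are resolved against their own collections.

## Synthetic benchmark generator

The generator stands in for benchmark PPI datasets.  Each protein i gets a
latent vector z_i ~ N(0, I_q); its PSSM rows are integer scores
round(tilt + noise) clipped to [−10, 12], where tilt = tilt_scale·(z_i·B)/√q
for a fixed random mixing matrix B (q×20) and noise is N(0, noise_sd²) per
entry.  Sequences take each position's argmax-score residue.  Positive
pairs are drawn without replacement with log-weight
link_gain·separation·(z_i·z_j) (Gumbel top-k); negatives are uniform over
the remaining pairs.  Defaults: 120 proteins, lengths 50–200, q = 1,
tilt_scale = 3, noise_sd = 2, link_gain = 3, 200+200 pairs.

Why these defaults:

- **q = 1**: a single latent similarity axis makes the planted rule
  ("both aligned and strong") geometrically simple, the kind of structure
  the pipeline is designed to recover; it is a recoverability benchmark,
  not a biophysical simulation.
- **tilt_scale = 3** keeps scores mostly inside the logistic's responsive
  range so latent magnitude survives the squashing; **noise_sd = 2** is
  realistic per-position profile noise that averages out over ≥50 rows.
- **link_gain = 3**: with a bounded (e.g. purely logistic) link the weight
  ratio between bulk pairs is O(1) and the planted labels would stay noisy
  at any separation, capping achievable accuracy near 0.7.  The
  exponential tilt with this gain makes separation = 4 an almost
  deterministic rule while separation = 0 is an exact null (uniform
  sampling, labels independent of everything).
- A `cohort` index draws fresh proteins under the *same* mixing matrix B,
  emulating independent datasets from one conserved interaction system —
  the analogue of the cross-species assumption that orthologs keep their
  interactions.

What the generator does *not* emulate: real amino-acid alphabet statistics
and alignment-depth effects, domain architecture, hub proteins and network
topology, homology between train and test sets.  Passing the end-to-end
tests therefore shows the pipeline recovers a planted low-dimensional
similarity signal from profile-shaped inputs at realistic sizes — it says
nothing about accuracy on real interactomes, which depends on external
PSSM generation and curated pair sets.

## Problem sizes used in tests and the acceptance script

Solver checks run on 20 random instances (n ≤ 50, m ≤ 10); rotation checks
on 100 seeded builds; metric checks exhaustively over all 2400 non-empty
confusion tables with cells in 0…6 and 500 seeded score vectors (n ≤ 12);
end-to-end checks on the 120-protein / 400-pair fixture (one seeded run at
separation 4, ten at separation 0); the ensemble comparison on 20 seeds of
10-d two-class Gaussian data (class shift 1.2 sd, 150/150 train/test).
These sizes give stable statistics while keeping a full run in seconds.

## Known limitations

- Binary classification only; the forest internals are two-class.
- LPP is linear; kernel variants and out-of-sample graph updates are out
  of scope.
- The `as_printed` precision dialect is intentionally nonstandard (it is
  specificity); use `standard` for comparisons outside this literature.
- With very small folds an unlucky bootstrap can make a feature subset
  constant; the identity-block fallback keeps the rotation orthogonal but
  that block uninformative.
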