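# ppiforest

Sequence-based prediction of protein–protein interactions (PPIs).  Most
protein pairs have never been assayed experimentally; `ppiforest`
implements a classical machine-learning pipeline that calls interactions
from sequence-derived evolutionary profiles alone:

1. **PSSM input** — each protein is represented by its N×20
   position-specific scoring matrix (PSI-BLAST log-odds profile), parsed
   from the standard `-out_ascii_pssm` dialect.  Running PSI-BLAST itself is
   out of scope; the package consumes its output.
2. **Composition descriptor** — the variable-length PSSM is squashed
   entrywise by the logistic function s = 1/(1+e^(−x)) and condensed to the
   length-normalized 20×20 cross-product matrix C = (1/N)·SᵀS, flattened to
   a fixed 400-dimensional vector per protein.
3. **Locality Preserving Projections (LPP)** — a linear embedding W
   minimizing Σᵢⱼ (yᵢ−yⱼ)² Pᵢⱼ over a symmetrized k-nearest-neighbor graph
   with heat-kernel weights Pᵢⱼ = exp(−‖xᵢ−xⱼ‖²/t), solved as the
   generalized eigenproblem X L Xᵀ w = λ X D Xᵀ w with L = D − P, subject
   to wᵀX D Xᵀw = 1.  The l smallest-eigenvalue eigenvectors give each
   protein a compact embedding y = Wᵀ(x − x̄).
4. **Pair features** — a labeled pair (a, b) becomes the concatenation
   [y_a, y_b] (2l values).
5. **Rotation Forest** — an ensemble of L unpruned CART trees; each tree
   sees the pair features rotated by a block-diagonal orthogonal matrix
   built from full-rank PCA on per-feature-subset bootstrap samples (K
   subsets, 75 % bootstrap).  Class posteriors are averaged over trees.

Evaluation follows the conventions of the PPI benchmark literature:
stratified 5-fold cross-validation with accuracy, precision (in two
dialects — see `docs/methods.md`), sensitivity, Matthews correlation
coefficient and ROC/AUC, a sweep over embedding dimensions, and an
independent train-on-one-dataset / test-on-another protocol.

A synthetic benchmark generator produces PSSMs with a planted,
tunable-strength latent interaction signal, so the entire pipeline is
testable end to end without downloads.

## Worked example

Generate a synthetic dataset with a strong planted signal and
cross-validate the full pipeline:

```sh
$ ppiforest simulate --out demo --seed 1 --separation 4
wrote 120 proteins, 400 pairs to demo

$ ppiforest cv --pssm-dir demo/pssm --pairs demo/pairs.tsv \
      --out demo/cv --dim 20 --seed 1
cv: mean accuracy 0.9750 +/- 0.0153, mean AUC 0.9843 (results in demo/cv)

$ cat demo/cv/cv.tsv
fold    accuracy    precision   sensitivity mcc         auc
1       0.975000    0.975000    0.975000    0.950000    0.995625
2       0.962500    0.975000    0.950000    0.925289    0.957500
3       1.000000    1.000000    1.000000    1.000000    1.000000
4       0.962500    0.925000    1.000000    0.927613    0.985000
5       0.975000    0.975000    0.975000    0.950000    0.983438
mean    0.975000    0.970000    0.980000    0.950580    0.984313
sd      0.015309    0.027386    0.020917    0.030042    0.016539
```

Each row is one held-out fold of the 400 labeled pairs (200 interacting,
200 non-interacting over 120 proteins): the pipeline recovers the planted
latent-similarity rule almost perfectly (97.5 % accuracy, AUC 0.98), with
fold-to-fold spread of about 1.5 points.  With `--separation 0` the same
command sits at chance, as it should.  `ppiforest sweep --dims 10,20,40`
repeats the CV at several embedding dimensions and reports the best
(`best dim 10, accuracy 0.9825` on this fixture); `ppiforest independent`
trains on one dataset and scores another.

The same functionality is available from Python
(`ppiforest.cross_validate`, `ppiforest.fit_lpp`, ...), and the individual
steps are exposed as `featurize` / `fit-lpp` / `transform` / `train` /
`predict` subcommands for scripted pipelines on real PSSM directories.

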