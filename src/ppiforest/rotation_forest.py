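"""Rotation Forest ensemble for binary classification, from scratch.

Each of the L ensemble members rotates the feature space before growing an
unpruned decision tree:

1. randomly partition the m feature indices into K disjoint subsets;
2. for each subset, draw a bootstrap sample of 75% of the training rows
   (with replacement) and run full-rank PCA on those rows restricted to the
   subset's columns;
3. assemble the per-subset principal-axis coefficient matrices into a
   block-diagonal (up to feature permutation) m x m rotation matrix F;
4. train the base tree on the rotated data S F.

Because every PCA block keeps all components, each F is orthogonal: the
rotation diversifies the trees without losing information.  Prediction
averages the trees' class posteriors on their respective rotated inputs and
takes the arg-max (ties at 0.5 go to the negative class).

Binary labels {0, 1} only; the positive class is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


class RotationForestError(ValueError):
    pass


@dataclass
class RFConfig:
    """n_subsets is the K of the rotation construction, n_trees the
    ensemble size L."""

    n_subsets: int = 5
    n_trees: int = 5
    bootstrap_fraction: float = 0.75
    with_replacement: bool = True
    seed: int = 0
    criterion: str = "gini"
    max_depth: int | None = None

    def validate(self, n_features: int) -> None:
        if not 1 <= self.n_subsets <= n_features:
            raise RotationForestError(
                f"n_subsets must be in [1, {n_features}], got {self.n_subsets}"
            )
        if self.n_trees < 1:
            raise RotationForestError("n_trees must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise RotationForestError("bootstrap_fraction must be in (0, 1]")


@dataclass
class RotationMatrix:
    """An m x m orthogonal matrix, block-diagonal over the feature subsets."""

    F: np.ndarray
    subsets: list[np.ndarray]

    @property
    def n_features(self) -> int:
        return self.F.shape[0]


@dataclass
class RotationForestModel:
    members: list[tuple[RotationMatrix, DecisionTreeClassifier]]
    classes: np.ndarray
    config: RFConfig

    @property
    def n_trees(self) -> int:
        return len(self.members)


def partition_features(
    m: int, n_subsets: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Randomly split feature indices 0..m-1 into K disjoint subsets.

    A random permutation is cut into K contiguous chunks; when K does not
    divide m the first (m mod K) subsets receive one extra index.
    """
    if n_subsets > m:
        raise RotationForestError(f"n_subsets={n_subsets} exceeds n_features={m}")
    perm = rng.permutation(m)
    base, extra = divmod(m, n_subsets)
    subsets: list[np.ndarray] = []
    start = 0
    for j in range(n_subsets):
        size = base + (1 if j < extra else 0)
        subsets.append(np.sort(perm[start : start + size]))
        start += size
    return subsets


def _pca_block(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Full-rank PCA axes (columns) of the given rows; identity fallback
    when the bootstrap sample has (numerically) no variance."""
    c = rows.shape[1]
    centered = rows - rows.mean(axis=0)
    cov = centered.T @ centered / max(len(rows) - 1, 1)
    total_var = float(np.trace(cov))
    if total_var <= 1e-12:
        logger.warning("zero-variance feature subset in bootstrap; identity block")
        return np.eye(c)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # descending variance
    axes = evecs[:, order]
    # deterministic sign per axis
    for j in range(c):
        i_max = int(np.argmax(np.abs(axes[:, j])))
        if axes[i_max, j] < 0:
            axes[:, j] = -axes[:, j]
    return axes


def build_rotation_matrix(
    S: np.ndarray,
    y: np.ndarray,
    subsets: Sequence[np.ndarray],
    config: RFConfig,
    rng: np.random.Generator,
) -> RotationMatrix:
    """Build one sparse rotation matrix from per-subset bootstrap PCA.

    For each feature subset, ceil(bootstrap_fraction * n) rows are drawn
    (with replacement by default) and the full set of principal-axis
    coefficients of those rows' subset columns becomes the subset's diagonal
    block, indexed back to the original feature positions.
    """
    S = np.asarray(S, dtype=float)
    n, m = S.shape
    if n < 2:
        raise RotationForestError("need at least 2 training rows")
    n_boot = int(np.ceil(config.bootstrap_fraction * n))
    F = np.zeros((m, m))
    for idx in subsets:
        if config.with_replacement:
            rows = rng.integers(0, n, size=n_boot)
        else:
            rows = rng.permutation(n)[:n_boot]
        block = _pca_block(S[np.ix_(rows, idx)], rng)
        F[np.ix_(idx, idx)] = block
    return RotationMatrix(F=F, subsets=[np.asarray(s) for s in subsets])


def fit(S: np.ndarray, y: np.ndarray, config: RFConfig) -> RotationForestModel:
    """Fit the L-member rotation forest on (S, y), y binary in {0, 1}."""
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=int)
    if S.ndim != 2 or S.shape[0] != y.shape[0]:
        raise RotationForestError("S must be n x m with matching labels")
    n, m = S.shape
    config.validate(m)
    classes = np.unique(y)
    if classes.size < 2:
        raise RotationForestError("training labels contain a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise RotationForestError("labels must be in {0, 1}")

    master = np.random.SeedSequence(int(config.seed))
    members: list[tuple[RotationMatrix, DecisionTreeClassifier]] = []
    for child in master.spawn(config.n_trees):
        rng = np.random.default_rng(child)
        subsets = partition_features(m, config.n_subsets, rng)
        rot = build_rotation_matrix(S, y, subsets, config, rng)
        tree = DecisionTreeClassifier(
            criterion=config.criterion,
            max_depth=config.max_depth,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(S @ rot.F, y)
        members.append((rot, tree))
    return RotationForestModel(members=members, classes=np.array([0, 1]), config=config)


def predict_proba(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Average the member trees' class posteriors on their rotated inputs.

    Returns a q x 2 matrix with columns (class 0, class 1); rows sum to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m = model.members[0][0].n_features
    if X.shape[1] != m:
        raise RotationForestError(
            f"dimension mismatch: model expects {m} features, got {X.shape[1]}"
        )
    acc = np.zeros((X.shape[0], 2))
    for rot, tree in model.members:
        proba = tree.predict_proba(X @ rot.F)
        for col, cls in enumerate(tree.classes_):
            acc[:, int(cls)] += proba[:, col]
    return acc / model.n_trees


def predict(model: RotationForestModel, X: np.ndarray) -> np.ndarray:
    """Arg-max of the averaged posterior; an exact 0.5 tie yields class 0."""
    proba = predict_proba(model, X)
    return (proba[:, 1] > 0.5).astype(int)


def save_model(model: RotationForestModel, path: str) -> None:
    import joblib

    joblib.dump(model, path)


def load_model(path: str) -> RotationForestModel:
    import joblib

    return joblib.load(path)
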