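"""Locality Preserving Projections (LPP) from scratch.

LPP seeks a linear map W minimizing sum_ij (y_i - y_j)^2 P_ij over a
neighborhood graph with heat-kernel weights

    P_ij = exp(-||x_i - x_j||^2 / t)   if i, j are linked, else 0,

which, with the degree matrix D (D_ii = sum_j P_ij) and graph Laplacian
L = D - P, reduces to the generalized eigenproblem

    X L X^T w = lambda X D X^T w,       subject to w^T X D X^T w = 1,

where X holds the (column-mean-centered) samples as columns.  The l
eigenvectors with smallest eigenvalues form the projection; an unseen
sample maps to y = W^T (x - mean).

Construction choices (documented, standard): symmetrized k-nearest-neighbor
link rule under Euclidean distance; heat scale t defaulting to the mean
squared linked distance; small ridge eps * I added to the right-hand matrix
because X D X^T is rank-deficient whenever n <= m; per-column sign fixed so
the largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import scipy.linalg
from scipy.spatial.distance import squareform, pdist


class LPPConfigError(ValueError):
    """Invalid LPP hyperparameters for the given data."""


class LPPNumericalError(RuntimeError):
    """The generalized eigenproblem could not be solved."""


@dataclass
class LPPConfig:
    """Hyperparameters of the LPP fit.

    n_neighbors: k of the symmetrized kNN link rule (must be < n samples).
    heat_scale: kernel scale t > 0, or "auto" = mean squared linked distance.
    out_dim: number of embedding dimensions l (<= input dimension).
    regularization: ridge eps added to X D X^T, or "auto" =
        1e-6 * trace(X D X^T) / m.
    link_rule: "knn" (default) or "eps-ball" with radius ``epsilon_ball``.
    """

    n_neighbors: int = 5
    heat_scale: Union[float, str] = "auto"
    out_dim: int = 40
    regularization: Union[float, str] = "auto"
    link_rule: str = "knn"
    epsilon_ball: float = 1.0
    seed: int = 0


@dataclass
class NeighborhoodGraph:
    """Symmetric heat-kernel weight matrix with degree and Laplacian views."""

    weights: np.ndarray  # P, n x n, symmetric, zero diagonal
    heat_scale: float

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree_matrix - self.weights


@dataclass
class LPPModel:
    """Fitted projection: columns of W are eigenvectors in ascending
    eigenvalue order, each scaled to w^T X D X^T w = 1 (when that quadratic
    form is nondegenerate)."""

    W: np.ndarray  # m x l
    eigenvalues: np.ndarray  # ascending
    means: np.ndarray  # training column means, length m
    config: LPPConfig
    heat_scale: float = 0.0

    @property
    def out_dim(self) -> int:
        return self.W.shape[1]

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        return transform(self, X_new)


def _linked_mask(X: np.ndarray, config: LPPConfig, d2: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    if config.link_rule == "eps-ball":
        mask = d2 <= config.epsilon_ball**2
        np.fill_diagonal(mask, False)
        return mask
    if config.link_rule != "knn":
        raise LPPConfigError(f"unknown link rule {config.link_rule!r}")
    k = config.n_neighbors
    if k < 1 or k >= n:
        raise LPPConfigError(f"n_neighbors must be in [1, n-1]; got k={k}, n={n}")
    # argsort with the index as tie-break keeps neighbor sets deterministic
    d2_off = d2.copy()
    np.fill_diagonal(d2_off, np.inf)  # a point is never its own neighbor
    order = np.argsort(d2_off, axis=1, kind="stable")
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    mask[rows, order[:, :k].ravel()] = True
    return mask | mask.T  # link if i in kNN(j) OR j in kNN(i)


def build_graph(X: np.ndarray, config: LPPConfig) -> NeighborhoodGraph:
    """Build the symmetrized kNN heat-kernel graph over the sample rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise LPPConfigError("need an n x m matrix with n >= 2")
    if not np.all(np.isfinite(X)):
        raise LPPConfigError("non-finite entries in X")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    mask = _linked_mask(X, config, d2)
    if config.heat_scale == "auto":
        linked = d2[mask]
        t = float(linked.mean()) if linked.size and linked.mean() > 0 else 1.0
    else:
        t = float(config.heat_scale)
        if t <= 0:
            raise LPPConfigError(f"heat_scale must be > 0, got {t}")
    P = np.where(mask, np.exp(-d2 / t), 0.0)
    np.fill_diagonal(P, 0.0)
    return NeighborhoodGraph(weights=P, heat_scale=t)


def fit_lpp(X: np.ndarray, config: LPPConfig) -> LPPModel:
    """Fit LPP on the rows of X (n samples x m features).

    Centers X by column means, builds the neighborhood graph, and solves the
    generalized symmetric eigenproblem
    ``(Xc^T L Xc) w = lambda (Xc^T D Xc + eps I) w`` (Xc^T has samples as
    columns).  Returns the ``out_dim`` smallest-eigenvalue eigenvectors.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 2:
        raise LPPConfigError("need at least 2 samples")
    l = config.out_dim
    if l < 1 or l > m:
        raise LPPConfigError(f"out_dim must be in [1, {m}]; got {l}")
    graph = build_graph(X, config)
    means = X.mean(axis=0)
    Xc = X - means  # samples as rows; Xc.T is the samples-as-columns X

    D = graph.degrees
    Lap = graph.laplacian

    # Solve within span(Xc^T).  When n <= m both X L X^T and X D X^T are
    # rank-deficient and the regularized full-space problem acquires
    # spurious lambda = 0 eigenvectors orthogonal to the data (zero
    # embedding variance).  Restricting w to the data span removes exactly
    # those: for w = V u every term of the regularized pencil stays in the
    # span, so restricted eigenpairs are exact eigenpairs of the full
    # problem.
    U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(svals > max(n, m) * np.finfo(float).eps * (svals[0] if svals.size else 0.0)))
    V = Vt[:rank].T  # m x r basis of span(Xc^T)
    T = Xc @ V  # n x r data in span coordinates

    A_r = T.T @ Lap @ T
    B0_r = (T.T * D) @ T
    A_r = 0.5 * (A_r + A_r.T)
    B0_r = 0.5 * (B0_r + B0_r.T)

    if config.regularization == "auto":
        eps = 1e-6 * np.trace(B0_r) / m
        if eps <= 0:
            eps = 1e-12
    else:
        eps = float(config.regularization)
        if eps < 0:
            raise LPPConfigError("regularization must be >= 0")

    n_eig = min(l, rank)
    if n_eig > 0:
        B_r = B0_r + eps * np.eye(rank)
        try:
            evals, evecs = scipy.linalg.eigh(A_r, B_r, subset_by_index=[0, n_eig - 1])
        except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
            raise LPPNumericalError(
                "generalized eigenproblem is singular; set regularization eps > 0"
            ) from exc
        W = V @ np.array(evecs, dtype=float)
    else:  # degenerate data (all rows identical): constant zero embedding
        evals = np.zeros(0)
        W = np.zeros((m, 0))
    if W.shape[1] < l:  # pad so the embedding always has out_dim columns
        W = np.hstack([W, np.zeros((m, l - W.shape[1]))])
        evals = np.r_[evals, np.zeros(l - len(evals))]
    # rescale to the constraint w^T X D X^T w = 1 where nondegenerate
    for j in range(W.shape[1]):
        yj = Xc @ W[:, j]
        q = float(yj @ (D * yj))
        if q > 1e-300:
            W[:, j] /= np.sqrt(q)
    # deterministic sign: largest-magnitude entry positive
    for j in range(W.shape[1]):
        i_max = int(np.argmax(np.abs(W[:, j])))
        if W[i_max, j] < 0:
            W[:, j] = -W[:, j]
    return LPPModel(
        W=W,
        eigenvalues=np.array(evals, dtype=float),
        means=means,
        config=config,
        heat_scale=graph.heat_scale,
    )


def transform(model: LPPModel, X_new: np.ndarray) -> np.ndarray:
    """Project new samples: Y = (X_new - training means) @ W."""
    X_new = np.asarray(X_new, dtype=float)
    one_dim = X_new.ndim == 1
    if one_dim:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.W.shape[0]:
        raise LPPConfigError(
            f"dimension mismatch: model fitted on {model.W.shape[0]} features, "
            f"got {X_new.shape[1]}"
        )
    Y = (X_new - model.means) @ model.W
    return Y[0] if one_dim else Y


def save_model(model: LPPModel, prefix: str) -> None:
    """Persist a fitted model as <prefix>.json (config) + <prefix>.npz (arrays)."""
    import json
    from dataclasses import asdict

    np.savez(
        f"{prefix}.npz", W=model.W, eigenvalues=model.eigenvalues, means=model.means
    )
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {"config": asdict(model.config), "heat_scale": model.heat_scale},
            fh,
            indent=2,
            sort_keys=True,
        )


def load_model(prefix: str) -> LPPModel:
    import json

    arrays = np.load(f"{prefix}.npz")
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    cfg = LPPConfig(**meta["config"])
    return LPPModel(
        W=arrays["W"],
        eigenvalues=arrays["eigenvalues"],
        means=arrays["means"],
        config=cfg,
        heat_scale=meta["heat_scale"],
    )
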