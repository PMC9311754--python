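"""Independent reference implementations used as test oracles.

These deliberately take different computational routes from the package
(naive loops, explicit B^{-1/2} whitening, exhaustive pair counting) so the
comparisons are meaningful.
"""

import numpy as np


def naive_graph(X, k, t=None):
    """Loop-based symmetrized kNN heat-kernel graph."""
    n = len(X)
    d2 = np.array([[np.sum((X[i] - X[j]) ** 2) for j in range(n)] for i in range(n)])
    linked = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = sorted((d2[i, j], j) for j in range(n) if j != i)
        for _, j in order[:k]:
            linked[i, j] = True
            linked[j, i] = True
    if t is None:
        t = d2[linked].mean()
    P = np.zeros((n, n))
    P[linked] = np.exp(-d2[linked] / t)
    return P, t


def dense_lpp_oracle(X, config):
    """Locality-preserving projection via explicit whitening.

    Solves A w = lambda B w by forming B^{-1/2} through a full symmetric
    eigendecomposition and diagonalizing B^{-1/2} A B^{-1/2}; valid for
    full-rank inputs (n > m).  Returns (W, eigenvalues, embedding).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    P, t = naive_graph(
        X,
        config.n_neighbors,
        None if config.heat_scale == "auto" else config.heat_scale,
    )
    D = P.sum(axis=1)
    L = np.diag(D) - P
    Xc = X - X.mean(axis=0)
    A = Xc.T @ L @ Xc
    B0 = Xc.T @ np.diag(D) @ Xc
    eps = (
        1e-6 * np.trace(B0) / m
        if config.regularization == "auto"
        else float(config.regularization)
    )
    B = B0 + eps * np.eye(m)
    evals_b, evecs_b = np.linalg.eigh(B)
    B_inv_half = evecs_b @ np.diag(1.0 / np.sqrt(evals_b)) @ evecs_b.T
    M = B_inv_half @ (0.5 * (A + A.T)) @ B_inv_half
    evals, U = np.linalg.eigh(0.5 * (M + M.T))
    W = B_inv_half @ U[:, : config.out_dim]
    for j in range(W.shape[1]):
        q = W[:, j] @ B0 @ W[:, j]
        if q > 0:
            W[:, j] /= np.sqrt(q)
    return W, np.sort(evals)[: config.out_dim], Xc @ W


def concordance_auc(y, s):
    """Exhaustive pair-counting AUC: (concordant + 0.5 * ties) / (P * N)."""
    pos = [x for t, x in zip(y, s) if t == 1]
    neg = [x for t, x in zip(y, s) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
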