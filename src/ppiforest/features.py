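"""Fixed-length per-protein descriptors and per-pair feature assembly.

A variable-length N x 20 PSSM is bridged to one fixed-length sample by
logistic squashing followed by the length-normalized 20 x 20 cross-product
matrix ("composition"), flattened to 400 values:

    s_ij = 1 / (1 + exp(-score_ij))          (squash to (0, 1))
    C    = (1/N) * S^T S                     (20 x 20)
    x    = vec(C)                            (row-major, 400-d)

C depends on the rows only through a sum of outer products, so it is
invariant to row order and to duplicating all rows.  A 20-d column-mean
alternative ("plain-mean") is available for ablation.

Pair features are the concatenation of the two proteins' embeddings in
pair-list order (a then b); order matters and no symmetrization is applied
unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ppiforest.pssm_io import PSSM, PairList, ValidationError


@dataclass
class CompositionVector:
    """Fixed-length descriptor of one protein derived from its PSSM."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"composition vector for {self.protein_id!r} has non-finite values"
            )


@dataclass
class PairFeature:
    """Concatenated embeddings of an ordered protein pair."""

    id_a: str
    id_b: str
    values: np.ndarray
    label: int | None = None


def pssm_to_composition(pssm: PSSM, mode: str = "cross-product") -> CompositionVector:
    """Convert a PSSM to a fixed-length composition vector.

    ``mode="cross-product"`` (default) gives the 400-d squashed cross-product
    descriptor; ``mode="plain-mean"`` gives the 20-d column mean of the
    squashed matrix.
    """
    S = 1.0 / (1.0 + np.exp(-pssm.scores))
    n = pssm.length
    if mode == "cross-product":
        C = (S.T @ S) / n
        values = C.ravel()  # row-major
    elif mode == "plain-mean":
        values = S.mean(axis=0)
    else:
        raise ValueError(f"unknown composition mode {mode!r}")
    return CompositionVector(protein_id=pssm.protein_id, values=values)


def assemble_design_matrix(
    vectors: Sequence[CompositionVector],
) -> tuple[np.ndarray, dict[str, int]]:
    """Stack composition vectors into an n x d design matrix.

    Row order follows input order; the returned map sends protein id to row
    index.  Duplicate ids are an error.
    """
    if not vectors:
        raise ValidationError("assemble_design_matrix: empty input")
    dim = vectors[0].values.shape[0]
    index: dict[str, int] = {}
    rows = []
    for i, v in enumerate(vectors):
        if v.protein_id in index:
            raise ValidationError(f"duplicate protein id {v.protein_id!r}")
        if v.values.shape[0] != dim:
            raise ValidationError(
                f"inconsistent descriptor length for {v.protein_id!r}: "
                f"{v.values.shape[0]} != {dim}"
            )
        index[v.protein_id] = i
        rows.append(v.values)
    return np.vstack(rows), index


def make_pair_features(
    pairs: PairList,
    embeddings: Mapping[str, np.ndarray],
    symmetrize: bool = False,
) -> list[PairFeature]:
    """Build per-pair feature vectors by concatenating per-protein embeddings.

    Each output vector is ``concat(embed(a), embed(b))`` in pair-list order.
    With ``symmetrize=True`` the reversed pair is appended with the same
    label (training-time augmentation only).
    """
    out: list[PairFeature] = []
    for rec in pairs:
        for pid in (rec.id_a, rec.id_b):
            if pid not in embeddings:
                raise ValidationError(f"no embedding for protein id {pid!r}")
        ea = np.asarray(embeddings[rec.id_a], dtype=float).ravel()
        eb = np.asarray(embeddings[rec.id_b], dtype=float).ravel()
        out.append(
            PairFeature(
                id_a=rec.id_a,
                id_b=rec.id_b,
                values=np.concatenate([ea, eb]),
                label=rec.label,
            )
        )
        if symmetrize:
            out.append(
                PairFeature(
                    id_a=rec.id_b,
                    id_b=rec.id_a,
                    values=np.concatenate([eb, ea]),
                    label=rec.label,
                )
            )
    return out


def pair_feature_matrix(
    features: Sequence[PairFeature],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair features into (X, y); y entries are -1 where unlabeled."""
    if not features:
        return np.zeros((0, 0)), np.zeros(0, dtype=int)
    X = np.vstack([f.values for f in features])
    y = np.array([f.label if f.label is not None else -1 for f in features], dtype=int)
    return X, y
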