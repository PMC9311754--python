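"""Evaluation: confusion metrics, ROC/AUC, stratified k-fold CV, the
embedding-dimension sweep, and the independent (cross-dataset) protocol.

Two precision dialects are reported.  Historical PPI benchmark tables often
print "precision" computed as TN / (TN + FP) — i.e. specificity — so the
``as_printed`` dialect reproduces that convention for comparison tables,
while ``standard`` uses TP / (TP + FP).  Accuracy, sensitivity and MCC are
identical in both dialects, and the ROC always uses the standard false
positive rate FP / (FP + TN) (any other denominator does not yield a ROC).

Cross-validation is stratified on the pair label.  By default the LPP
embedding is fitted on the training fold's proteins only (no test
leakage); a transductive mode fitting LPP on all proteins is available for
comparison with protocols that do not separate this step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ppiforest import rotation_forest as rf
from ppiforest.features import (
    CompositionVector,
    assemble_design_matrix,
    make_pair_features,
    pair_feature_matrix,
    pssm_to_composition,
)
from ppiforest.lpp import LPPConfig, fit_lpp, transform
from ppiforest.pssm_io import PSSM, PairList, ValidationError
from ppiforest.rotation_forest import RFConfig

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "mcc", "auc")


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion-derived metrics plus (optionally) AUC.

    ``zero_division`` lists metrics whose denominator was zero and were
    reported as 0 by convention.
    """

    accuracy: float
    precision: float
    sensitivity: float
    mcc: float
    auc: float | None
    dialect: str
    table: ConfusionTable
    zero_division: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


@dataclass
class ROCCurve:
    """Threshold-sweep ROC: points from (0,0) to (1,1), fpr non-decreasing."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionTable:
    """Count the four confusion cells; positive class is 1."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise EvaluationError(f"length mismatch: {yt.shape} vs {yp.shape}")
    for arr, name in ((yt, "y_true"), (yp, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise EvaluationError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionTable(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(
    ct: ConfusionTable, dialect: str = "as_printed", auc: float | None = None
) -> MetricsReport:
    """Accuracy, precision (per dialect), sensitivity and MCC from counts.

    Zero denominators yield 0 for the affected metric and are flagged.
    """
    if dialect not in ("as_printed", "standard"):
        raise EvaluationError(f"unknown dialect {dialect!r}")
    if ct.total <= 0:
        raise EvaluationError("empty confusion table")
    tp, tn, fp, fn = ct.tp, ct.tn, ct.fp, ct.fn
    flags: list[str] = []

    accuracy = (tp + tn) / ct.total

    if dialect == "as_printed":
        num, den = tn, tn + fp
    else:
        num, den = tp, tp + fp
    if den == 0:
        precision, _ = 0.0, flags.append("precision")
    else:
        precision = num / den

    if tp + fn == 0:
        sensitivity, _ = 0.0, flags.append("sensitivity")
    else:
        sensitivity = tp / (tp + fn)

    denom = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tn + fn) * float(tp + fp)
    )
    if denom == 0:
        mcc, _ = 0.0, flags.append("mcc")
    else:
        mcc = (tp * tn - fp * fn) / denom

    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        mcc=mcc,
        auc=auc,
        dialect=dialect,
        table=ct,
        zero_division=flags,
    )


def roc_and_auc(y_true: Sequence[int], scores: Sequence[float]) -> ROCCurve:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid rule.

    ``scores`` are class-1 posteriors (any monotone score works).  TPR =
    TP/(TP+FN), FPR = FP/(FP+TN).
    """
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise EvaluationError("length mismatch between labels and scores")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes in y_true")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    # cumulative counts after each prediction-positive prefix
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied score block
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# pipeline configuration and end-to-end protocols
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to run PSSM -> composition -> LPP -> pair features
    -> rotation forest.

    ``dim_means`` resolves whether ``lpp.out_dim`` counts per-protein
    embedding dimensions ("per_protein", default; pair vectors have twice
    that length) or the final pair-vector length ("per_pair").
    """

    composition: str = "cross-product"
    lpp: LPPConfig = field(default_factory=lambda: LPPConfig(out_dim=40))
    rf: RFConfig = field(default_factory=RFConfig)
    dialect: str = "as_printed"
    transductive_lpp: bool = False
    dim_means: str = "per_protein"
    symmetrize_pairs: bool = False


@dataclass
class FoldResult:
    metrics: MetricsReport
    roc: ROCCurve
    test_indices: np.ndarray


@dataclass
class CVResult:
    folds: list[FoldResult]
    fold_assignment: np.ndarray  # fold index per pair

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(f.metrics, name) for f in self.folds], dtype=float)

    def mean(self, name: str) -> float:
        return float(self.metric_values(name).mean())

    def std(self, name: str) -> float:
        # sample SD across folds, matching how benchmark tables report +/-
        vals = self.metric_values(name)
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds, start=1):
            rows.append({"fold": str(i), **{m: getattr(f.metrics, m) for m in METRIC_NAMES}})
        rows.append(
            {"fold": "mean", **{m: self.mean(m) for m in METRIC_NAMES}}
        )
        rows.append({"fold": "sd", **{m: self.std(m) for m in METRIC_NAMES}})
        return pd.DataFrame(rows)


def _per_protein_dim(config: PipelineConfig) -> int:
    if config.dim_means == "per_protein":
        return config.lpp.out_dim
    if config.dim_means == "per_pair":
        if config.lpp.out_dim % 2:
            raise EvaluationError("per_pair dimension must be even")
        return config.lpp.out_dim // 2
    raise EvaluationError(f"unknown dim_means {config.dim_means!r}")


def _compositions(
    pssms: Mapping[str, PSSM] | Sequence[PSSM], mode: str
) -> list[CompositionVector]:
    items = pssms.values() if isinstance(pssms, Mapping) else pssms
    return [pssm_to_composition(p, mode=mode) for p in items]


def _fit_and_score(
    comp_vectors: list[CompositionVector],
    train_pairs: PairList,
    test_pairs: PairList,
    config: PipelineConfig,
    seed: int,
) -> tuple[MetricsReport, ROCCurve]:
    """Fit LPP (+rotation forest) on the training pairs' proteins and score
    the test pairs.  Shared by CV folds and the independent protocol."""
    X_all, index = assemble_design_matrix(comp_vectors)
    d = _per_protein_dim(config)

    if config.transductive_lpp:
        fit_ids = list(index)
    else:
        fit_ids = sorted(train_pairs.ids())
    fit_rows = [index[i] for i in fit_ids]
    X_fit = X_all[fit_rows]
    out_dim = min(d, X_all.shape[1])
    lpp_cfg = replace(config.lpp, out_dim=out_dim, seed=seed)
    model = fit_lpp(X_fit, lpp_cfg)
    Y_all = transform(model, X_all)
    embeddings = {pid: Y_all[row] for pid, row in index.items()}

    feats_train = make_pair_features(
        train_pairs, embeddings, symmetrize=config.symmetrize_pairs
    )
    feats_test = make_pair_features(test_pairs, embeddings)
    Xtr, ytr = pair_feature_matrix(feats_train)
    Xte, yte = pair_feature_matrix(feats_test)

    # K cannot exceed the pair-feature count at small embedding dims
    rf_cfg = replace(
        config.rf, seed=seed, n_subsets=min(config.rf.n_subsets, Xtr.shape[1])
    )
    forest = rf.fit(Xtr, ytr, rf_cfg)
    scores = rf.predict_proba(forest, Xte)[:, 1]
    y_pred = (scores > 0.5).astype(int)
    roc = roc_and_auc(yte, scores)
    metrics = compute_metrics(
        confusion_counts(yte, y_pred), dialect=config.dialect, auc=roc.auc
    )
    return metrics, roc


def cross_validate(
    pssms: Mapping[str, PSSM] | Sequence[PSSM],
    pairs: PairList,
    config: PipelineConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold fits LPP on the training fold's proteins (unless
    ``transductive_lpp``), embeds all proteins, trains the rotation forest
    on training pairs and scores the held-out pairs.
    """
    config = config or PipelineConfig()
    comp = _compositions(pssms, config.composition)
    y = pairs.labels()
    counts = np.bincount(y, minlength=2)
    if k_folds < 2 or k_folds > counts.min():
        raise EvaluationError(
            f"k_folds={k_folds} incompatible with class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(pairs), dtype=int)
    folds: list[FoldResult] = []
    for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold_i
        train_pairs = PairList([pairs.records[i] for i in train_idx])
        test_pairs = PairList([pairs.records[i] for i in test_idx])
        metrics, roc = _fit_and_score(
            comp, train_pairs, test_pairs, config, seed=seed * 1000 + fold_i
        )
        folds.append(FoldResult(metrics=metrics, roc=roc, test_indices=test_idx))
    return CVResult(folds=folds, fold_assignment=assignment)


def dimension_sweep(
    pssms: Mapping[str, PSSM] | Sequence[PSSM],
    pairs: PairList,
    dims: Sequence[int],
    config: PipelineConfig | None = None,
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, CVResult]]:
    """Run CV at each embedding dimension; returns a tidy table plus the
    per-dimension CV results."""
    config = config or PipelineConfig()
    rows = []
    results: dict[int, CVResult] = {}
    for d in dims:
        cfg = replace(config, lpp=replace(config.lpp, out_dim=int(d)))
        res = cross_validate(pssms, pairs, cfg, k_folds=k_folds, seed=seed)
        results[int(d)] = res
        row: dict[str, float] = {"dim": int(d)}
        for m in METRIC_NAMES:
            row[m] = res.mean(m)
            row[f"{m}_sd"] = res.std(m)
        rows.append(row)
    return pd.DataFrame(rows), results


def independent_test(
    train_pssms: Mapping[str, PSSM] | Sequence[PSSM],
    train_pairs: PairList,
    test_pssms: Mapping[str, PSSM] | Sequence[PSSM],
    test_pairs: PairList,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Train on one dataset, evaluate on another (cross-species protocol).

    LPP and the forest are fitted on the training data only; test proteins
    are embedded with the fitted projection.  The two id spaces are resolved
    against their own collections and may overlap or be disjoint.
    """
    config = config or PipelineConfig()
    comp_train = _compositions(train_pssms, config.composition)
    comp_test = _compositions(test_pssms, config.composition)

    X_train, idx_train = assemble_design_matrix(comp_train)
    X_test, idx_test = assemble_design_matrix(comp_test)
    d = _per_protein_dim(config)
    out_dim = min(d, X_train.shape[1])
    lpp_cfg = replace(config.lpp, out_dim=out_dim, seed=seed)

    if config.transductive_lpp:
        model = fit_lpp(np.vstack([X_train, X_test]), lpp_cfg)
    else:
        fit_ids = sorted(train_pairs.ids())
        model = fit_lpp(X_train[[idx_train[i] for i in fit_ids]], lpp_cfg)
    emb_train = {pid: v for pid, v in zip(idx_train, transform(model, X_train))}
    emb_test = {pid: v for pid, v in zip(idx_test, transform(model, X_test))}

    feats_train = make_pair_features(
        train_pairs, emb_train, symmetrize=config.symmetrize_pairs
    )
    feats_test = make_pair_features(test_pairs, emb_test)
    Xtr, ytr = pair_feature_matrix(feats_train)
    Xte, yte = pair_feature_matrix(feats_test)
    forest = rf.fit(
        Xtr,
        ytr,
        replace(config.rf, seed=seed,
                n_subsets=min(config.rf.n_subsets, Xtr.shape[1])),
    )
    scores = rf.predict_proba(forest, Xte)[:, 1]
    y_pred = (scores > 0.5).astype(int)
    auc = None
    if 0 < yte.sum() < len(yte):
        auc = roc_and_auc(yte, scores).auc
    return compute_metrics(
        confusion_counts(yte, y_pred), dialect=config.dialect, auc=auc
    )
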