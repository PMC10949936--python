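"""Cross-validated evaluation: confusion metrics, AUC, KL diagnostics.

The harness runs stratified k-fold cross-validation (default 10-fold) of
any of the three classifier modes.  All fitted artifacts — dictionaries,
PCA projections, K-SVD atoms — are built from each fold's training
portion only; held-out samples never influence them.  Accuracy, true
positive rate (sensitivity to malignancy) and true negative rate
(specificity to benignity) are computed from pooled confusion counts, and
AUC from the pooled continuous ensemble scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classify as _cls
from .classify import DEFAULT_EPSILON, DecisionRecord
from .dictionaries import (BlockSpec, KsvdSpec, build_block_dictionaries,
                           build_patch_dictionary, ksvd_learn_per_class)
from .features import (CLASS_BENIGN, CLASS_MALIGNANT, FeatureMatrix,
                       PoolingSpec, average_pool, pca_reduce)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with malignant as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Pooled cross-validation metrics plus the per-fold breakdown.

    acc/tpr/tnr/auc are proportions in [0, 1]; tpr/tnr/auc are None when
    their denominator class is absent.  ``as_percent`` mirrors the usual
    2-decimal percentage presentation.
    """

    counts: ConfusionCounts
    acc: float
    tpr: float | None
    tnr: float | None
    auc: float | None
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)
    records: list[DecisionRecord] = field(default_factory=list)

    def as_percent(self) -> dict[str, float | None]:
        fmt = lambda v: None if v is None else round(100.0 * v, 2)
        return {"ACC": fmt(self.acc), "TPR": fmt(self.tpr),
                "TNR": fmt(self.tnr), "AUC": fmt(self.auc)}


def confusion(predictions, truth) -> ConfusionCounts:
    """Count TP/TN/FP/FN (positive = malignant, class ``m``)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    pos_p = predictions == CLASS_MALIGNANT
    pos_t = truth == CLASS_MALIGNANT
    return ConfusionCounts(
        TP=int(np.sum(pos_p & pos_t)),
        TN=int(np.sum(~pos_p & ~pos_t)),
        FP=int(np.sum(pos_p & ~pos_t)),
        FN=int(np.sum(~pos_p & pos_t)),
    )


def acc(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    return (counts.TP + counts.TN) / counts.total


def tpr(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positives were evaluated."""
    denom = counts.TP + counts.FN
    return None if denom == 0 else counts.TP / denom


def tnr(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when no negatives were evaluated."""
    denom = counts.TN + counts.FP
    return None if denom == 0 else counts.TN / denom


def auc(scores, truth) -> float | None:
    """Area under the ROC curve of the continuous ensemble score.

    Equals the pairwise concordance P(score_pos > score_neg) + 1/2 P(tie).
    Returns None when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    y = (truth == CLASS_MALIGNANT).astype(int)
    if len(np.unique(y)) < 2:
        return None
    return float(roc_auc_score(y, scores))


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One evaluation run's configuration.

    mode             : 'blockboost', 'patchsample' or 'src'
    block_length     : s, for the block modes
    epsilon          : noise margin; relative to ||y||_2 per block by default
    normalize        : unit-normalize dictionary atoms
    pooling_target   : optional average-pooling length applied up front
    pca_components   : optional PCA reduction (conventional SRC)
    ksvd             : optional per-class dictionary learning (LS variants)
    """

    mode: str = "blockboost"
    block_length: int = 64
    epsilon: float = DEFAULT_EPSILON
    relative_epsilon: bool = True
    normalize: bool = True
    pooling_target: int | None = None
    pca_components: int | None = None
    ksvd: KsvdSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("blockboost", "patchsample", "src"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _fit_fold(train: FeatureMatrix, config: PipelineConfig):
    """Build every fitted artifact for one fold from training data only."""
    if config.mode == "src":
        if config.ksvd is not None:
            D, labels = ksvd_learn_per_class(train, config.ksvd)
        else:
            D = train.values.T.copy()
            if config.normalize:
                norms = np.linalg.norm(D, axis=0)
                D = D / np.where(norms == 0, 1.0, norms)
            labels = train.labels.copy()
        return ("src", D, labels)
    spec = BlockSpec(config.block_length)
    if config.ksvd is not None:
        # label-specific learning per block: learn class dictionaries on
        # each block slice, concatenate into per-block dictionaries
        s = config.block_length
        n_blk = spec.n_blocks(train.l)
        blocks, labels = [], None
        for i in range(n_blk):
            sub = FeatureMatrix(train.values[:, i * s:(i + 1) * s],
                                train.labels, train.sample_ids)
            D_i, labels = ksvd_learn_per_class(sub, config.ksvd)
            blocks.append(D_i)
        from .dictionaries import BlockDictionarySet
        dicts = BlockDictionarySet(blocks, labels, normalized=True)
        if config.mode == "patchsample":
            from .dictionaries import PatchDictionary
            mat = np.hstack(blocks)
            plabels = np.concatenate([labels] * n_blk)
            prov = [(f"ksvd{i}", i) for i in range(n_blk)
                    for _ in range(len(labels))]
            return ("patchsample", PatchDictionary(mat, plabels, prov, True))
        return ("blockboost", dicts)
    if config.mode == "blockboost":
        return ("blockboost", build_block_dictionaries(train, spec,
                                                       config.normalize))
    return ("patchsample", build_patch_dictionary(train, spec,
                                                  config.normalize))


def _classify_fold(artifacts, test: FeatureMatrix,
                   config: PipelineConfig) -> list[DecisionRecord]:
    kind = artifacts[0]
    if kind == "src":
        _, D, labels = artifacts
        return _cls.classify_src(test, D, labels, config.epsilon,
                                 config.relative_epsilon)
    if kind == "blockboost":
        return _cls.classify_blockboost(test, artifacts[1], config.epsilon,
                                        config.relative_epsilon)
    return _cls.classify_patchsample(test, artifacts[1], config.epsilon,
                                     config.relative_epsilon)


def cross_validate(
    features: FeatureMatrix,
    config: PipelineConfig,
    folds: int = 10,
    seed: int = 0,
    return_artifacts: bool = False,
) -> MetricsReport:
    """Stratified k-fold cross-validation of one pipeline configuration.

    Per fold, dictionaries (and PCA or K-SVD when configured) are fit on
    the training portion only and the held-out portion is classified.
    Confusion counts are pooled across folds; AUC is computed on the
    pooled ensemble scores (per-fold metrics are also reported).
    """
    labels = features.labels
    counts = {c: int(np.sum(labels == c)) for c in set(labels.tolist())}
    if min(counts.values(), default=0) < folds:
        raise ValueError(f"every class needs at least {folds} samples for "
                         f"{folds}-fold CV; class counts: {counts}")
    if config.pooling_target is not None:
        features = average_pool(features, PoolingSpec(config.pooling_target))
        labels = features.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_strat = (labels == CLASS_MALIGNANT).astype(int)
    all_records: list[DecisionRecord] = []
    fold_rows = []
    artifacts_per_fold = []
    for fold_no, (tr_idx, te_idx) in enumerate(
            skf.split(features.values, y_strat)):
        train, test = features.subset(tr_idx), features.subset(te_idx)
        if config.pca_components is not None:
            train, test = pca_reduce(train, test, config.pca_components)
        artifacts = _fit_fold(train, config)
        if return_artifacts:
            artifacts_per_fold.append(artifacts)
        records = _classify_fold(artifacts, test, config)
        all_records.extend(records)
        cm = confusion([r.predicted for r in records], test.labels)
        fold_rows.append({
            "fold": fold_no, "n": cm.total, "TP": cm.TP, "TN": cm.TN,
            "FP": cm.FP, "FN": cm.FN, "acc": acc(cm), "tpr": tpr(cm),
            "tnr": tnr(cm),
            "auc": auc([r.ells for r in records], test.labels),
        })
    pooled = confusion([r.predicted for r in all_records],
                       [r.true_label for r in all_records])
    report = MetricsReport(
        counts=pooled, acc=acc(pooled), tpr=tpr(pooled), tnr=tnr(pooled),
        auc=auc([r.ells for r in all_records],
                [r.true_label for r in all_records]),
        per_fold=pd.DataFrame(fold_rows), records=all_records,
    )
    if return_artifacts:
        return report, artifacts_per_fold
    return report


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def kl_component_divergence(
    features: FeatureMatrix,
    bins: int = 32,
    smoothing: float = 1e-10,
) -> np.ndarray:
    """Per-component KL divergence between the two class distributions.

    Each component is histogrammed for both classes on shared equal-width
    bin edges spanning the pooled range; ``smoothing`` mass is added to
    every bin before normalization, and ``sum p log(p/q)`` is returned in
    nats (malignant distribution against benign).  Constant components
    yield 0 by convention.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if len(features.classes_present()) < 2:
        raise ValueError("both classes must be present")
    m = features.values[features.labels == CLASS_MALIGNANT]
    n = features.values[features.labels == CLASS_BENIGN]
    out = np.zeros(features.l)
    for t in range(features.l):
        lo = min(m[:, t].min(), n[:, t].min())
        hi = max(m[:, t].max(), n[:, t].max())
        if hi == lo:
            continue
        edges = np.linspace(lo, hi, bins + 1)
        p = np.histogram(m[:, t], bins=edges)[0].astype(float) + smoothing
        q = np.histogram(n[:, t], bins=edges)[0].astype(float) + smoothing
        p /= p.sum()
        q /= q.sum()
        out[t] = float(np.sum(p * np.log(p / q)))
    return out


def kl_from_masses(p, q) -> float:
    """KL divergence of pre-binned probability masses, in nats."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def export_score_histograms(
    records: list[DecisionRecord],
    out: str | Path | None = None,
    bins: int = 20,
) -> pd.DataFrame:
    """Per-class histograms of the ensemble decision scores as a tidy table.

    Columns: true_label, bin_left, bin_right, count.  Written as CSV when
    ``out`` is given.
    """
    if not records:
        warnings.warn("no decision records; writing empty histogram table",
                      RuntimeWarning, stacklevel=2)
        df = pd.DataFrame(columns=["true_label", "bin_left", "bin_right",
                                   "count"])
    else:
        scores = np.asarray([r.ells for r in records])
        labels = np.asarray([r.true_label for r in records])
        edges = np.histogram_bin_edges(scores, bins=bins)
        rows = []
        for cls in sorted(set(labels.tolist())):
            hist = np.histogram(scores[labels == cls], bins=edges)[0]
            for b in range(len(hist)):
                rows.append({"true_label": cls, "bin_left": edges[b],
                             "bin_right": edges[b + 1],
                             "count": int(hist[b])})
        df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, index=False)
    return df
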