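"""Classification metrics and the repeated stratified cross-validation protocol."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from itcep.encoders import build_aapp_table, load_phychem_table
from itcep.io_data import PairRecord
from itcep.model import ModelConfig, build_itcep_model, encode_features, train_model

__all__ = ["MetricsReport", "FoldResult", "CVReport", "compute_metrics", "cross_validate"]


@dataclass(frozen=True)
class MetricsReport:
    """Threshold metrics plus AUC. ``auc`` is NaN when the label vector is
    single-class (undefined ranking problem)."""

    precision: float
    accuracy: float
    recall: float
    f1: float
    mcc: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Standard binary metrics at ``threshold`` and trapezoidal ROC AUC.

    MCC uses the convention of 0 when any denominator factor is 0;
    precision/recall/F1 are 0 when undefined.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary")

    pred = (p > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))

    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / len(y) if len(y) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    auc = float(roc_auc_score(y, p)) if len(np.unique(y)) == 2 else float("nan")
    return MetricsReport(
        precision=precision,
        accuracy=accuracy,
        recall=recall,
        f1=f1,
        mcc=mcc,
        auc=auc,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


@dataclass
class FoldResult:
    repeat: int
    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    aapp_source_indices: np.ndarray
    metrics: MetricsReport


@dataclass
class CVReport:
    """Per-fold, per-repeat results; folds within a repeat partition the data."""

    k: int
    repeats: int
    seeds: list[int]
    folds: list[FoldResult] = field(default_factory=list)

    def mean_auc(self) -> float:
        return float(np.mean([f.metrics.auc for f in self.folds]))

    def mean_accuracy(self) -> float:
        return float(np.mean([f.metrics.accuracy for f in self.folds]))


def cross_validate(
    dataset: Sequence[PairRecord],
    scheme: str = "onehot-aapp",
    config: ModelConfig | None = None,
    k: int = 5,
    repeats: int = 4,
    seeds: Sequence[int] | None = None,
    rebuild_aapp_per_fold: bool = True,
) -> CVReport:
    """Repeated label-stratified k-fold cross-validation.

    For each repeat a fresh shuffled split is made with that repeat's
    seed. The per-epitope positional-preference table (and, for phychem
    schemes, the standardized scales table, which is residue-fixed) is
    rebuilt from each training fold only so no held-out pair contributes
    to the features that score it; ``rebuild_aapp_per_fold=False`` mimics
    a whole-dataset table instead.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset) < k:
        raise ValueError("dataset smaller than k")
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("need exactly one seed per repeat")

    config = config or ModelConfig(scheme=scheme)
    if config.scheme != scheme:
        raise ValueError("config.scheme disagrees with requested scheme")
    labels = np.array([r.label for r in dataset], dtype=int)
    phychem = load_phychem_table() if scheme.startswith("phychem") else None

    report = CVReport(k=k, repeats=repeats, seeds=list(seeds))
    for rep, seed in enumerate(seeds):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(dataset)), labels)):
            train = [dataset[i] for i in train_idx]
            test = [dataset[i] for i in test_idx]
            aapp_source = train_idx if rebuild_aapp_per_fold else np.arange(len(dataset))
            aapp_records = [dataset[i] for i in aapp_source if dataset[i].label == 1]
            aapp = build_aapp_table(aapp_records) if scheme.endswith("aapp") else None
            training_peptides = sorted({r.peptide for r in aapp_records}) if aapp else None

            fold_config = ModelConfig.from_dict(config.to_dict())
            fold_config.seed = config.seed + 1000 * rep + fold
            net = build_itcep_model(fold_config)
            x1, x2 = encode_features(train, scheme, aapp, phychem, training_peptides)
            trained = train_model(net, x1, x2, [r.label for r in train], fold_config)
            tx1, tx2 = encode_features(test, scheme, aapp, phychem, training_peptides)
            probs = trained.predict_proba(tx1, tx2)
            metrics = compute_metrics([r.label for r in test], probs)
            report.folds.append(
                FoldResult(
                    repeat=rep,
                    fold=fold,
                    train_indices=np.array(train_idx),
                    test_indices=np.array(test_idx),
                    aapp_source_indices=np.array(aapp_source),
                    metrics=metrics,
                )
            )
    return report
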