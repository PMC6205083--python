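"""Cross-validation and performance evaluation.

ROC and precision-recall curves use descending-score sweeps with tied
scores grouped (so the trapezoidal AUC equals the Mann-Whitney statistic
with ties counted 1/2).  Cross-validation refits the PSSM and any other
encoders on the training folds only, so validation windows never leak into
the tendency matrix that encodes them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .encoders import WindowFeaturizer
from .io import LabeledDataset, ProteinRecord, dedup_exact_flank, extract_windows, label_windows
from .network import DenseNetworkClassifier

logger = logging.getLogger(__name__)


@dataclass
class RocCurve:
    """A receiver operating characteristic curve with its trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        )


@dataclass
class PrCurve:
    """Precision-recall points and average precision."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    average_precision: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"precision": self.precision, "recall": self.recall})


@dataclass
class StringencyLevel:
    cutoff: float
    specificity: float
    sensitivity: float


@dataclass
class StringencyThresholds:
    """High/medium/low score cutoffs chosen at target specificities."""

    high: StringencyLevel
    medium: StringencyLevel
    low: StringencyLevel

    def __post_init__(self):
        if not (self.high.cutoff >= self.medium.cutoff >= self.low.cutoff):
            raise ValueError("stringency cutoffs must be ordered high >= medium >= low")

    def cutoff_for(self, stringency: str) -> float:
        return getattr(self, stringency).cutoff


@dataclass
class FoldResult:
    fold: int
    roc: RocCurve
    pr: PrCurve
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class CvReport:
    """Per-fold and pooled (concatenated-fold) cross-validation curves."""

    n_folds: int
    seed: int
    folds: list[FoldResult]
    pooled_roc: RocCurve
    pooled_pr: PrCurve

    @property
    def fold_aucs(self) -> list[float]:
        return [f.roc.auc for f in self.folds]

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "fold": f.fold,
                "auc": f.roc.auc,
                "average_precision": f.pr.average_precision,
            }
            for f in self.folds
        ]
        rows.append(
            {
                "fold": "pooled",
                "auc": self.pooled_roc.auc,
                "average_precision": self.pooled_pr.average_precision,
            }
        )
        return pd.DataFrame(rows)


def _check_binary(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    return labels


def roc(scores, labels) -> RocCurve:
    """ROC curve by descending-score sweep; AUC by the trapezoid rule."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(metrics.auc(fpr, tpr)))


def precision_recall(scores, labels) -> PrCurve:
    """Precision-recall curve plus average precision."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    prec, rec, thr = metrics.precision_recall_curve(labels, scores)
    ap = float(metrics.average_precision_score(labels, scores))
    return PrCurve(precision=prec, recall=rec, thresholds=thr, average_precision=ap)


def stratified_folds(labels, n: int, seed: int) -> np.ndarray:
    """Class-stratified fold assignment (0..n-1 per window), deterministic."""
    labels = np.asarray(labels, dtype=int)
    if n < 2:
        raise ValueError("need at least 2 folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n:
        raise ValueError(
            f"smallest class has {counts.min()} members, cannot make {n} folds"
        )
    skf = StratifiedKFold(n_splits=n, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[val_idx] = fold
    return assignment


def select_thresholds(
    curve: RocCurve, target_specificities=(0.95, 0.90, 0.85)
) -> StringencyThresholds:
    """Choose high/medium/low cutoffs: the smallest score cutoff whose
    specificity (1 − FPR) meets each target.

    An unattainable target falls back to the maximal finite cutoff with a
    warning.
    """
    targets = tuple(target_specificities)
    if len(targets) != 3 or not (targets[0] > targets[1] > targets[2]):
        raise ValueError("need three strictly decreasing specificity targets")
    if not all(0.0 < t < 1.0 for t in targets):
        raise ValueError("specificity targets must be in (0, 1)")
    finite = np.isfinite(curve.thresholds)
    thr = curve.thresholds[finite]
    spec = 1.0 - curve.fpr[finite]
    sens = curve.tpr[finite]
    levels = []
    for target in targets:
        ok = spec >= target
        if ok.any():
            # thresholds are descending; the last qualifying one is smallest
            i = np.where(ok)[0][-1]
        else:
            warnings.warn(
                f"specificity {target} unattainable; using maximal-score cutoff"
            )
            i = 0
        levels.append(
            StringencyLevel(
                cutoff=float(thr[i]),
                specificity=float(spec[i]),
                sensitivity=float(sens[i]),
            )
        )
    return StringencyThresholds(high=levels[0], medium=levels[1], low=levels[2])


def cross_validate(
    dataset: LabeledDataset,
    featurizer: WindowFeaturizer,
    classifier: DenseNetworkClassifier | None = None,
    n_folds: int = 4,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CvReport:
    """n-fold stratified cross-validation with per-fold encoder refitting.

    For each fold the featurizer (including the PSSM) is fit on the training
    folds only, both partitions are encoded, a fresh network is trained, and
    the validation fold is scored.
    """
    labels = np.asarray(dataset.labels)
    if fold_assignment is None:
        fold_assignment = stratified_folds(labels, n_folds, seed)
    folds = []
    pooled_scores, pooled_labels = [], []
    proto = classifier if classifier is not None else DenseNetworkClassifier()
    for fold in range(n_folds):
        val_mask = fold_assignment == fold
        train_ds = dataset.subset(np.where(~val_mask)[0])
        val_ds = dataset.subset(np.where(val_mask)[0])
        try:
            feat = clone(featurizer)
            feat.fit(train_ds)
            X_train = feat.transform(train_ds)
            X_val = feat.transform(val_ds)
            clf = clone(proto)
            clf.seed = (int(proto.seed) * 1009 + seed * 31 + fold) % (2**31)
            clf.fit(X_train, train_ds.labels)
            scores = clf.decision_scores(X_val)
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {fold}: {exc}") from exc
        y_val = np.asarray(val_ds.labels)
        folds.append(
            FoldResult(
                fold=fold,
                roc=roc(scores, y_val),
                pr=precision_recall(scores, y_val),
                scores=scores,
                labels=y_val,
            )
        )
        pooled_scores.append(scores)
        pooled_labels.append(y_val)
    pooled_scores = np.concatenate(pooled_scores)
    pooled_labels = np.concatenate(pooled_labels)
    return CvReport(
        n_folds=n_folds,
        seed=seed,
        folds=folds,
        pooled_roc=roc(pooled_scores, pooled_labels),
        pooled_pr=precision_recall(pooled_scores, pooled_labels),
    )


def sweep_window_size(
    records: list[ProteinRecord],
    positives: set[tuple[str, int]],
    modification_type: str,
    L_values,
    featurizer: WindowFeaturizer,
    classifier: DenseNetworkClassifier | None = None,
    n_folds: int = 4,
    seed: int = 0,
    dedup: bool = True,
) -> pd.DataFrame:
    """Re-extract windows at each odd L, cross-validate, tabulate pooled AUC.

    The table is returned for the user to pick L; nothing is auto-selected.
    """
    from .alphabet import MODIFICATION_RESIDUE

    L_values = list(L_values)
    if any(L % 2 == 0 for L in L_values):
        raise ValueError("window lengths must be odd")
    if L_values != sorted(L_values):
        raise ValueError("window lengths must be ascending")
    residue = MODIFICATION_RESIDUE[modification_type]
    rows = []
    for L in L_values:
        windows = []
        for rec in records:
            windows.extend(extract_windows(rec, residue, L))
        ds = label_windows(windows, positives, modification_type)
        if dedup:
            ds = dedup_exact_flank(ds)
        report = cross_validate(ds, featurizer, classifier, n_folds=n_folds, seed=seed)
        rows.append({"L": L, "auc": report.pooled_roc.auc})
    return pd.DataFrame(rows)


def sweep_schemes(
    dataset: LabeledDataset,
    scheme_combinations,
    classifier: DenseNetworkClassifier | None = None,
    n_folds: int = 4,
    seed: int = 0,
    k_values=(0, 1, 2, 3, 4),
    property_table=None,
) -> pd.DataFrame:
    """Cross-validate each scheme combination on identical folds."""
    fold_assignment = stratified_folds(dataset.labels, n_folds, seed)
    rows = []
    for schemes in scheme_combinations:
        feat = WindowFeaturizer(
            schemes=tuple(schemes), k_values=k_values, property_table=property_table
        )
        report = cross_validate(
            dataset,
            feat,
            classifier,
            n_folds=n_folds,
            seed=seed,
            fold_assignment=fold_assignment,
        )
        rows.append({"schemes": "+".join(schemes), "auc": report.pooled_roc.auc})
    return pd.DataFrame(rows)
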