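"""Hold-out and leave-one-subject-out evaluation protocols.

Both protocols split strictly by subject so no window from a test subject can
influence training. Within each fold the full downstream pipeline — feature
z-scoring, MI filtering, SFFS, base classifiers and the fusion stage — is
re-fit on the training subjects only. Metrics are the standard confusion
quantities with class 1 (positive valence) as positive: accuracy, precision,
recall and F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from emofuse.data_model import zscore_apply, zscore_fit
from emofuse.features import FeatureTable
from emofuse.fusion import (
    ClassifierSpec,
    FUSION_VARIANTS,
    default_specs,
    fit_fusion,
    predict_fusion,
)
from emofuse.selection import make_knn_evaluator, mi_filter, sffs

logger = logging.getLogger(__name__)


@dataclass
class FoldResult:
    test_subjects: tuple[str, ...]
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class EvaluationReport:
    protocol: str  # "holdout" | "loso"
    folds: list[FoldResult]
    config: dict = field(default_factory=dict)

    @property
    def macro(self) -> dict[str, float]:
        return {
            name: float(np.mean([getattr(f, name) for f in self.folds]))
            for name in ("accuracy", "precision", "recall", "f1")
        }

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "macro": self.macro,
            "folds": [vars(f) | {"test_subjects": list(f.test_subjects)}
                      for f in self.folds],
            "config": self.config,
        }

    def to_csv(self, path) -> None:
        """Flat per-fold report: one row per test subject / fold."""
        import pandas as pd

        pd.DataFrame([
            {"test_subjects": "|".join(f.test_subjects), "tp": f.tp, "tn": f.tn,
             "fp": f.fp, "fn": f.fn, "accuracy": f.accuracy,
             "precision": f.precision, "recall": f.recall, "f1": f.f1}
            for f in self.folds
        ]).to_csv(path, index=False)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, tn, fp, fn


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with class 1 positive.

    Zero-denominator cases return 0 with a logged warning.
    """
    tp, tn, fp, fn = confusion(y_true, y_pred)
    return metrics_from_confusion(tp, tn, fp, fn)


def metrics_from_confusion(tp: int, tn: int, fp: int, fn: int):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        logger.warning("no positive predictions; precision set to 0")
        precision = 0.0
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        logger.warning("no positive ground truth; recall set to 0")
        recall = 0.0
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return acc, precision, recall, f1


def holdout_split(subject_ids: np.ndarray, n_train_subjects: int = 27,
                  n_test_subjects: int = 5, seed: int = 0):
    """Random disjoint subject split; returns (train_mask, test_mask)."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if n_train_subjects + n_test_subjects > subjects.size:
        raise ValueError(
            f"requested {n_train_subjects}+{n_test_subjects} subjects, "
            f"only {subjects.size} available"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    train_subjects = set(order[:n_train_subjects])
    test_subjects = set(order[n_train_subjects:n_train_subjects + n_test_subjects])
    train_mask = np.isin(subject_ids, list(train_subjects))
    test_mask = np.isin(subject_ids, list(test_subjects))
    return train_mask, test_mask


@dataclass
class PipelineConfig:
    """Everything needed to run selection + fusion inside one fold."""

    mi_fraction: float = 0.5
    target_dim: int = 65
    use_sffs: bool = True
    fusion_variant: str | None = "knn+rf+svm"  # None = no fusion
    final_family: str = "rf"
    selector_knn_k: int = 5
    seed: int = 0
    select_per_fold: bool = True
    naive_insample: bool = False

    def specs(self) -> dict[str, ClassifierSpec]:
        return default_specs(seed=self.seed)


def _select(x: np.ndarray, y: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    result = mi_filter(x, y, cfg.mi_fraction)
    idx = result.retained
    if cfg.use_sffs and cfg.target_dim < idx.size:
        evaluator = make_knn_evaluator(n_neighbors=cfg.selector_knn_k,
                                       seed=cfg.seed)
        sub = sffs(x[:, idx], y, cfg.target_dim, evaluator)
        idx = idx[sub.retained]
    elif cfg.target_dim < idx.size:
        # rank-truncate by MI when the wrapper stage is disabled
        by_score = sorted(idx, key=lambda j: (-result.scores[j], j))
        idx = np.sort(np.asarray(by_score[:cfg.target_dim]))
    return idx


def _fit_predict_fold(x_train, y_train, x_test, cfg: PipelineConfig,
                      selected: np.ndarray | None = None):
    scaler = zscore_fit(x_train)
    xtr = zscore_apply(x_train, scaler)
    xte = zscore_apply(x_test, scaler)
    if selected is None:
        selected = _select(xtr, y_train, cfg)
    specs = cfg.specs()
    final_spec = specs[cfg.final_family]
    if cfg.fusion_variant is None:
        clf = final_spec.build()
        clf.fit(xtr[:, selected], y_train)
        return clf.predict(xte[:, selected]), selected
    bases = tuple(specs[f] for f in FUSION_VARIANTS[cfg.fusion_variant])
    model = fit_fusion(xtr, xtr[:, selected], y_train, bases, final_spec,
                       selected=selected, cv_seed=cfg.seed,
                       naive_insample=cfg.naive_insample)
    labels, _ = predict_fusion(model, xte, xte[:, selected])
    return labels, selected


def _fold_result(test_subjects, y_true, y_pred) -> FoldResult:
    tp, tn, fp, fn = confusion(y_true, y_pred)
    acc, prec, rec, f1 = metrics_from_confusion(tp, tn, fp, fn)
    return FoldResult(tuple(test_subjects), tp, tn, fp, fn, acc, prec, rec, f1)


def run_holdout(table: FeatureTable, cfg: PipelineConfig,
                n_train_subjects: int = 27, n_test_subjects: int = 5,
                seed: int | None = None) -> EvaluationReport:
    """Single subject-disjoint hold-out evaluation of the configured pipeline."""
    split_seed = cfg.seed if seed is None else seed
    train_mask, test_mask = holdout_split(table.subject_ids, n_train_subjects,
                                          n_test_subjects, split_seed)
    y_pred, _ = _fit_predict_fold(table.values[train_mask],
                                  table.labels[train_mask],
                                  table.values[test_mask], cfg)
    fold = _fold_result(np.unique(table.subject_ids[test_mask]),
                        table.labels[test_mask], y_pred)
    return EvaluationReport("holdout", [fold], config=vars(cfg).copy())


def loso_cv(table: FeatureTable, cfg: PipelineConfig,
            exclude_subjects: tuple[str, ...] = ()) -> EvaluationReport:
    """Leave-one-subject-out cross-validation.

    One fold per retained subject; within each fold z-scoring, selection and
    the fusion stage are re-fit on the training subjects only. With
    ``cfg.select_per_fold`` False the feature subset is selected once on the
    whole table (faster, but the selection stage then sees every subject;
    the per-fold classifiers remain subject-disjoint).
    """
    subjects = [s for s in np.unique(table.subject_ids)
                if s not in set(exclude_subjects)]
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    shared_selected = None
    if not cfg.select_per_fold:
        logger.warning("selecting features once on all subjects (fast mode); "
                       "the selection stage is not subject-disjoint")
        scaler = zscore_fit(table.values)
        shared_selected = _select(zscore_apply(table.values, scaler),
                                  table.labels, cfg)
    folds = []
    for subject in subjects:
        test_mask = table.subject_ids == subject
        train_mask = ~test_mask & np.isin(table.subject_ids, subjects)
        y_train = table.labels[train_mask]
        if np.unique(y_train).size < 2 or np.unique(table.labels[test_mask]).size < 1:
            logger.warning("fold %s skipped: single-class training labels", subject)
            continue
        y_pred, _ = _fit_predict_fold(table.values[train_mask], y_train,
                                      table.values[test_mask], cfg,
                                      selected=shared_selected)
        folds.append(_fold_result([subject], table.labels[test_mask], y_pred))
    return EvaluationReport("loso", folds, config=vars(cfg).copy())
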