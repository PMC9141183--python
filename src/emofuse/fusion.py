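"""Multi-classifier probability fusion (stacking with weight features).

Base classifiers (any subset of KNN, SVM, RF) are trained on the selected
feature subset. Their per-class probability outputs are summed elementwise
across bases into two "weight features" (binary task), which are concatenated
with the full original feature matrix; a final classifier is fit on the
standardized concatenation. Training-set probabilities are cross-fitted
(out-of-fold) so the final classifier never sees in-sample base outputs;
a ``naive_insample`` switch reproduces the literal in-sample reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# probability-mode SVMs are intentional (the fusion stage consumes class
# probabilities); silence scikit-learn's deprecation chatter about it
warnings.filterwarnings(
    "ignore",
    message="The `probability` parameter was deprecated",
    category=FutureWarning,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from emofuse.data_model import ZScoreParams, zscore_apply, zscore_fit


class BoundedKNN(KNeighborsClassifier):
    """KNN that clamps k to the training-set size.

    The reference k of 41 assumes thousands of training windows; on small
    (synthetic or per-fold) training sets the neighborhood cannot exceed the
    number of stored samples.
    """

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(X))
        return super().fit(X, y)

#: Fusion variants studied: pairs and the full triple.
FUSION_VARIANTS = {
    "knn+rf": ("knn", "rf"),
    "knn+svm": ("knn", "svm"),
    "rf+svm": ("rf", "svm"),
    "knn+rf+svm": ("knn", "rf", "svm"),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A base- or final-classifier configuration.

    Defaults follow the reference configuration: KNN with k = 41, RBF-kernel
    SVM with C = 0.7 and gamma = 0.015 (probability mode on), and a
    100-tree random forest with a fixed seed.
    """

    family: str  # "knn" | "svm" | "svm-poly" | "rf"
    k: int = 41
    C: float = 0.7
    gamma: float = 0.015
    degree: int = 3
    n_trees: int = 100
    seed: int = 0

    def build(self):
        fam = self.family.lower()
        if fam == "knn":
            return BoundedKNN(n_neighbors=self.k)
        if fam == "svm":
            return SVC(C=self.C, gamma=self.gamma, kernel="rbf",
                       probability=True, random_state=self.seed)
        if fam == "svm-poly":
            return SVC(C=self.C, degree=self.degree, kernel="poly",
                       probability=True, random_state=self.seed)
        if fam == "rf":
            return RandomForestClassifier(n_estimators=self.n_trees,
                                          random_state=self.seed)
        raise ValueError(f"unknown classifier family {self.family!r}")


def default_specs(seed: int = 0) -> dict[str, ClassifierSpec]:
    return {
        "knn": ClassifierSpec("knn", seed=seed),
        "svm": ClassifierSpec("svm", seed=seed),
        "rf": ClassifierSpec("rf", seed=seed),
    }


@dataclass
class FusionModel:
    base_specs: tuple[ClassifierSpec, ...]
    base_models: list
    final_spec: ClassifierSpec
    final_model: object
    scaler: ZScoreParams
    classes: np.ndarray
    selected: np.ndarray | None = None  # column indices of the selected subset


def train_bases(x_select: np.ndarray, y: np.ndarray,
                specs: tuple[ClassifierSpec, ...],
                cv_splits: int = 5, cv_seed: int = 0,
                naive_insample: bool = False):
    """Fit base classifiers and return cross-fitted training probabilities.

    Returns ``(models, probs)`` where ``models`` are refit on all training
    rows (used at prediction time) and ``probs`` is a list of
    (n_samples, n_classes) out-of-fold probability matrices, one per base.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes in y")
    models, probs = [], []
    splits = min(cv_splits, int(np.bincount(y).min()))
    for spec in specs:
        clf = spec.build()
        if not hasattr(clf, "predict_proba"):
            raise TypeError(f"{spec.family} does not emit probabilities")
        if naive_insample:
            clf.fit(x_select, y)
            p = clf.predict_proba(x_select)
        else:
            skf = StratifiedKFold(n_splits=splits, shuffle=True,
                                  random_state=cv_seed)
            p = cross_val_predict(spec.build(), x_select, y, cv=skf,
                                  method="predict_proba")
            clf.fit(x_select, y)
        models.append(clf)
        probs.append(np.asarray(p))
    return models, probs


def weight_features(prob_outputs: list[np.ndarray]) -> np.ndarray:
    """Sum per-class probabilities elementwise across the fused bases.

    The result has n_classes columns regardless of how many bases are fused;
    each row sums to the number of bases.
    """
    if not prob_outputs:
        raise ValueError("no probability outputs")
    shape = prob_outputs[0].shape
    for p in prob_outputs[1:]:
        if p.shape != shape:
            raise ValueError("bases emit probabilities over different class sets")
    return np.sum(prob_outputs, axis=0)


def fit_fusion(x_ori: np.ndarray, x_select: np.ndarray, y: np.ndarray,
               base_specs: tuple[ClassifierSpec, ...],
               final_spec: ClassifierSpec,
               selected: np.ndarray | None = None,
               cv_seed: int = 0, naive_insample: bool = False) -> FusionModel:
    """Train the full fusion stage.

    ``x_ori`` is the complete original feature matrix, ``x_select`` the
    selected subset the bases consume. The final classifier is fit on the
    z-scored concatenation [x_ori || weight features]; standardization is
    re-fit on this training matrix.
    """
    y = np.asarray(y)
    models, probs = train_bases(x_select, y, base_specs, cv_seed=cv_seed,
                                naive_insample=naive_insample)
    weights = weight_features(probs)
    stacked = np.hstack([x_ori, weights])
    scaler = zscore_fit(stacked)
    final = final_spec.build()
    final.fit(zscore_apply(stacked, scaler), y)
    return FusionModel(
        base_specs=tuple(base_specs),
        base_models=models,
        final_spec=final_spec,
        final_model=final,
        scaler=scaler,
        classes=np.unique(y),
        selected=None if selected is None else np.asarray(selected),
    )


def predict_fusion(model: FusionModel, x_ori_new: np.ndarray,
                   x_select_new: np.ndarray):
    """Predict labels and probabilities for new rows.

    Test-time weight features come from the bases refit on all training data.
    """
    if x_ori_new.shape[0] != x_select_new.shape[0]:
        raise ValueError("x_ori_new and x_select_new row counts differ")
    probs = [m.predict_proba(x_select_new) for m in model.base_models]
    weights = weight_features(probs)
    stacked = zscore_apply(np.hstack([x_ori_new, weights]), model.scaler)
    labels = model.final_model.predict(stacked)
    if hasattr(model.final_model, "predict_proba"):
        p = model.final_model.predict_proba(stacked)
    else:
        p = np.eye(model.classes.size)[np.searchsorted(model.classes, labels)]
    return labels, p
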