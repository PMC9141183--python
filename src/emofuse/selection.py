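"""Two-stage feature selection: mutual-information filter, then SFFS.

The filter ranks features by the plug-in mutual information I(X_j; Y) between
a quantile-binned feature and the binary label and keeps a fixed fraction of
the top scorers (fraction 0.5 on a 249-column table keeps 124). The retained
features then go through sequential forward floating selection — a greedy
forward search with conditional backward removals — scored by stratified
cross-validated accuracy of a small KNN classifier, down to a target
dimension (65 in the reference configuration).

Forward-only (SFS), backward-only (SBS), correlation and PCA selectors are
provided as thin alternatives for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier


@dataclass
class MIResult:
    scores: np.ndarray          # per-feature MI in nats
    ranking: np.ndarray         # feature indices, best first (ties: lowest index)
    retained: np.ndarray        # sorted retained index set
    retain_fraction: float


@dataclass
class SFFSResult:
    trajectory: list[tuple[int, str, int, float]]  # (step, action, feature, score)
    best_by_size: dict[int, tuple[float, tuple[int, ...]]]
    retained: np.ndarray        # sorted final index set of size target_dim
    target_dim: int


def discrete_mutual_information(x_codes: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) between two discrete code vectors.

    I(X;Y) = sum_xy p(x,y) ln[p(x,y) / (p(x) p(y))] over the empirical joint.
    """
    x_codes = np.asarray(x_codes)
    y = np.asarray(y)
    xs, xi = np.unique(x_codes, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xs.size, ys.size))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def quantile_bin(x: np.ndarray, bins: int = 10) -> np.ndarray:
    """Code a continuous feature into (at most) ``bins`` quantile bins.

    Invariant to strictly monotone transforms. Features with fewer unique
    values than bins are coded by their unique values directly.
    """
    x = np.asarray(x, dtype=np.float64)
    uniq = np.unique(x)
    if uniq.size <= bins:
        return np.searchsorted(uniq, x)
    edges = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    edges = np.unique(edges)
    return np.searchsorted(edges, x, side="right")


def mutual_information_scores(features: np.ndarray, labels: np.ndarray,
                              bins: int = 10) -> np.ndarray:
    """Per-column plug-in MI with the label after quantile binning (nats)."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.shape[0] < 10:
        raise ValueError("need at least 10 rows for MI estimation")
    if np.unique(labels).size < 2:
        raise ValueError("labels contain a single class")
    return np.array([
        discrete_mutual_information(quantile_bin(features[:, j], bins), labels)
        for j in range(features.shape[1])
    ])


def mi_filter(features: np.ndarray, labels: np.ndarray,
              retain_fraction: float = 0.5, bins: int = 10) -> MIResult:
    """Keep the floor(retain_fraction * n_features) top-MI features."""
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    scores = mutual_information_scores(features, labels, bins)
    n_keep = int(np.floor(retain_fraction * scores.size))
    # stable sort on -score keeps lowest index first among ties
    ranking = np.argsort(-scores, kind="stable")
    retained = np.sort(ranking[:n_keep])
    return MIResult(scores=scores, ranking=ranking, retained=retained,
                    retain_fraction=retain_fraction)


# ---------------------------------------------------------------------------
# Wrapper searches
# ---------------------------------------------------------------------------

def make_knn_evaluator(n_neighbors: int = 5, n_splits: int = 5, seed: int = 0):
    """Stratified K-fold CV accuracy of a KNN classifier, as a subset scorer.

    The fold assignment is frozen at construction so every subset is scored
    on identical folds (deterministic given the seed).
    """
    def evaluator(features: np.ndarray, labels: np.ndarray,
                  subset: tuple[int, ...]) -> float:
        x = features[:, list(subset)]
        splits = min(n_splits, int(np.bincount(labels).min()))
        if splits < 2:
            raise ValueError("too few samples per class for CV")
        skf = StratifiedKFold(n_splits=splits, shuffle=True, random_state=seed)
        correct = 0
        for tr, te in skf.split(x, labels):
            clf = KNeighborsClassifier(n_neighbors=min(n_neighbors, len(tr)))
            clf.fit(x[tr], labels[tr])
            correct += int((clf.predict(x[te]) == labels[te]).sum())
        return correct / len(labels)

    return evaluator


def _best_candidate(scores: list[tuple[float, int]]) -> tuple[float, int]:
    # max score, ties broken by lowest feature index
    return max(scores, key=lambda t: (t[0], -t[1]))


def sffs(features: np.ndarray, labels: np.ndarray, target_dim: int,
         evaluator=None, max_cycles: int = 200) -> SFFSResult:
    """Sequential forward floating selection down to ``target_dim`` features.

    Classic floating search: repeatedly add the single feature that maximizes
    the evaluator score, then remove any feature whose removal strictly
    improves the best-known score at the smaller size; stop once the best
    subset of size ``target_dim`` survives a full forward-backward cycle
    unchanged.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n_features = features.shape[1]
    if not 1 <= target_dim <= n_features:
        raise ValueError(f"target_dim must be in [1, {n_features}]")
    if evaluator is None:
        evaluator = make_knn_evaluator()
    if target_dim == n_features:
        full = tuple(range(n_features))
        score = evaluator(features, labels, full)
        return SFFSResult(trajectory=[(0, "add", -1, score)],
                          best_by_size={n_features: (score, full)},
                          retained=np.arange(n_features), target_dim=target_dim)

    current: list[int] = []
    best_by_size: dict[int, tuple[float, tuple[int, ...]]] = {}
    trajectory: list[tuple[int, str, int, float]] = []
    step = 0

    def record_best(subset: list[int], score: float) -> None:
        key = tuple(sorted(subset))
        k = len(key)
        if k not in best_by_size or score > best_by_size[k][0]:
            best_by_size[k] = (score, key)

    for _ in range(max_cycles):
        target_before = best_by_size.get(target_dim)
        # forward step
        if len(current) < target_dim:
            cands = [
                (evaluator(features, labels, tuple(current + [j])), j)
                for j in range(n_features) if j not in current
            ]
            score, j = _best_candidate(cands)
            current.append(j)
            step += 1
            trajectory.append((step, "add", j, score))
            record_best(current, score)
        # conditional backward steps
        while len(current) > 2:
            cands = [
                (evaluator(features, labels,
                           tuple(f for f in current if f != j)), j)
                for j in current
            ]
            score, j = _best_candidate(cands)
            smaller = len(current) - 1
            if smaller in best_by_size and score <= best_by_size[smaller][0]:
                break
            current = [f for f in current if f != j]
            step += 1
            trajectory.append((step, "remove", j, score))
            record_best(current, score)
        if len(current) >= target_dim and best_by_size.get(target_dim) == target_before:
            break

    score, subset = best_by_size[target_dim]
    return SFFSResult(trajectory=trajectory, best_by_size=best_by_size,
                      retained=np.asarray(sorted(subset)), target_dim=target_dim)


def sfs(features: np.ndarray, labels: np.ndarray, target_dim: int,
        evaluator=None) -> np.ndarray:
    """Forward-only sequential selection (no backward removals)."""
    features = np.asarray(features, dtype=np.float64)
    if evaluator is None:
        evaluator = make_knn_evaluator()
    current: list[int] = []
    while len(current) < target_dim:
        cands = [
            (evaluator(features, labels, tuple(current + [j])), j)
            for j in range(features.shape[1]) if j not in current
        ]
        _, j = _best_candidate(cands)
        current.append(j)
    return np.asarray(sorted(current))


def sbs(features: np.ndarray, labels: np.ndarray, target_dim: int,
        evaluator=None) -> np.ndarray:
    """Backward-only sequential elimination down to ``target_dim``."""
    features = np.asarray(features, dtype=np.float64)
    if evaluator is None:
        evaluator = make_knn_evaluator()
    current = list(range(features.shape[1]))
    while len(current) > target_dim:
        cands = [
            (evaluator(features, labels, tuple(f for f in current if f != j)), j)
            for j in current
        ]
        _, j = _best_candidate(cands)
        current.remove(j)
    return np.asarray(sorted(current))


def correlation_filter(features: np.ndarray, labels: np.ndarray,
                       threshold: float = 0.93,
                       mode: str = "target") -> np.ndarray:
    """Correlation-based filter.

    ``mode="target"`` retains features whose |Pearson correlation with the
    label| is at least ``threshold``; ``mode="pairwise"`` greedily drops the
    later member of any feature pair correlated above the threshold.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if mode == "target":
        std = features.std(axis=0)
        centered = features - features.mean(axis=0)
        ly = labels - labels.mean()
        denom = np.where(std > 0, std, 1.0) * max(ly.std(), 1e-12) * len(labels)
        corr = np.abs(centered.T @ ly) / denom
        corr[std == 0] = 0.0
        return np.flatnonzero(corr >= threshold)
    if mode == "pairwise":
        corr = np.corrcoef(features, rowvar=False)
        keep: list[int] = []
        for j in range(features.shape[1]):
            if all(abs(corr[j, k]) < threshold for k in keep):
                keep.append(j)
        return np.asarray(keep)
    raise ValueError(f"unknown mode {mode!r}")


def pca_transform(features: np.ndarray, n_components: int):
    """Variance-ranked PCA to ``n_components``; returns (transformed, model)."""
    model = PCA(n_components=n_components, svd_solver="full")
    return model.fit_transform(np.asarray(features, dtype=np.float64)), model


def alt_selectors(features: np.ndarray, labels: np.ndarray, method: str,
                  **params):
    """Dispatch to the comparison selectors: SFS, SBS, correlation or PCA."""
    method = method.lower()
    if method == "sfs":
        return sfs(features, labels, **params)
    if method == "sbs":
        return sbs(features, labels, **params)
    if method == "correlation":
        return correlation_filter(features, labels, **params)
    if method == "pca":
        return pca_transform(features, **params)
    raise ValueError(f"unknown selection method {method!r}")
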