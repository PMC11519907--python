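"""KNN classification of impedance events and recovery-rate evaluation.

Training libraries hold an equal number of feature vectors per class
(n = 3000 by default).  Classification is k-nearest-neighbour (k = 11 by
default) under a standardized Euclidean metric: each feature axis is
divided by its standard deviation over the pooled library, so diameter
(um) and phase (rad) contribute comparably.  Votes are unweighted; a
majority-vote tie goes to the class of the single nearest neighbour among
the tied classes.

Concentrations follow from counts divided by the analysed volume
(flow rate x duration), and the recovery rate of a class is the
percentage ratio of its classified concentration to its known (true)
concentration — 100% is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "TrainingLibrary",
    "KNNModel",
    "build_library",
    "select_k",
    "classify",
    "pool_binary",
    "estimate_concentration",
    "recovery_report",
]


@dataclass(frozen=True)
class TrainingLibrary:
    """Per-class feature sets plus pooled feature scales.

    Libraries built from monocultures have a uniform per-class size
    (n = 3000); pooling for binary classification concatenates member
    classes, so a pooled library may be unbalanced.
    """

    classes: dict[str, np.ndarray]  # label -> (n, n_features)
    feature_stds: np.ndarray  # (n_features,)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("library has no classes")
        if np.any(np.asarray(self.feature_stds) <= 0):
            raise ValueError("feature standard deviations must be positive")

    @property
    def n_total(self) -> int:
        return sum(len(x) for x in self.classes.values())

    @property
    def n_per_class(self) -> int:
        sizes = {len(x) for x in self.classes.values()}
        if len(sizes) > 1:
            raise ValueError("library is unbalanced; per-class size is undefined")
        return sizes.pop()

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All features stacked with their labels, class order preserved."""
        X = np.vstack(list(self.classes.values()))
        y = np.concatenate([[label] * len(x) for label, x in self.classes.items()])
        return X, y


@dataclass(frozen=True)
class KNNModel:
    k: int
    library: TrainingLibrary

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.library.n_total:
            raise ValueError(f"k must lie in [1, {self.library.n_total}], got {self.k}")


def _pooled_stds(class_features: dict[str, np.ndarray]) -> np.ndarray:
    pooled = np.vstack(list(class_features.values()))
    stds = pooled.std(axis=0, ddof=1)
    if np.any(stds <= 0):
        raise ValueError("a feature has zero variance over the pooled library")
    return stds


def build_library(
    per_class: dict[str, np.ndarray],
    n: int = 3000,
    seed: int = 0,
) -> TrainingLibrary:
    """Subsample every class to exactly ``n`` feature vectors (seeded).

    Sampling is without replacement; a class with fewer than ``n``
    features is an error naming the class.  Feature standard deviations
    are computed over the pooled (subsampled) library.
    """
    rng = np.random.default_rng(seed)
    classes: dict[str, np.ndarray] = {}
    for label, feats in per_class.items():
        feats = np.asarray(feats, dtype=float)
        if len(feats) < n:
            raise ValueError(f"class {label!r} has only {len(feats)} features; {n} required")
        if len(feats) == n:
            classes[label] = feats.copy()
        else:
            idx = np.sort(rng.choice(len(feats), size=n, replace=False))
            classes[label] = feats[idx]
    return TrainingLibrary(classes, _pooled_stds(classes))


def classify(model: KNNModel, queries: np.ndarray) -> np.ndarray:
    """Label each query by majority vote over its k nearest neighbours.

    Distances are standardized Euclidean (each axis scaled by the pooled
    library std); the neighbour search is exhaustive over the whole
    library.  Ties between classes with equal votes resolve to the class
    of the nearest neighbour belonging to a tied class.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[0] == 0:
        return np.array([], dtype=object)
    X, y = model.library.stacked()
    stds = model.library.feature_stds
    labels, y_codes = np.unique(y, return_inverse=True)
    nn = NearestNeighbors(n_neighbors=model.k, algorithm="brute")
    nn.fit(X / stds)
    _, nbr_idx = nn.kneighbors(queries / stds)  # (nq, k), sorted by distance

    nbr_codes = y_codes[nbr_idx]
    counts = np.zeros((len(queries), len(labels)), dtype=int)
    for c in range(len(labels)):
        counts[:, c] = (nbr_codes == c).sum(axis=1)
    top = counts.max(axis=1)
    out = np.empty(len(queries), dtype=object)
    for i in range(len(queries)):
        tied = np.flatnonzero(counts[i] == top[i])
        if len(tied) == 1:
            out[i] = labels[tied[0]]
        else:
            # nearest neighbour among the tied classes decides
            for code in nbr_codes[i]:
                if code in tied:
                    out[i] = labels[code]
                    break
    return out


def select_k(
    library: TrainingLibrary,
    candidates: list[int],
    folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick k by minimum stratified cross-validated misclassification loss.

    Ties between candidates resolve to the smallest k.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > min(len(x) for x in library.classes.values()):
        raise ValueError("more folds than samples in the smallest class")
    X, y = library.stacked()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = {k: 0 for k in candidates}
    total = len(y)
    for train_idx, test_idx in skf.split(X, y):
        sub: dict[str, np.ndarray] = {}
        y_train = y[train_idx]
        for label in library.classes:
            sub[label] = X[train_idx][y_train == label]
        fold_lib = TrainingLibrary(sub, _pooled_stds(sub))
        for k in candidates:
            pred = classify(KNNModel(k, fold_lib), X[test_idx])
            losses[k] += int(np.sum(pred != y[test_idx]))
    best = min(candidates, key=lambda k: (losses[k] / total, k))
    return best


def pool_binary(
    library: TrainingLibrary,
    grouping: dict[str, str],
) -> TrainingLibrary:
    """Merge classes into groups (e.g. microplastic vs biological).

    Every library class must be mapped; pooled groups concatenate their
    member classes and feature stds are recomputed over the pooled data.
    """
    unmapped = set(library.classes) - set(grouping)
    if unmapped:
        raise ValueError(f"grouping does not cover class(es): {sorted(unmapped)}")
    groups: dict[str, list[np.ndarray]] = {}
    for label, feats in library.classes.items():
        groups.setdefault(grouping[label], []).append(feats)
    pooled = {g: np.vstack(members) for g, members in groups.items()}
    return TrainingLibrary(pooled, _pooled_stds(pooled))


def estimate_concentration(
    counts: dict[str, int],
    flow_rate: float,
    duration: float,
) -> dict[str, float]:
    """Counts -> particles/uL given flow rate (uL/min) and duration (s)."""
    if flow_rate <= 0 or duration <= 0:
        raise ValueError("flow rate and duration must be positive")
    volume_ul = flow_rate * duration / 60.0
    return {label: n / volume_ul for label, n in counts.items()}


def recovery_report(
    estimated: dict[str, float],
    truth: dict[str, float],
) -> dict[str, float]:
    """Per-class recovery rate, percent: 100 * estimated / true concentration.

    Classes with zero (or missing) true concentration are skipped with a
    warning rather than reported as infinite.
    """
    import warnings

    report: dict[str, float] = {}
    for label, est in estimated.items():
        t = truth.get(label, 0.0)
        if t <= 0:
            warnings.warn(f"class {label!r} has zero true concentration; skipped")
            continue
        report[label] = 100.0 * est / t
    return report
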