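"""Random-forest classification with explicit bootstrap and vote access.

The ensemble is built tree by tree: each tree is grown fully (to
``min_leaf``) on a bootstrap of the training subjects drawn with
replacement at the original sample size, considering ``mtry`` randomly
drawn candidate features per split.  Keeping the bootstrap multisets
in-package makes the out-of-bag bookkeeping, per-tree vote counting and
deterministic tie-breaking part of the model contract; single-tree
induction is delegated to scikit-learn's ``DecisionTreeClassifier``.

Because the surrounding pipeline clusters voxels *before* training, the
OOB accuracy here is a diagnostic only, never a generalization estimate or
model-selection signal — held-out information leaks into the parcelation,
so honest evaluation must come from cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .parcellate import FeatureMatrix

__all__ = [
    "ForestParams",
    "ForestModel",
    "OOBResult",
    "purity",
    "bootstrap_indices",
    "expected_absent_fraction",
    "train_forest",
    "predict_votes",
    "predict_labels",
    "oob_accuracy",
    "feature_importances",
    "save_forest",
    "load_forest",
]


def purity(criterion: str, class_proportions: Sequence[float]) -> float:
    """Node impurity: Gini index or cross-entropy (natural log).

    Gini: ``sum_k p_k (1 - p_k)``; entropy: ``-sum_k p_k ln p_k`` with
    ``0 ln 0 = 0``.  Proportions must be a probability vector.
    """
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative class proportion")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    if criterion == "gini":
        return float(np.sum(p * (1.0 - p)))
    if criterion == "entropy":
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))
    raise ValueError(f"criterion must be 'gini' or 'entropy', got {criterion!r}")


def expected_absent_fraction(n: int) -> float:
    """Closed-form probability (1 - 1/N)^N that a sample misses a bootstrap."""
    return (1.0 - 1.0 / n) ** n


def bootstrap_indices(
    n_samples: int, n_draws: int, seed: int
) -> np.ndarray:
    """The forest's bootstrap generator: ``n_draws`` resamples of size N.

    Sampling is uniform with replacement at the original sample size, one
    row per tree; this exact routine is used by :func:`train_forest`.
    """
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_samples, size=(n_draws, n_samples))


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` is the number of candidate features drawn at each split
    (default ``floor(sqrt(p))``); ``min_leaf`` the minimum leaf size (trees
    are otherwise grown to purity, no depth cap or pruning).
    """

    n_trees: int = 500
    criterion: str = "gini"
    mtry: int | None = None
    seed: int = 0
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.criterion not in ("gini", "entropy"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is None:
            return max(1, int(np.sqrt(n_features)))
        if self.mtry > n_features:
            raise ValueError(
                f"mtry={self.mtry} exceeds feature count {n_features}"
            )
        return self.mtry


@dataclass(frozen=True, eq=False)
class ForestModel:
    """Trained ensemble with per-tree prediction and bootstrap access."""

    params: ForestParams
    classes: tuple[str, ...]
    trees: tuple[DecisionTreeClassifier, ...]
    in_bag: np.ndarray  # (n_trees, n_train) bootstrap index rows
    feature_names: tuple[str, ...] | None
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def in_bag_mask(self) -> np.ndarray:
        """(n_trees, n_train) boolean: subject present in the tree's bag."""
        n_train = self.in_bag.shape[1]
        mask = np.zeros((self.n_trees, n_train), dtype=bool)
        rows = np.repeat(np.arange(self.n_trees), n_train)
        mask[rows, self.in_bag.ravel()] = True
        return mask

    def absent_fraction(self) -> float:
        """Mean fraction of training subjects absent per bootstrap."""
        return float(1.0 - self.in_bag_mask().mean())

    def tree_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_samples) predicted class indices."""
        return np.stack([t.predict(X).astype(np.intp) for t in self.trees])


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.data
    return np.asarray(features, dtype=float)


def _check_alignment(
    model: ForestModel, features: FeatureMatrix | np.ndarray
) -> np.ndarray:
    X = _as_array(features)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature columns ({X.shape[1] if X.ndim == 2 else '?'}) do not "
            f"align with training columns ({model.n_features})"
        )
    if (
        isinstance(features, FeatureMatrix)
        and model.feature_names is not None
        and features.feature_names != model.feature_names
    ):
        raise ValueError("feature names do not match the training columns")
    return X


def train_forest(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
    params: ForestParams,
    classes: Sequence[str] | None = None,
) -> ForestModel:
    """Train a seeded random forest on a subjects x features matrix.

    ``classes`` fixes the label order used for vote columns and argmax
    tie-breaking (default: sorted unique labels).
    """
    X = _as_array(features)
    y_raw = np.asarray(labels, dtype=object)
    if X.shape[0] != y_raw.shape[0]:
        raise ValueError("labels do not match feature rows")
    present = set(y_raw.tolist())
    if len(present) < 2:
        raise ValueError("training data contains a single class")
    cls = tuple(classes) if classes is not None else tuple(sorted(present))
    if not present <= set(cls):
        raise ValueError("labels outside the configured class set")
    index = {c: i for i, c in enumerate(cls)}
    y = np.asarray([index[v] for v in y_raw], dtype=np.intp)
    n, p = X.shape
    mtry = params.resolved_mtry(p)
    in_bag = bootstrap_indices(n, params.n_trees, params.seed)
    tree_seeds = np.random.default_rng(params.seed + 1).integers(
        0, 2**31 - 1, size=params.n_trees
    )
    trees = []
    for t in range(params.n_trees):
        idx = in_bag[t]
        tree = DecisionTreeClassifier(
            criterion=params.criterion,
            max_features=mtry,
            min_samples_leaf=params.min_leaf,
            random_state=int(tree_seeds[t]),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    names = (
        features.feature_names if isinstance(features, FeatureMatrix) else None
    )
    return ForestModel(params, cls, tuple(trees), in_bag, names, p)


def predict_votes(
    model: ForestModel, features: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Per-subject per-class tree vote counts (rows sum to n_trees)."""
    X = _check_alignment(model, features)
    preds = model.tree_predictions(X)
    votes = np.zeros((X.shape[0], len(model.classes)), dtype=np.intp)
    for row in preds:
        votes[np.arange(X.shape[0]), row] += 1
    return votes


def votes_to_labels(votes: np.ndarray, classes: Sequence[str]) -> np.ndarray:
    """Argmax over vote counts; ties go to the earlier configured class."""
    votes = np.asarray(votes)
    winners = votes.argmax(axis=1)  # argmax returns the first maximum
    return np.asarray([classes[i] for i in winners], dtype=object)


def predict_labels(
    model: ForestModel, features: FeatureMatrix | np.ndarray
) -> np.ndarray:
    return votes_to_labels(predict_votes(model, features), model.classes)


@dataclass(frozen=True)
class OOBResult:
    accuracy: float
    n_evaluated: int
    excluded: tuple[str, ...] = ()


def oob_accuracy(
    model: ForestModel,
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[str],
) -> OOBResult:
    """Out-of-bag accuracy: majority vote over trees excluding each subject.

    Subjects in every tree's bag (possible for tiny forests) are excluded
    from the estimate and reported, not fatal.
    """
    X = _check_alignment(model, features)
    y = np.asarray(labels, dtype=object)
    inb = model.in_bag_mask()
    preds = model.tree_predictions(X)
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes)), dtype=np.intp)
    for t in range(model.n_trees):
        out = ~inb[t]
        votes[np.flatnonzero(out), preds[t][out]] += 1
    has_oob = votes.sum(axis=1) > 0
    excluded = tuple(
        features.subject_ids[i] if isinstance(features, FeatureMatrix) else str(i)
        for i in np.flatnonzero(~has_oob)
    )
    if not has_oob.any():
        return OOBResult(float("nan"), 0, excluded)
    pred = votes_to_labels(votes[has_oob], model.classes)
    acc = float(np.mean(pred == y[has_oob]))
    return OOBResult(acc, int(has_oob.sum()), excluded)


def save_forest(model: ForestModel, path) -> None:
    """Serialize a trained model (params, label order, trees, bootstraps)."""
    import pickle

    payload = {
        "format": "mvbc-forest-v1",
        "params": model.params,
        "classes": model.classes,
        "trees": model.trees,
        "in_bag": model.in_bag,
        "feature_names": model.feature_names,
        "n_features": model.n_features,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_forest(path) -> ForestModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != "mvbc-forest-v1":
        raise ValueError(f"{path}: not an mvbc forest archive")
    return ForestModel(
        payload["params"],
        payload["classes"],
        payload["trees"],
        payload["in_bag"],
        payload["feature_names"],
        payload["n_features"],
    )


def feature_importances(model: ForestModel) -> np.ndarray:
    """Mean-decrease-impurity importances, normalized to sum to 1.

    Per feature: the mean over trees of the (sample-weighted) impurity
    decreases summed over the nodes that split on it; features never
    selected score 0.
    """
    imp = np.zeros(model.n_features)
    for tree in model.trees:
        imp += tree.tree_.compute_feature_importances(normalize=False)
    imp /= model.n_trees
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp
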