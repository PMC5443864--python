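"""Nested cross-validation, grid search, permutation null and confusion.

The schedule mirrors standard practice for small-cohort neuroimaging
classifiers: the cohort is split into ``n_outer`` disjoint (stratified)
outer folds; for each outer fold the training subjects are split again
into ``n_inner`` folds on which every hyperparameter configuration is
scored by mean held-out accuracy; the winning configuration (ties go to
the first point in grid order) is retrained on the whole outer-training
set and scored once on the untouched outer test fold.  Every data-driven
stage — confound regression, parcelation, feature extraction — is fitted
on training subjects only, inside the fold.

Significance comes from an empirical permutation null: the training
labels are permuted, the label-dependent stages are re-run, and the
resulting accuracy (scored against the *true* test labels) is recorded.
The unsupervised stages are deterministic functions of the data and fold
structure and do not see labels, so their fold-wise results are cached
and shared across permutation replicates — this is an exact equivalence
with a full re-run, not an approximation.  The p-value uses the add-one
estimator ``(1 + #{null >= observed}) / (1 + n_perm)``, whose smallest
attainable value is ``1 / (n_perm + 1)``; a Gaussian tail fit of the null
is reported alongside for reference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import MultiViewDataset
from .forest import ForestParams, predict_votes, train_forest, votes_to_labels
from .multiview import predict_late, train_intermediate, predict_intermediate, train_late
from .parcellate import (
    FeatureMatrix,
    build_adjacency,
    extract_features,
    fit_parcelation,
    ward_linkage,
)
from .preprocess import regress_out_confounds

__all__ = [
    "CVSchedule",
    "ParamGrid",
    "GridPoint",
    "FoldResult",
    "EvaluationReport",
    "PermutationResult",
    "NestedCVEngine",
    "nested_cv",
    "nested_cv_multi",
    "permutation_test",
    "confusion",
]

MODEL_KINDS = ("sv", "intermediate", "late")


@dataclass(frozen=True)
class CVSchedule:
    """Nested cross-validation layout (outer generalization, inner tuning)."""

    n_outer: int = 5
    n_inner: int = 3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("n_outer and n_inner must be >= 2")


@dataclass(frozen=True)
class GridPoint:
    """One hyperparameter configuration: per-view k plus forest settings."""

    k: tuple[tuple[str, int], ...]
    n_trees: int
    criterion: str
    mtry: int | None

    def k_for(self, view: str) -> int:
        for name, k in self.k:
            if name == view:
                return k
        raise KeyError(f"no cluster count for view {view!r}")

    def forest_params(self, seed: int) -> ForestParams:
        return ForestParams(self.n_trees, self.criterion, self.mtry, seed, 1)

    def as_dict(self) -> dict:
        return {
            "k": dict(self.k),
            "n_trees": self.n_trees,
            "criterion": self.criterion,
            "mtry": self.mtry,
        }


@dataclass(frozen=True)
class ParamGrid:
    """Hyperparameter grid; axes must be non-empty.

    ``k_clusters`` is either a list shared by all views (each grid point
    applies one k to every view) or a mapping view -> list (cartesian
    product across views).
    """

    k_clusters: Sequence[int] | Mapping[str, Sequence[int]]
    n_trees: Sequence[int] = (500,)
    criterion: Sequence[str] = ("gini",)
    mtry: Sequence[int | None] = (None,)

    def points(self, view_names: Sequence[str]) -> list[GridPoint]:
        if isinstance(self.k_clusters, Mapping):
            axes = [
                [(name, int(k)) for k in self.k_clusters[name]]
                for name in view_names
            ]
            k_combos = [tuple(c) for c in itertools.product(*axes)]
        else:
            k_combos = [
                tuple((name, int(k)) for name in view_names)
                for k in self.k_clusters
            ]
        pts = [
            GridPoint(kc, int(nt), str(cr), None if mt is None else int(mt))
            for kc in k_combos
            for nt in self.n_trees
            for cr in self.criterion
            for mt in self.mtry
        ]
        if not pts:
            raise ValueError("empty parameter grid")
        return pts


@dataclass(frozen=True, eq=False)
class FoldResult:
    index: int
    test_ids: tuple[str, ...]
    best_params: GridPoint | dict[str, GridPoint]
    test_accuracy: float
    predictions: dict[str, str]
    parcel_labels: dict[str, np.ndarray]
    confound_coefficients: dict[str, np.ndarray | None]


@dataclass(frozen=True, eq=False)
class PermutationResult:
    observed: float
    null_accuracies: np.ndarray
    n_perm: int

    @property
    def p_value(self) -> float:
        ge = int(np.sum(self.null_accuracies >= self.observed - 1e-12))
        return (1 + ge) / (1 + self.n_perm)

    @property
    def p_gaussian(self) -> float:
        """Parametric tail approximation of the null (reference only)."""
        from scipy.stats import norm

        mu = float(self.null_accuracies.mean())
        sd = float(self.null_accuracies.std(ddof=1))
        if sd == 0:
            return 1.0 if self.observed <= mu else 0.0
        return float(norm.sf((self.observed - mu) / sd))


@dataclass(frozen=True, eq=False)
class EvaluationReport:
    model_kind: str
    view: str | None
    classes: tuple[str, ...]
    folds: tuple[FoldResult, ...]
    mean_accuracy: float
    sd_accuracy: float
    predictions: dict[str, str]
    confusion: pd.DataFrame
    permutation: PermutationResult | None = None


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> pd.DataFrame:
    """Row-normalized confusion matrix in percent.

    Rows are true classes, columns predicted classes; the diagonal holds
    per-class accuracies and each row sums to 100.
    """
    classes = tuple(classes)
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    mat = np.zeros((len(classes), len(classes)))
    for i, c_true in enumerate(classes):
        sel = y_true == c_true
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"no subjects with true class {c_true!r}")
        for j, c_pred in enumerate(classes):
            mat[i, j] = 100.0 * np.sum(y_pred[sel] == c_pred) / n
    return pd.DataFrame(mat, index=list(classes), columns=list(classes))


def _make_folds(labels, n_splits, seed, stratified):
    y = np.asarray(labels, dtype=object)
    idx = np.arange(len(y))
    if stratified:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(idx, y)]
    splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(idx)]


class NestedCVEngine:
    """Runs the nested schedule for a fixed fold structure.

    Fold assignment and every label-blind stage (confound fit, Ward
    linkage, median features) are computed once and cached per (fold,
    view); ``run`` then executes the label-dependent stages — inner grid
    scoring, best-point selection, final training — for an arbitrary
    training-label vector, which is what makes permutation replicates
    cheap and exactly equivalent to a full re-run.
    """

    def __init__(
        self,
        dataset: MultiViewDataset,
        grid: ParamGrid,
        schedule: CVSchedule,
        covariates: Sequence[str] = (),
        connectivity: int = 6,
        classes: Sequence[str] | None = None,
        aggregator: str = "median",
    ):
        self.dataset = dataset
        self.grid = grid
        self.schedule = schedule
        self.covariates = tuple(covariates)
        self.connectivity = connectivity
        self.aggregator = aggregator
        self.classes = (
            tuple(classes) if classes is not None else dataset.classes()
        )
        self.true_labels = dataset.labels
        self.points = grid.points(dataset.view_names)
        self.adjacency = {
            v.view_name: build_adjacency(v.mask, connectivity)
            for v in dataset.views
        }
        self.outer = _make_folds(
            self.true_labels, schedule.n_outer, schedule.seed, schedule.stratified
        )
        self.inner: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for i, (tr, _) in enumerate(self.outer):
            sub = _make_folds(
                self.true_labels[tr],
                schedule.n_inner,
                schedule.seed + 100 + i,
                schedule.stratified,
            )
            self.inner.append([(tr[a], tr[b]) for a, b in sub])
        self._check_class_coverage()
        self._res_cache: dict = {}
        self._tree_cache: dict = {}
        self._feat_cache: dict = {}

    # ------------------------------------------------------------------ folds
    def _check_class_coverage(self) -> None:
        all_classes = set(self.classes)
        splits = [(("outer", i), tr) for i, (tr, _) in enumerate(self.outer)]
        for i, folds in enumerate(self.inner):
            splits += [
                (("inner", i, j), tr) for j, (tr, _) in enumerate(folds)
            ]
        for key, tr in splits:
            present = set(self.true_labels[tr].tolist())
            if present != all_classes:
                missing = sorted(all_classes - present)
                raise ValueError(
                    f"classes {missing} absent from training fold {key}; "
                    "use stratified folds or more subjects per class"
                )

    def _split(self, key) -> tuple[np.ndarray, np.ndarray]:
        if key[0] == "outer":
            return self.outer[key[1]]
        _, i, j = key
        return self.inner[i][j]

    # --------------------------------------------------------- cached stages
    def _residual(self, key, view_name):
        ck = (key, view_name)
        if ck not in self._res_cache:
            view = self.dataset.view(view_name)
            tr, _ = self._split(key)
            if self.covariates:
                res, model = regress_out_confounds(view, self.covariates, tr)
                self._res_cache[ck] = (res, model.coefficients)
            else:
                self._res_cache[ck] = (view, None)
        return self._res_cache[ck]

    def _tree(self, key, view_name):
        ck = (key, view_name)
        if ck not in self._tree_cache:
            res, _ = self._residual(key, view_name)
            tr, _ = self._split(key)
            self._tree_cache[ck] = ward_linkage(
                res.data[tr].T, self.adjacency[view_name]
            )
        return self._tree_cache[ck]

    def _features(self, key, view_name, k) -> FeatureMatrix:
        """Median cluster features for ALL subjects under the fold's fit."""
        ck = (key, view_name, k)
        if ck not in self._feat_cache:
            res, _ = self._residual(key, view_name)
            tr, _ = self._split(key)
            parc = fit_parcelation(
                res.restrict(tr),
                self.adjacency[view_name],
                k,
                tree=self._tree(key, view_name),
            )
            self._feat_cache[ck] = (
                extract_features(res, parc, self.aggregator),
                parc.labels,
            )
        return self._feat_cache[ck][0]

    def parcel_labels(self, key, view_name, k) -> np.ndarray:
        self._features(key, view_name, k)
        return self._feat_cache[(key, view_name, k)][1]

    # ------------------------------------------------------------- modelling
    def _seed(self, key, point_idx: int, tag: int) -> int:
        h = (self.schedule.seed * 1000003 + hash(key) % 65521) % (2**31 - 1)
        return (h * 131 + point_idx * 17 + tag) % (2**31 - 1)

    def _fit_predict(
        self, key, kind, view, point_or_map, train_labels
    ) -> np.ndarray:
        """Train the requested model on the fold's training rows and
        predict its evaluation rows."""
        tr, ev = self._split(key)
        y_tr = train_labels[tr]
        if kind == "sv":
            point = point_or_map
            F = self._features(key, view, point.k_for(view))
            params = point.forest_params(self._seed(key, 0, 1))
            model = train_forest(F.restrict(tr), y_tr, params, self.classes)
            votes = predict_votes(model, F.restrict(ev))
            return votes_to_labels(votes, self.classes)
        if kind == "intermediate":
            point = point_or_map
            per_view_tr = {}
            per_view_ev = {}
            for name in self.dataset.view_names:
                F = self._features(key, name, point.k_for(name))
                per_view_tr[name] = F.restrict(tr)
                per_view_ev[name] = F.restrict(ev)
            params = point.forest_params(self._seed(key, 0, 2))
            model = train_intermediate(per_view_tr, y_tr, params, self.classes)
            labels, _ = predict_intermediate(model, per_view_ev)
            return labels
        if kind == "late":
            points: Mapping[str, GridPoint] = point_or_map
            per_view_tr = {}
            per_view_ev = {}
            params_map = {}
            for vi, name in enumerate(self.dataset.view_names):
                pt = points[name]
                F = self._features(key, name, pt.k_for(name))
                per_view_tr[name] = F.restrict(tr)
                per_view_ev[name] = F.restrict(ev)
                params_map[name] = pt.forest_params(self._seed(key, vi, 3))
            model = train_late(
                per_view_tr, y_tr, params_map, self.classes,
                allow_unequal_trees=True,
            )
            labels, _ = predict_late(model, per_view_ev)
            return labels
        raise ValueError(f"unknown model kind {kind!r}")

    def _inner_score(self, fold_i, kind, view, point, train_labels) -> float:
        accs = []
        for j in range(len(self.inner[fold_i])):
            key = ("inner", fold_i, j)
            _, ev = self._split(key)
            pred = self._fit_predict(key, kind, view, point, train_labels)
            accs.append(float(np.mean(pred == train_labels[ev])))
        return float(np.mean(accs))

    def _select(self, fold_i, kind, view, train_labels):
        """Best grid point(s) by mean inner accuracy; first wins ties.

        For the late model each view's configuration is chosen
        independently by its single-view inner accuracy.
        """
        if kind in ("sv", "intermediate"):
            best, best_score = None, -np.inf
            for point in self.points:
                s = self._inner_score(fold_i, kind, view, point, train_labels)
                if s > best_score:
                    best, best_score = point, s
            return best
        chosen: dict[str, GridPoint] = {}
        for name in self.dataset.view_names:
            best, best_score = None, -np.inf
            for point in self.points:
                s = self._inner_score(fold_i, "sv", name, point, train_labels)
                if s > best_score:
                    best, best_score = point, s
            chosen[name] = best
        return chosen

    def run(
        self,
        train_labels: np.ndarray | None = None,
        model_kind: str = "intermediate",
        view: str | None = None,
        collect_artifacts: bool = True,
    ):
        """Execute the schedule; score outer-test against the TRUE labels.

        ``train_labels`` replaces the labels seen by selection/training
        (used by the permutation null); defaults to the true labels.
        """
        if model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if model_kind == "sv":
            if view is None:
                if len(self.dataset.view_names) == 1:
                    view = self.dataset.view_names[0]
                else:
                    raise ValueError("sv model requires a view name")
            self.dataset.view(view)  # validate
        labels = (
            self.true_labels if train_labels is None
            else np.asarray(train_labels, dtype=object)
        )
        folds = []
        predictions: dict[str, str] = {}
        ids = self.dataset.subject_ids
        skip_inner = len(self.points) == 1
        for i, (tr, te) in enumerate(self.outer):
            if skip_inner:
                best = (
                    self.points[0]
                    if model_kind != "late"
                    else {n: self.points[0] for n in self.dataset.view_names}
                )
            else:
                best = self._select(i, model_kind, view, labels)
            key = ("outer", i)
            pred = self._fit_predict(key, model_kind, view, best, labels)
            acc = float(np.mean(pred == self.true_labels[te]))
            fold_pred = {ids[s]: pred[j] for j, s in enumerate(te)}
            predictions.update(fold_pred)
            parcels: dict[str, np.ndarray] = {}
            coefs: dict[str, np.ndarray | None] = {}
            if collect_artifacts:
                used_views = (
                    [view] if model_kind == "sv" else list(self.dataset.view_names)
                )
                for name in used_views:
                    pt = best[name] if isinstance(best, dict) else best
                    parcels[name] = self.parcel_labels(key, name, pt.k_for(name))
                    coefs[name] = self._residual(key, name)[1]
            folds.append(
                FoldResult(
                    i, tuple(ids[s] for s in te), best, acc, fold_pred,
                    parcels, coefs,
                )
            )
        accs = np.array([f.test_accuracy for f in folds])
        y_pred = np.asarray([predictions[s] for s in ids], dtype=object)
        report = EvaluationReport(
            model_kind,
            view,
            self.classes,
            tuple(folds),
            float(accs.mean()),
            float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            predictions,
            confusion(self.true_labels, y_pred, self.classes),
        )
        return report


def nested_cv(
    dataset: MultiViewDataset,
    model_kind: str,
    grid: ParamGrid,
    schedule: CVSchedule,
    *,
    view: str | None = None,
    covariates: Sequence[str] = (),
    connectivity: int = 6,
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Nested-CV generalization estimate for one model kind."""
    engine = NestedCVEngine(
        dataset, grid, schedule, covariates, connectivity, classes
    )
    return engine.run(None, model_kind, view)


def nested_cv_multi(
    dataset: MultiViewDataset,
    specs: Sequence[tuple[str, str | None]],
    grid: ParamGrid,
    schedule: CVSchedule,
    *,
    covariates: Sequence[str] = (),
    connectivity: int = 6,
    classes: Sequence[str] | None = None,
) -> dict[tuple[str, str | None], EvaluationReport]:
    """Evaluate several model kinds on shared folds and cached features.

    ``specs`` lists ``(model_kind, view)`` pairs (view is None except for
    single-view models).  All models share the identical fold structure,
    confound fits and parcelations, which makes their accuracies directly
    comparable.
    """
    engine = NestedCVEngine(
        dataset, grid, schedule, covariates, connectivity, classes
    )
    return {
        (kind, view): engine.run(None, kind, view) for kind, view in specs
    }


def permutation_test(
    dataset: MultiViewDataset,
    model_kind: str,
    grid: ParamGrid,
    schedule: CVSchedule,
    n_perm: int = 500,
    *,
    view: str | None = None,
    covariates: Sequence[str] = (),
    connectivity: int = 6,
    classes: Sequence[str] | None = None,
    perm_seed: int | None = None,
) -> tuple[EvaluationReport, PermutationResult]:
    """Label-permutation null for the nested-CV accuracy.

    Each replicate permutes the subjects' labels, re-runs selection and
    training with the permuted labels, and scores the outer-test
    predictions against the true labels; the observed accuracy uses the
    unpermuted labels.  Returns the observed report (with the permutation
    result attached) and the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = NestedCVEngine(
        dataset, grid, schedule, covariates, connectivity, classes
    )
    observed = engine.run(None, model_kind, view)
    rng = np.random.default_rng(
        perm_seed if perm_seed is not None else schedule.seed + 7919
    )
    null = np.empty(n_perm)
    for r in range(n_perm):
        permuted = rng.permutation(engine.true_labels)
        rep = engine.run(permuted, model_kind, view, collect_artifacts=False)
        null[r] = rep.mean_accuracy
    perm = PermutationResult(observed.mean_accuracy, null, n_perm)
    report = EvaluationReport(
        observed.model_kind,
        observed.view,
        observed.classes,
        observed.folds,
        observed.mean_accuracy,
        observed.sd_accuracy,
        observed.predictions,
        observed.confusion,
        perm,
    )
    return report, perm
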