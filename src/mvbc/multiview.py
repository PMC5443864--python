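"""Multi-view integration: feature concatenation and pooled-tree voting.

Two strategies combine per-view cluster features into one prediction:

* **intermediate** integration concatenates the views' feature matrices
  before training a single forest, letting splits mix views freely;
* **late** integration trains one forest per view and pools every tree's
  vote into a single count — each *tree* weighs equally, so with equal
  forest sizes per view this coincides with a view-majority vote.

Early (voxel-level) integration is deliberately not offered: gray-matter
and white-matter views carry their signal in disjoint voxel populations,
which makes voxelwise concatenation ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .forest import (
    ForestModel,
    ForestParams,
    predict_votes,
    train_forest,
    votes_to_labels,
)
from .parcellate import FeatureMatrix

__all__ = [
    "IntermediateModel",
    "LateModel",
    "concat_features",
    "train_intermediate",
    "train_late",
    "predict_intermediate",
    "predict_late",
]


@dataclass(frozen=True, eq=False)
class IntermediateModel:
    """Forest on concatenated features plus the view -> column-range map."""

    forest: ForestModel
    view_blocks: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        blocks = dict(self.view_blocks)
        spans = sorted(blocks.values())
        edge = 0
        for lo, hi in spans:
            if lo != edge or hi <= lo:
                raise ValueError("view blocks must partition the columns")
            edge = hi
        if edge != self.forest.n_features:
            raise ValueError("view blocks do not cover the feature space")
        object.__setattr__(self, "view_blocks", blocks)

    @property
    def classes(self) -> tuple[str, ...]:
        return self.forest.classes


@dataclass(frozen=True, eq=False)
class LateModel:
    """One forest per view; prediction pools every view's trees' votes."""

    per_view_forests: Mapping[str, ForestModel]

    def __post_init__(self) -> None:
        forests = dict(self.per_view_forests)
        if not forests:
            raise ValueError("at least one view forest is required")
        ref = next(iter(forests.values())).classes
        for name, f in forests.items():
            if f.classes != ref:
                raise ValueError(
                    f"view {name!r} forest has a different class label order"
                )
        object.__setattr__(self, "per_view_forests", forests)

    @property
    def classes(self) -> tuple[str, ...]:
        return next(iter(self.per_view_forests.values())).classes

    @property
    def total_trees(self) -> int:
        return sum(f.n_trees for f in self.per_view_forests.values())


def concat_features(
    per_view: Mapping[str, FeatureMatrix],
) -> tuple[FeatureMatrix, dict[str, tuple[int, int]]]:
    """Column-wise concatenation in the mapping's view order.

    Returns the combined matrix and the block map recording which column
    range came from which view.  All views must list the same subjects in
    the same order.
    """
    if not per_view:
        raise ValueError("no views to concatenate")
    items = list(per_view.items())
    ref_ids = items[0][1].subject_ids
    for name, fm in items[1:]:
        if fm.subject_ids != ref_ids:
            raise ValueError(f"view {name!r} subject order differs")
    blocks: dict[str, tuple[int, int]] = {}
    mats, names = [], []
    start = 0
    for name, fm in items:
        stop = start + fm.n_features
        blocks[name] = (start, stop)
        start = stop
        mats.append(fm.data)
        names.extend(fm.feature_names)
    combined = FeatureMatrix(np.hstack(mats), tuple(names), ref_ids)
    return combined, blocks


def train_intermediate(
    per_view: Mapping[str, FeatureMatrix],
    labels: Sequence[str],
    params: ForestParams,
    classes: Sequence[str] | None = None,
) -> IntermediateModel:
    combined, blocks = concat_features(per_view)
    forest = train_forest(combined, labels, params, classes)
    return IntermediateModel(forest, blocks)


def predict_intermediate(
    model: IntermediateModel, per_view: Mapping[str, FeatureMatrix]
) -> tuple[np.ndarray, np.ndarray]:
    combined, blocks = concat_features(per_view)
    if dict(blocks) != dict(model.view_blocks):
        raise ValueError("view blocks do not match the trained model")
    votes = predict_votes(model.forest, combined)
    return votes_to_labels(votes, model.classes), votes


def train_late(
    per_view: Mapping[str, FeatureMatrix],
    labels: Sequence[str],
    params: ForestParams | Mapping[str, ForestParams],
    classes: Sequence[str] | None = None,
    allow_unequal_trees: bool = False,
) -> LateModel:
    """Train one forest per view (equal tree counts enforced by default).

    ``params`` may be a single ForestParams shared by the views or a
    per-view mapping (e.g. per-view winners of an inner-loop search).
    Unequal forest sizes silently bias the pooled vote toward the bigger
    forest, hence the guard.
    """
    if classes is None:
        classes = tuple(sorted(set(labels)))
    forests: dict[str, ForestModel] = {}
    for i, (name, fm) in enumerate(per_view.items()):
        p = params[name] if isinstance(params, Mapping) else params
        # decorrelate per-view forests sharing one params object
        p_view = ForestParams(
            p.n_trees, p.criterion, p.mtry, p.seed + 7 * i, p.min_leaf
        )
        forests[name] = train_forest(fm, labels, p_view, classes)
    sizes = {f.n_trees for f in forests.values()}
    if len(sizes) > 1 and not allow_unequal_trees:
        raise ValueError(
            "per-view forests have unequal tree counts; pass "
            "allow_unequal_trees=True to pool them anyway"
        )
    return LateModel(forests)


def predict_late(
    model: LateModel, per_view: Mapping[str, FeatureMatrix]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-tree prediction: element-wise sum of per-view vote counts.

    Returns ``(labels, pooled_votes)``; pooled counts sum, per subject, to
    the total number of trees across views.  Ties break to the earlier
    class in the configured label order.
    """
    missing = set(model.per_view_forests) - set(per_view)
    if missing:
        raise ValueError(f"features missing for views: {sorted(missing)}")
    pooled: np.ndarray | None = None
    for name, forest in model.per_view_forests.items():
        votes = predict_votes(forest, per_view[name])
        pooled = votes if pooled is None else pooled + votes
    assert pooled is not None
    return votes_to_labels(pooled, model.classes), pooled
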