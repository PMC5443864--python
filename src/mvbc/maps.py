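"""Voxel-level relevance maps from trained forests.

Forest importances live on clusters; to make them anatomically comparable
across models they are re-normalized to unit mass within each view and
spread uniformly over each cluster's member voxels (score / cluster size),
so every map sums to 1 over the mask regardless of the model it came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .data_model import BrainMask, save_map
from .forest import ForestModel, feature_importances
from .multiview import IntermediateModel
from .parcellate import Parcelation

__all__ = [
    "ImportanceMap",
    "spread_cluster_scores",
    "project_importances",
    "compare_maps",
    "save_importance_map",
]


@dataclass(frozen=True, eq=False)
class ImportanceMap:
    """Non-negative per-voxel relevance scores summing to 1 on the mask."""

    view_name: str
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("importance values must be a 1-D voxel vector")
        if (values < 0).any():
            raise ValueError("importance values must be non-negative")
        if abs(values.sum() - 1.0) > 1e-6:
            raise ValueError(f"importance mass is {values.sum()}, not 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


def spread_cluster_scores(
    scores: np.ndarray, parcelation: Parcelation
) -> np.ndarray:
    """Spread per-cluster scores to voxels, size-normalized.

    Scores are first re-normalized to sum to 1; cluster score ``s_c`` then
    contributes ``s_c / |c|`` to each of its member voxels, so the voxel
    map conserves total mass 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (parcelation.k,):
        raise ValueError(
            f"expected {parcelation.k} cluster scores, got {scores.shape}"
        )
    if (scores < 0).any():
        raise ValueError("cluster scores must be non-negative")
    total = scores.sum()
    if total <= 0:
        raise ValueError("all cluster scores are zero; nothing to project")
    scores = scores / total
    sizes = parcelation.cluster_sizes()
    return (scores / sizes)[parcelation.labels]


def project_importances(
    model: ForestModel | IntermediateModel,
    parcelation: Parcelation,
    view_name: str | None = None,
) -> ImportanceMap:
    """Back-project cluster importances to voxels for one view.

    For an intermediate (concatenated) model the importance vector is
    first sliced to the view's column block and re-normalized to sum to 1
    within the view; cluster score ``s_c`` then contributes ``s_c / |c|``
    to each member voxel, conserving total mass 1.
    """
    if isinstance(model, IntermediateModel):
        if view_name is None:
            view_name = parcelation.view_name
        if view_name not in model.view_blocks:
            raise ValueError(f"view {view_name!r} absent from the block map")
        lo, hi = model.view_blocks[view_name]
        scores = feature_importances(model.forest)[lo:hi]
        source = "intermediate"
    else:
        scores = feature_importances(model)
        view_name = view_name or parcelation.view_name
        source = "sv"
    if scores.shape[0] != parcelation.k:
        raise ValueError(
            f"{scores.shape[0]} importances but parcelation has "
            f"{parcelation.k} clusters"
        )
    per_voxel = spread_cluster_scores(scores, parcelation)
    return ImportanceMap(view_name, per_voxel, source)


def compare_maps(a: ImportanceMap, b: ImportanceMap) -> float:
    """Spearman rank correlation of two voxel relevance maps.

    Rank-based on purpose: impurity importances are heavy tailed, so a
    linear correlation would be driven by a handful of top clusters.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("maps are defined on different masks")
    rho = spearmanr(a.values, b.values).statistic
    return float(rho)


def save_importance_map(imp: ImportanceMap, mask: BrainMask, path) -> None:
    if mask.n_voxels != imp.values.shape[0]:
        raise ValueError("mask does not match the importance map")
    save_map(imp.values, mask, path)
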