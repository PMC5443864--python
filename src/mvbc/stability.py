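"""Held-out-subject stability analysis and the five-group taxonomy.

For each target subject the models are retrained ``n_rep`` times on random
70% subsets of the cohort that never contain the target; the target's
predicted label is recorded each time and the remaining 30% holdout is
scored as an over-training check.  A subject whose label distribution
concentrates (majority fraction above a threshold) is *stable* under that
model; comparing stable labels across single-view and multi-view models
partitions subjects into five groups — correct everywhere, consistently
mis-assigned to one specific class (by every model), rescued by the
multi-view models, or unstable/disagreeing.

A *patients-only* variant removes one class (e.g. the controls) from every
training subset, so targets can only receive the remaining labels; a
systematic mis-assignment that persists under this restriction indicates a
feature pattern genuinely shared with the wrongly assigned class rather
than a quirk of the training-set composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MultiViewDataset
from .forest import ForestParams, predict_votes, train_forest, votes_to_labels
from .multiview import predict_intermediate, predict_late, train_intermediate, train_late
from .parcellate import build_adjacency, extract_features, fit_parcelation
from .preprocess import regress_out_confounds

__all__ = [
    "StabilityReport",
    "stability_analysis",
    "restricted_class_variant",
    "assign_groups",
    "UNSTABLE",
]

#: sentinel label for subjects without a majority-stable prediction
UNSTABLE = "unstable"

ModelKind = str | tuple[str, str]  # "intermediate" | "late" | ("sv", view)


def _kind_key(kind: ModelKind) -> str:
    if isinstance(kind, tuple):
        return f"sv:{kind[1]}"
    return kind


@dataclass(frozen=True, eq=False)
class StabilityReport:
    """Per-target label distributions over repetitions, per model kind."""

    target_class: str
    classes: tuple[str, ...]
    model_kinds: tuple[str, ...]
    n_rep: int
    counts: Mapping[str, pd.DataFrame]  # kind -> targets x classes counts
    holdout_accuracy: Mapping[str, np.ndarray]  # kind -> (targets, n_rep)
    excluded_class: str | None = None
    holdout_floor: float | None = None

    @property
    def target_ids(self) -> tuple[str, ...]:
        first = self.counts[self.model_kinds[0]]
        return tuple(first.index)

    def majority(self, kind: str, threshold: float = 0.5) -> pd.Series:
        """Stable label per target: majority fraction > threshold, else
        ``unstable`` (ties are never stable)."""
        df = self.counts[kind]
        out = {}
        for sid, row in df.iterrows():
            counts = row.to_numpy()
            top = counts.max()
            if top / self.n_rep <= threshold or (counts == top).sum() > 1:
                out[sid] = UNSTABLE
            else:
                out[sid] = df.columns[int(counts.argmax())]
        return pd.Series(out, name=kind)

    def flagged_repetitions(self, floor: float) -> dict[str, np.ndarray]:
        """(target, rep) pairs whose holdout accuracy fell below ``floor``."""
        return {
            kind: np.argwhere(acc < floor)
            for kind, acc in self.holdout_accuracy.items()
        }


def _predict_one(
    kind: ModelKind,
    per_view_train,
    per_view_eval,
    y_train,
    params: ForestParams,
    classes,
):
    if isinstance(kind, tuple):  # ("sv", view)
        _, view = kind
        model = train_forest(per_view_train[view], y_train, params, classes)
        votes = predict_votes(model, per_view_eval[view])
        return votes_to_labels(votes, classes)
    if kind == "intermediate":
        model = train_intermediate(per_view_train, y_train, params, classes)
        labels, _ = predict_intermediate(model, per_view_eval)
        return labels
    if kind == "late":
        model = train_late(per_view_train, y_train, params, classes)
        labels, _ = predict_late(model, per_view_eval)
        return labels
    raise ValueError(f"unknown model kind {kind!r}")


def stability_analysis(
    dataset: MultiViewDataset,
    target_class: str,
    model_kinds: Sequence[ModelKind],
    *,
    k_per_view: Mapping[str, int],
    params: ForestParams | Mapping[str, ForestParams] = ForestParams(n_trees=100),
    n_rep: int = 100,
    train_frac: float = 0.70,
    seed: int = 0,
    covariates: Sequence[str] = (),
    connectivity: int = 6,
    classes: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    excluded_class: str | None = None,
    refit_parcelation: bool = True,
    holdout_floor: float | None = None,
    max_resample: int = 20,
) -> StabilityReport:
    """Repeatedly retrain on random subsets that exclude each target.

    Parameters
    ----------
    target_class:
        Class whose subjects are analysed (optionally restricted to the
        ids in ``targets``).
    model_kinds:
        Any of ``("sv", view_name)``, ``"intermediate"``, ``"late"``.
    k_per_view, params:
        Frozen hyperparameters (e.g. the nested-CV winners); stability
        repetitions do not re-tune.
    excluded_class:
        If given, subjects of this class never enter a training subset
        (the patients-only variant when the control class is excluded).
    refit_parcelation:
        Refit confound model and parcelation on every 70% subset (strict,
        default).  ``False`` fits them once per target on all non-target
        subjects — faster but approximate, as the unsupervised fit then
        sees subjects outside the current training subset.

    Training subsets of size ``round(train_frac * n_subjects)`` are drawn
    uniformly without class stratification; draws missing a trainable
    class are resampled (up to ``max_resample`` times).
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    cls = tuple(classes) if classes is not None else dataset.classes()
    labels = dataset.labels
    ids = dataset.subject_ids
    if target_class not in cls:
        raise ValueError(f"unknown target class {target_class!r}")
    target_idx = [i for i, s in enumerate(ids) if labels[i] == target_class]
    if targets is not None:
        want = set(targets)
        unknown = want - set(ids)
        if unknown:
            raise ValueError(f"unknown target ids: {sorted(unknown)}")
        bad = [s for s in want if labels[ids.index(s)] != target_class]
        if bad:
            raise ValueError(
                f"targets {sorted(bad)} do not belong to class {target_class!r}"
            )
        target_idx = [i for i in target_idx if ids[i] in want]
    if not target_idx:
        raise ValueError("no target subjects selected")
    train_classes = tuple(c for c in cls if c != excluded_class)
    if excluded_class is not None and len(train_classes) < 2:
        raise ValueError("at least two classes must remain for training")
    kind_keys = tuple(_kind_key(k) for k in model_kinds)
    adjacency = {
        v.view_name: build_adjacency(v.mask, connectivity)
        for v in dataset.views
    }
    n = dataset.n_subjects
    n_train = int(round(train_frac * n))
    counts = {
        key: pd.DataFrame(
            0, index=[ids[i] for i in target_idx], columns=list(cls)
        )
        for key in kind_keys
    }
    holdout = {
        key: np.full((len(target_idx), n_rep), np.nan) for key in kind_keys
    }
    root = np.random.SeedSequence(seed)
    target_seeds = root.spawn(len(target_idx))
    for ti, t in enumerate(target_idx):
        rng = np.random.default_rng(target_seeds[ti])
        pool = np.array(
            [
                i
                for i in range(n)
                if i != t and labels[i] in train_classes
            ]
        )
        n_tr = min(n_train, len(pool) - 1)
        for rep in range(n_rep):
            for _attempt in range(max_resample):
                train_rows = rng.choice(pool, size=n_tr, replace=False)
                if set(labels[train_rows]) == set(train_classes):
                    break
            else:
                raise RuntimeError(
                    "could not draw a training subset containing every class"
                )
            assert t not in train_rows
            holdout_rows = np.array(
                sorted(set(range(n)) - set(train_rows.tolist()) - {t})
            )
            eval_rows = np.concatenate([[t], holdout_rows])
            per_view_train = {}
            per_view_eval = {}
            for view in dataset.views:
                name = view.view_name
                if covariates:
                    res, _ = regress_out_confounds(view, covariates, train_rows)
                else:
                    res = view
                fit_rows = (
                    train_rows
                    if refit_parcelation
                    else np.array([i for i in range(n) if i != t])
                )
                parc = fit_parcelation(
                    res.restrict(fit_rows), adjacency[name], k_per_view[name]
                )
                F = extract_features(res, parc)
                per_view_train[name] = F.restrict(train_rows)
                per_view_eval[name] = F.restrict(eval_rows)
            for kind, key in zip(model_kinds, kind_keys):
                p = params[key] if isinstance(params, Mapping) else params
                p = ForestParams(
                    p.n_trees,
                    p.criterion,
                    p.mtry,
                    int(rng.integers(0, 2**31 - 1)),
                    p.min_leaf,
                )
                pred = _predict_one(
                    kind,
                    per_view_train,
                    per_view_eval,
                    labels[train_rows],
                    p,
                    train_classes,
                )
                counts[key].loc[ids[t], pred[0]] += 1
                if len(holdout_rows):
                    acc = float(np.mean(pred[1:] == labels[holdout_rows]))
                    holdout[key][ti, rep] = acc
    return StabilityReport(
        target_class,
        cls,
        kind_keys,
        n_rep,
        counts,
        holdout,
        excluded_class,
        holdout_floor,
    )


def restricted_class_variant(
    dataset: MultiViewDataset,
    excluded_class: str,
    target_class: str,
    model_kinds: Sequence[ModelKind],
    **kwargs,
) -> StabilityReport:
    """Stability analysis with one class removed from every training set.

    Targets can then only receive the remaining labels (e.g. controls can
    only be called one of the pathological classes).
    """
    return stability_analysis(
        dataset,
        target_class,
        model_kinds,
        excluded_class=excluded_class,
        **kwargs,
    )


def assign_groups(
    report: StabilityReport,
    stability_threshold: float = 0.5,
    sv_kinds: Sequence[str] | None = None,
    mv_kinds: Sequence[str] | None = None,
) -> pd.Series:
    """Assign each target to one of the five stability groups.

    * ``correct-stable`` — every model stable on the true class;
    * ``stable-as-<c>`` — every model stable on the same wrong class c;
    * ``mv-rescued`` — all multi-view models stable-correct while at most
      one single-view model is correct;
    * ``unstable`` — everything else (disagreement or no stable label).

    The assignment is a total function of the label distributions and the
    threshold.
    """
    if sv_kinds is None:
        sv_kinds = [k for k in report.model_kinds if k.startswith("sv:")]
    if mv_kinds is None:
        mv_kinds = [k for k in report.model_kinds if not k.startswith("sv:")]
    majorities = {
        k: report.majority(k, stability_threshold) for k in report.model_kinds
    }
    out = {}
    for sid in report.target_ids:
        stable = {k: majorities[k][sid] for k in report.model_kinds}
        vals = set(stable.values())
        if vals == {report.target_class}:
            out[sid] = "correct-stable"
            continue
        if len(vals) == 1 and UNSTABLE not in vals:
            out[sid] = f"stable-as-{vals.pop()}"
            continue
        sv_correct = sum(
            1 for k in sv_kinds if stable[k] == report.target_class
        )
        mv_all_correct = mv_kinds and all(
            stable[k] == report.target_class for k in mv_kinds
        )
        if mv_all_correct and sv_correct <= 1:
            out[sid] = "mv-rescued"
        else:
            out[sid] = UNSTABLE
    return pd.Series(out, name="group")
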