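"""Voxelwise confound regression, smoothness estimation and template GOF.

Confound removal fits, per voxel, an ordinary-least-squares model
``value ~ intercept + covariates`` on a designated set of (training)
subjects and subtracts the fitted values from *all* subjects, so the model
can be estimated inside a cross-validation fold and applied to held-out
subjects without leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import BrainMask, ViewDataset

__all__ = [
    "ConfoundModel",
    "regress_out_confounds",
    "estimate_smoothness",
    "goodness_of_fit",
]

#: FWHM of a Gaussian with unit standard deviation
GAUSSIAN_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True, eq=False)
class ConfoundModel:
    """Per-voxel OLS coefficients for intercept + named covariates.

    ``coefficients`` has shape ``(1 + n_covariates, n_voxels)``; row 0 is
    the intercept, following rows align with ``covariate_names``.
    """

    covariate_names: tuple[str, ...]
    coefficients: np.ndarray

    def design(self, view: ViewDataset) -> np.ndarray:
        X = view.covariate_matrix(self.covariate_names)
        return np.column_stack([np.ones(len(X)), X])

    def apply(self, view: ViewDataset) -> ViewDataset:
        """Subtract the fitted confound model from every subject."""
        if self.coefficients.shape[1] != view.mask.n_voxels:
            raise ValueError("confound model does not match view geometry")
        fitted = self.design(view) @ self.coefficients
        return view.with_data(view.data - fitted)


def _collinear_covariates(X: np.ndarray, names: Sequence[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        others = np.column_stack([np.ones(len(X)), others])
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-10 * scale:
            bad.append(names[j])
    return bad


def regress_out_confounds(
    view: ViewDataset,
    covariate_names: Sequence[str],
    fit_subjects: Sequence[int] | None = None,
) -> tuple[ViewDataset, ConfoundModel]:
    """Remove linear covariate effects (e.g. age, sex) voxel by voxel.

    Parameters
    ----------
    view:
        Input view; all subjects are residualized.
    covariate_names:
        Covariates to regress out; must be present for every subject.
    fit_subjects:
        Row indices used to fit the model (default: all rows).  Pass the
        training rows of a fold so test subjects never influence the fit.

    Returns the residualized view and the fitted :class:`ConfoundModel`.
    """
    names = tuple(covariate_names)
    if fit_subjects is None:
        fit_rows = np.arange(view.n_subjects)
    else:
        fit_rows = np.asarray(fit_subjects, dtype=int)
    if len(fit_rows) < len(names) + 2:
        raise ValueError(
            f"need at least {len(names) + 2} fit subjects, got {len(fit_rows)}"
        )
    Xc = view.covariate_matrix(names)[fit_rows]
    X = np.column_stack([np.ones(len(fit_rows)), Xc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_covariates(Xc, list(names)) or list(names)
        raise ValueError(f"rank-deficient confound design; collinear: {bad}")
    Y = view.data[fit_rows]
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    model = ConfoundModel(names, coef)
    return model.apply(view), model


def estimate_smoothness(values: np.ndarray, mask: BrainMask) -> float:
    """Estimate the spatial smoothness of an in-mask map, in voxel FWHM.

    A simple Gaussian model: for each grid axis the lag-1 Pearson
    correlation ``r`` of in-mask neighbour pairs is inverted as the
    equivalent Gaussian smoothing kernel that would produce it from white
    noise (``sigma^2 = -1 / (4 ln r)``, since such a field has lag-d
    autocorrelation ``exp(-d^2 / (4 sigma^2))``); the per-axis FWHMs
    (``2 sqrt(2 ln 2) sigma``; 0 where ``r <= 0``) are averaged.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise ValueError("values must be per-voxel on the mask")
    if np.ptp(values) == 0:
        raise ValueError("constant volume: smoothness undefined")
    vol = np.full(mask.shape, np.nan)
    vol[tuple(mask.indices.T)] = values
    fwhms = []
    for axis in range(3):
        a = vol.take(range(0, mask.shape[axis] - 1), axis=axis)
        b = vol.take(range(1, mask.shape[axis]), axis=axis)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2:
            continue
        x, y = a[ok], b[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("constant neighbour values: correlation undefined")
        r = float(np.corrcoef(x, y)[0, 1])
        if r >= 1.0 - 1e-12:
            raise ValueError(f"axis {axis}: lag-1 correlation {r} >= 1")
        if r <= 0.0:
            fwhms.append(0.0)
        else:
            sigma = np.sqrt(-1.0 / (4.0 * np.log(r)))
            fwhms.append(GAUSSIAN_FWHM * sigma)
    if not fwhms:
        raise ValueError("no axis with enough in-mask neighbour pairs")
    return float(np.mean(fwhms))


def goodness_of_fit(
    values: np.ndarray, mask: BrainMask, template: BrainMask
) -> float:
    """Template goodness of fit: mean(inside template) - mean(outside).

    Used to pick the component map best matching a network template; the
    template must be a strict subset of the data mask so both the inside
    and the outside sets are non-empty.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise ValueError("values must be per-voxel on the mask")
    if template.shape != mask.shape:
        raise ValueError("template grid shape differs from data mask")
    inside = np.isin(mask.flat_indices, template.flat_indices)
    if not np.isin(template.flat_indices, mask.flat_indices).all():
        raise ValueError("template must lie inside the data mask")
    n_in = int(inside.sum())
    if n_in == 0 or n_in == mask.n_voxels:
        raise ValueError("template inside/outside sets must both be non-empty")
    return float(values[inside].mean() - values[~inside].mean())
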