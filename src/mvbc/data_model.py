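"""Core containers for multi-view voxel datasets and NIfTI I/O.

A *view* is one imaging modality's per-subject parametric map (e.g. an
ICA-derived default-mode-network component map, or a fractional-anisotropy
map).  All views of a cohort share the same ordered subject list but may use
different brain masks.  In-mask voxels are linearized in a fixed C order
(last grid axis fastest) so that feature columns have a stable identity
across runs, folds and processes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AFFINE_ATOL",
    "BrainMask",
    "SubjectRecord",
    "ViewDataset",
    "MultiViewDataset",
    "load_mask",
    "load_view",
    "save_map",
]

#: absolute tolerance when comparing affines of volumes against the mask
AFFINE_ATOL = 1e-4


@dataclass(frozen=True, eq=False)
class BrainMask:
    """Set of in-mask grid coordinates with the voxel-to-world affine.

    ``indices`` is an ``(n_voxels, 3)`` integer array sorted by C-order flat
    index (this ordering defines the column order of every data matrix built
    on the mask).  Grid indices are 0-based; world coordinates are obtained
    only through ``affine``.
    """

    shape: tuple[int, int, int]
    indices: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("mask indices must be an (n, 3) array")
        if idx.shape[0] == 0:
            raise ValueError("mask is empty")
        if (idx < 0).any() or (idx >= np.asarray(shape)).any():
            raise ValueError("mask coordinates fall outside the grid shape")
        flat = np.ravel_multi_index(idx.T, shape)
        if np.unique(flat).size != flat.size:
            raise ValueError("mask contains duplicate coordinates")
        order = np.argsort(flat, kind="stable")
        idx = np.ascontiguousarray(idx[order])
        idx.setflags(write=False)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is singular")
        aff = aff.copy()
        aff.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_volume(cls, volume: np.ndarray, affine: np.ndarray) -> "BrainMask":
        """Build a mask from a 3-D array; nonzero voxels are in-mask."""
        volume = np.asarray(volume)
        if volume.ndim != 3:
            raise ValueError("mask volume must be 3-D")
        return cls(volume.shape, np.argwhere(volume != 0), affine)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])

    @property
    def flat_indices(self) -> np.ndarray:
        """C-order flat index of each in-mask voxel (sorted ascending)."""
        return np.ravel_multi_index(self.indices.T, self.shape)

    def boolean_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol[tuple(self.indices.T)] = True
        return vol

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel ``values`` back into a full 3-D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        vol = np.full(self.shape, fill, dtype=float)
        vol[tuple(self.indices.T)] = values
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Read the in-mask voxels of a full 3-D volume (C order)."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} != mask shape {self.shape}"
            )
        return volume[tuple(self.indices.T)]

    def same_geometry(self, other: "BrainMask") -> bool:
        return (
            self.shape == other.shape
            and self.n_voxels == other.n_voxels
            and bool(np.array_equal(self.indices, other.indices))
            and bool(np.allclose(self.affine, other.affine, atol=AFFINE_ATOL))
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, class label and complete covariates."""

    subject_id: str
    label: str
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = {str(k): float(v) for k, v in dict(self.covariates).items()}
        for name, value in cov.items():
            if not np.isfinite(value):
                raise ValueError(
                    f"subject {self.subject_id!r}: covariate {name!r} is not finite"
                )
        object.__setattr__(self, "covariates", cov)


@dataclass(frozen=True, eq=False)
class ViewDataset:
    """One view's subjects x voxels matrix plus mask geometry and metadata."""

    view_name: str
    data: np.ndarray
    mask: BrainMask
    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        subjects = tuple(self.subjects)
        if data.ndim != 2:
            raise ValueError("view data must be 2-D (subjects x voxels)")
        if data.shape[0] != len(subjects):
            raise ValueError("row count does not match number of subjects")
        if data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"view {self.view_name!r}: {data.shape[1]} columns but mask has "
                f"{self.mask.n_voxels} voxels"
            )
        if not np.isfinite(data).all():
            raise ValueError(f"view {self.view_name!r}: non-finite values")
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "subjects", subjects)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(s.subject_id for s in self.subjects)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.subjects], dtype=object)

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        """Subjects x covariates matrix in the requested column order."""
        cols = []
        for name in names:
            try:
                cols.append([s.covariates[name] for s in self.subjects])
            except KeyError:
                raise KeyError(f"covariate {name!r} missing for some subject")
        return np.asarray(cols, dtype=float).T.reshape(self.n_subjects, len(names))

    def restrict(self, rows: Sequence[int]) -> "ViewDataset":
        rows = np.asarray(rows, dtype=int)
        return ViewDataset(
            self.view_name,
            self.data[rows],
            self.mask,
            tuple(self.subjects[i] for i in rows),
        )

    def with_data(self, data: np.ndarray) -> "ViewDataset":
        return ViewDataset(self.view_name, data, self.mask, self.subjects)


@dataclass(frozen=True, eq=False)
class MultiViewDataset:
    """Ordered collection of views sharing the identical subject list."""

    views: tuple[ViewDataset, ...]

    def __post_init__(self) -> None:
        views = tuple(self.views)
        if not views:
            raise ValueError("at least one view is required")
        names = [v.view_name for v in views]
        if len(set(names)) != len(names):
            raise ValueError("view names must be unique")
        ref = views[0].subject_ids
        for v in views[1:]:
            if v.subject_ids != ref:
                raise ValueError(
                    f"view {v.view_name!r} has a different subject list/order"
                )
        object.__setattr__(self, "views", views)

    @property
    def view_names(self) -> tuple[str, ...]:
        return tuple(v.view_name for v in self.views)

    @property
    def subjects(self) -> tuple[SubjectRecord, ...]:
        return self.views[0].subjects

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return self.views[0].subject_ids

    @property
    def labels(self) -> np.ndarray:
        return self.views[0].labels

    @property
    def n_subjects(self) -> int:
        return self.views[0].n_subjects

    def view(self, name: str) -> ViewDataset:
        for v in self.views:
            if v.view_name == name:
                return v
        raise KeyError(f"no view named {name!r}")

    def restrict(self, rows: Sequence[int]) -> "MultiViewDataset":
        return MultiViewDataset(tuple(v.restrict(rows) for v in self.views))

    def classes(self) -> tuple[str, ...]:
        """Sorted unique class labels (the configured label order default)."""
        return tuple(sorted(set(self.labels)))


def load_mask(path: str | Path) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask.from_volume(np.asanyarray(img.dataobj), img.affine)


def _read_subject_table(table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        path = Path(table)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep)
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise ValueError(f"subject table lacks required column {col!r}")
    if df.isna().any().any():
        raise ValueError("subject table contains missing values")
    return df


def load_view(
    nifti_paths: Sequence[str | Path],
    mask_path: str | Path | BrainMask,
    subject_table: str | Path | pd.DataFrame,
    view_name: str = "view",
) -> ViewDataset:
    """Assemble a ViewDataset from per-subject NIfTI volumes.

    Table rows and files correspond 1:1 in order.  Every volume must share
    the mask's grid shape and affine (within ``AFFINE_ATOL``); values are
    read in the file's native scaling.
    """
    mask = mask_path if isinstance(mask_path, BrainMask) else load_mask(mask_path)
    df = _read_subject_table(subject_table)
    paths = [Path(p) for p in nifti_paths]
    if len(paths) != len(df):
        raise ValueError(
            f"{len(paths)} volumes but {len(df)} subject-table rows"
        )
    cov_names = [c for c in df.columns if c not in ("subject_id", "label")]
    subjects = tuple(
        SubjectRecord(
            str(row["subject_id"]),
            str(row["label"]),
            {c: float(row[c]) for c in cov_names},
        )
        for _, row in df.iterrows()
    )
    data = np.empty((len(paths), mask.n_voxels), dtype=float)
    for i, path in enumerate(paths):
        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj)
        if vol.ndim == 4 and vol.shape[3] == 1:
            vol = vol[..., 0]
        if vol.shape != mask.shape:
            raise ValueError(
                f"{path}: shape {vol.shape} does not match mask {mask.shape}"
            )
        if not np.allclose(img.affine, mask.affine, atol=AFFINE_ATOL):
            raise ValueError(f"{path}: affine differs from mask affine")
        data[i] = mask.extract(np.asarray(vol, dtype=float))
    return ViewDataset(view_name, data, mask, subjects)


def save_map(
    values: np.ndarray, mask: BrainMask, path: str | Path, dtype=np.float32
) -> None:
    """Write per-voxel values as a NIfTI volume (0 outside the mask)."""
    vol = mask.unmask(np.asarray(values, dtype=float)).astype(dtype)
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))
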